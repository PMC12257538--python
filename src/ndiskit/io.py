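"""File I/O: curve TSVs with metadata headers, composition files, trajectories.

Trajectory formats (GRO, PDB, XYZ) are read and written through MDAnalysis;
atom-class assignment uses a plain-text mapping file (atom name + residue
name -> class), with molecule ids taken from residue numbering.  Curves (RDF,
S(Q), difference functions, experiment) are two-column TSV with '#'-prefixed
key: value metadata headers so every artifact carries its provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .composition import AtomClass, SolutionComposition, Species
from .structure import Configuration, PartialStructureFactor, RadialDistribution

__all__ = [
    "write_curve",
    "read_curve",
    "write_rdf",
    "write_sq",
    "read_sq",
    "load_composition",
    "load_class_map",
    "read_trajectory",
    "write_gro",
    "write_xyz",
    "write_class_map",
]


# ---------------------------------------------------------------------------
# curves


def write_curve(path: str | Path, x, y, meta: dict | None = None,
                columns: tuple[str, str] = ("Q", "value")) -> None:
    lines = []
    for key, val in (meta or {}).items():
        if isinstance(val, (dict, list, tuple)):
            val = json.dumps(val, default=str)
        lines.append(f"# {key}: {val}")
    lines.append(f"# columns: {columns[0]}\t{columns[1]}")
    for xi, yi in zip(np.asarray(x), np.asarray(y)):
        lines.append(f"{xi:.8g}\t{yi:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column TSV (or whitespace) curve; '#' lines become metadata."""
    meta: dict = {}
    xs, ys = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed curve line: {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    return np.asarray(xs), np.asarray(ys), meta


def write_rdf(path: str | Path, rdf: RadialDistribution) -> None:
    meta = {
        "kind": "rdf",
        "pair": f"{rdf.pair[0]}-{rdf.pair[1]}",
        "n_frames": rdf.n_frames,
        "partner_density": rdf.partner_density,
        "total_density": rdf.total_density,
        **rdf.meta,
    }
    write_curve(path, rdf.r, rdf.g, meta, columns=("r_A", "g"))


def write_sq(path: str | Path, sq: PartialStructureFactor) -> None:
    meta = {
        "kind": "sq",
        "pair": f"{sq.pair[0]}-{sq.pair[1]}",
        "convention": sq.convention,
        **sq.meta,
    }
    write_curve(path, sq.Q, sq.S, meta, columns=("Q_invA", "S"))


def read_sq(path: str | Path) -> PartialStructureFactor:
    Q, S, meta = read_curve(path)
    pair = tuple(meta.get("pair", "?-?").split("-")[:2])
    return PartialStructureFactor(pair=pair, Q=Q, S=S, meta=meta)


# ---------------------------------------------------------------------------
# composition files (YAML)


def load_composition(path: str | Path) -> SolutionComposition:
    """Load a solution composition from a YAML file.

    Schema::

        solvent_isotope: D2O
        temperature: 296.15      # optional, K
        label: "2 m TMACl + 2 m pyridine"   # optional
        classes:
          H_W: {element: H, exchangeable: true}
          H_TMA: {element: H, substitutable: true}
          O: {element: O}
        species:
          - {name: water, mole_ratio: 55.508, atoms: {H_W: 2, O: 1}}
    """
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("classes", "species"):
        if key not in doc:
            raise ValueError(f"composition file missing required field {key!r}")
    classes = {
        label: AtomClass(
            label=label,
            element=spec["element"],
            exchangeable=bool(spec.get("exchangeable", False)),
            substitutable=bool(spec.get("substitutable", False)),
            isotope=spec.get("isotope"),
        )
        for label, spec in doc["classes"].items()
    }
    species = [
        Species(sp["name"], float(sp["mole_ratio"]), dict(sp["atoms"]))
        for sp in doc["species"]
    ]
    return SolutionComposition(
        species=species,
        classes=classes,
        solvent_isotope=doc.get("solvent_isotope", "D2O"),
        temperature=doc.get("temperature"),
        label=doc.get("label", ""),
    )


# ---------------------------------------------------------------------------
# trajectories


def load_class_map(path: str | Path) -> dict[tuple[str, str], str]:
    """Read an (atom name, residue name) -> atom-class mapping.

    Three whitespace-separated columns: atom_name, residue_name, class.
    '*' wildcards the residue name.
    """
    mapping: dict[tuple[str, str], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"class-map line needs 3 columns: {line!r}")
        mapping[(parts[0], parts[1])] = parts[2]
    return mapping


def write_class_map(path: str | Path, mapping: dict[tuple[str, str], str]) -> None:
    lines = ["# atom_name\tresidue_name\tclass"]
    for (atom, res), cls in mapping.items():
        lines.append(f"{atom}\t{res}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n")


def _classify(name: str, resname: str, mapping: dict[tuple[str, str], str]) -> str:
    for key in ((name, resname), (name, "*")):
        if key in mapping:
            return mapping[key]
    raise KeyError(f"no atom-class mapping for atom {name!r} in residue {resname!r}")


def read_trajectory(
    topology: str | Path,
    class_map: dict[tuple[str, str], str] | str | Path,
    box: Sequence[float] | None = None,
) -> list[Configuration]:
    """Read GRO/PDB/XYZ configurations into labelled Configuration frames.

    ``box`` overrides (or supplies, for XYZ) the periodic box edge lengths in
    Angstrom.  Triclinic boxes are rejected: the minimum-image machinery is
    orthorhombic only.
    """
    import MDAnalysis as mda

    if not isinstance(class_map, dict):
        class_map = load_class_map(class_map)
    u = mda.Universe(str(topology))
    n = len(u.atoms)
    # XYZ files carry no residue information: wildcard residues, one
    # molecule id per atom (intramolecular exclusion then has no effect)
    resnames = (u.atoms.resnames if hasattr(u.atoms, "resnames")
                else np.full(n, "*"))
    mol_ids = (u.atoms.resids.astype(int) if hasattr(u.atoms, "resids")
               else np.arange(n))
    labels = np.array(
        [_classify(name, res, class_map)
         for name, res in zip(u.atoms.names, resnames)]
    )
    frames = []
    for _ in u.trajectory:
        if box is not None:
            edges = np.asarray(box, dtype=float)
        else:
            dims = u.dimensions
            if dims is None or not np.any(dims[:3]):
                raise ValueError(
                    "no box in file; supply edge lengths via the box argument"
                )
            if not np.allclose(dims[3:], 90.0):
                raise ValueError("triclinic boxes are not supported (orthorhombic only)")
            edges = dims[:3].astype(float)
        frames.append(
            Configuration(
                box=edges,
                labels=labels,
                molecule_ids=mol_ids,
                positions=u.atoms.positions.astype(float).copy(),
            )
        )
    return frames


def _as_universe(conf: Configuration, resnames: dict[str, str] | None = None):
    """Build an MDAnalysis Universe from a Configuration for writing."""
    import MDAnalysis as mda

    n = conf.n_atoms
    _, res_index = np.unique(conf.molecule_ids, return_inverse=True)
    n_res = res_index.max() + 1
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=res_index, trajectory=True
    )
    names = [l[:5] for l in conf.labels]
    u.add_TopologyAttr("names", names)
    res_labels = [""] * n_res
    for i, ri in enumerate(res_index):
        if not res_labels[ri]:
            lbl = conf.labels[i]
            res_labels[ri] = (resnames or {}).get(lbl, "MOL")
    u.add_TopologyAttr("resnames", res_labels)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.atoms.positions = conf.positions
    u.dimensions = [*conf.box, 90.0, 90.0, 90.0]
    return u


def write_gro(path: str | Path, frames: list[Configuration],
              resnames: dict[str, str] | None = None) -> None:
    """Write configurations as (multi-model) GRO via MDAnalysis (nm on disk)."""
    import MDAnalysis as mda

    path = Path(path)
    if len(frames) == 1:
        _as_universe(frames[0], resnames).atoms.write(str(path))
        return
    # one numbered file per frame: GRO has no multi-frame convention MDA writes
    for i, conf in enumerate(frames):
        _as_universe(conf, resnames).atoms.write(
            str(path.with_suffix(f".{i:04d}{path.suffix}"))
        )


def write_xyz(path: str | Path, frames: list[Configuration]) -> None:
    """Write an XYZ trajectory plus a side-channel box file (<path>.box)."""
    import MDAnalysis as mda

    path = Path(path)
    u = _as_universe(frames[0])
    with mda.Writer(str(path), n_atoms=frames[0].n_atoms) as w:
        for conf in frames:
            u.atoms.positions = conf.positions
            w.write(u.atoms)
    box_lines = ["# box edge lengths (A) per frame"]
    for conf in frames:
        box_lines.append(" ".join(f"{e:.4f}" for e in conf.box))
    path.with_suffix(path.suffix + ".box").write_text("\n".join(box_lines) + "\n")
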