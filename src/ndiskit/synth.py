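"""Synthetic inputs with known ground truth for every pipeline stage.

The generators stand in for force-field MD trajectories and diffractometer
output: ideal-gas and lattice configurations exercise the RDF estimator,
analytic g(r) profiles have closed-form or refined-quadrature transforms, the
planted complex emulates a dilute aqueous solution of a tetrahedral cation
and a planar aromatic with a face-on (or "headphone") binding geometry
planted at known distance and occupancy, and the noisy difference curve is a
smooth structure-factor-like function plus white noise of known sigma.

Molecules are rigid idealised shapes -- no force field, no water model: the
downstream stages test geometry and bookkeeping, not energetics.  Every
artifact is produced by its own seeded generator and records the seed and
the planted truth in its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Configuration, RadialDistribution

__all__ = [
    "GeneratorSpec",
    "generate",
    "ideal_gas",
    "cubic_lattice",
    "planted_complex",
    "analytic_rdf",
    "noisy_difference",
]

KINDS = ("ideal_gas", "lattice", "planted_complex", "analytic_rdf", "noisy_difference")


@dataclass
class GeneratorSpec:
    """Declarative request for one synthetic artifact."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; choose from {KINDS}")


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec to the matching generator function."""
    fns = {
        "ideal_gas": ideal_gas,
        "lattice": cubic_lattice,
        "planted_complex": planted_complex,
        "analytic_rdf": analytic_rdf,
        "noisy_difference": noisy_difference,
    }
    fn = fns[spec.kind]
    if spec.kind in ("ideal_gas", "planted_complex", "noisy_difference"):
        return fn(seed=spec.seed, **spec.params)
    return fn(**spec.params)


# ---------------------------------------------------------------------------
# configurations


def ideal_gas(
    n: int = 1000,
    box: float = 30.0,
    n_frames: int = 1,
    label: str = "X",
    seed: int = 0,
) -> list[Configuration]:
    """Uniformly random point particles: g(r) = 1 exactly in expectation."""
    if n <= 0 or n_frames <= 0:
        raise ValueError("n and n_frames must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        pos = rng.uniform(0.0, box, size=(n, 3))
        frames.append(
            Configuration(
                box=np.full(3, float(box)),
                labels=np.full(n, label),
                molecule_ids=np.arange(n),
                positions=pos,
            )
        )
    return frames


def cubic_lattice(
    n_per_side: int = 6, spacing: float = 4.0, label: str = "X"
) -> Configuration:
    """Simple cubic lattice: first RDF shells at a (6 neighbours) and a*sqrt(2) (12)."""
    if n_per_side < 2:
        raise ValueError("need at least 2 sites per side")
    idx = np.arange(n_per_side)
    grid = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    pos = (grid + 0.5) * spacing
    n = len(pos)
    return Configuration(
        box=np.full(3, n_per_side * spacing),
        labels=np.full(n, label),
        molecule_ids=np.arange(n),
        positions=pos,
    )


# rigid idealised molecules ---------------------------------------------------

RING_BOND = 1.39  # A, aromatic C-C
RING_CH = 1.08  # A, aromatic C-H
TMA_NC = 1.50  # A, N-C
TMA_CH = 1.09  # A, methyl C-H
WATER_OH = 0.9572  # A
WATER_HOH = np.deg2rad(104.52)


def _ring_template() -> tuple[np.ndarray, list[str]]:
    """Planar six-membered aromatic: heteroatom at +x, H on the five carbons."""
    angles = np.arange(6) * np.pi / 3.0
    heavy = RING_BOND * np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1)
    labels = ["N_ring"] + ["C_ring"] * 5
    coords = [heavy]
    for i in range(1, 6):
        # ring H radially outward from the carbon
        coords.append(heavy[i] * ((RING_BOND + RING_CH) / RING_BOND))
        labels.append("H_Py")
    return np.vstack([heavy] + coords[1:]), labels


def _tma_template() -> tuple[np.ndarray, list[str]]:
    """Tetramethylammonium: central N, 4 tetrahedral C, 12 methyl H."""
    t = 1.0 / np.sqrt(3.0)
    dirs = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    carbons = TMA_NC * dirs
    coords = [np.zeros(3)]
    labels = ["N_TMA"]
    for c_dir, c in zip(dirs, carbons):
        coords.append(c)
        labels.append("C_TMA")
        # three H staggered around the N-C axis, tetrahedral angle from it
        axis = c_dir
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, axis)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        for k in range(3):
            phi = 2.0 * np.pi * k / 3.0
            h_dir = (
                np.cos(np.deg2rad(180.0 - 109.47)) * axis
                + np.sin(np.deg2rad(180.0 - 109.47))
                * (np.cos(phi) * u + np.sin(phi) * v)
            )
            coords.append(c + TMA_CH * h_dir)
            labels.append("H_TMA")
    return np.asarray(coords), labels


#: direction of the first methyl carbon in the cation template
_TMA_C0_DIR = np.full(3, 1.0 / np.sqrt(3.0))


def _water_template() -> tuple[np.ndarray, list[str]]:
    h1 = WATER_OH * np.array([np.sin(WATER_HOH / 2), 0.0, np.cos(WATER_HOH / 2)])
    h2 = WATER_OH * np.array([-np.sin(WATER_HOH / 2), 0.0, np.cos(WATER_HOH / 2)])
    return np.vstack([np.zeros(3), h1, h2]), ["O_W", "H_W", "H_W"]


def planted_complex(
    n_aromatic: int = 10,
    n_cation: int = 10,
    n_water: int = 278,
    n_chloride: int = 10,
    box: float = 21.0,
    binding_distance: float = 4.0,
    binding_probability: float = 0.8,
    binding_mode: str = "face_on",
    jitter: float = 0.15,
    n_frames: int = 5,
    seed: int = 0,
) -> tuple[list[Configuration], dict]:
    """Dilute aqueous cation + aromatic solution with a planted binding geometry.

    Each aromatic ring independently hosts, with probability
    ``binding_probability``, one cation placed either on the ring normal at
    ``binding_distance`` ("face_on") or in-plane flanking the heteroatom
    direction at +/-60 deg ("headphone"), with isotropic Gaussian jitter.
    Unbound cations, waters and chlorides are placed uniformly.  The default
    sizes keep the solution stoichiometry of a 2-molal aqueous sample
    (about 27.75 waters per cation) at desk scale.

    Returns the frames and a ground-truth record (per-frame bound flags,
    planted distance and mode, the seed).
    """
    if binding_mode not in ("face_on", "headphone"):
        raise ValueError(f"unknown binding mode {binding_mode!r}")
    if not (0.0 <= binding_probability <= 1.0):
        raise ValueError("binding probability must be in [0, 1]")
    if min(n_aromatic, n_cation, n_water, n_chloride, n_frames) <= 0:
        raise ValueError("all counts must be positive")
    if n_cation < n_aromatic:
        raise ValueError("need at least one cation per aromatic for planting")

    rng = np.random.default_rng(seed)
    ring_xyz, ring_labels = _ring_template()
    tma_xyz, tma_labels = _tma_template()
    wat_xyz, wat_labels = _water_template()
    frames = []
    bound_record = []

    for _ in range(n_frames):
        labels: list[str] = []
        mol_ids: list[int] = []
        positions: list[np.ndarray] = []
        mol = 0

        def place(template, tmpl_labels, center, rot):
            nonlocal mol
            positions.append(rot.apply(template) + center)
            labels.extend(tmpl_labels)
            mol_ids.extend([mol] * len(tmpl_labels))
            mol += 1

        ring_centers = rng.uniform(0, box, size=(n_aromatic, 3))
        ring_rots = Rotation.random(n_aromatic, rng=rng)
        bound = rng.uniform(size=n_aromatic) < binding_probability
        for i in range(n_aromatic):
            place(ring_xyz, ring_labels, ring_centers[i], ring_rots[i])

        n_free = n_cation - int(bound.sum())
        placements = []
        for i in np.where(bound)[0]:
            rot = ring_rots[i]
            if binding_mode == "face_on":
                local = np.array([0.0, 0.0, rng.choice([-1.0, 1.0]) * binding_distance])
            else:
                side = rng.choice([-1.0, 1.0])
                ang = np.deg2rad(60.0) * side
                local = binding_distance * np.array([np.cos(ang), np.sin(ang), 0.0])
            site = ring_centers[i] + rot.apply(local) + rng.normal(0.0, jitter, size=3)
            # one methyl face points at the ring centre (the cation-pi contact
            # orientation), with a random spin about the contact axis
            toward = ring_centers[i] - site
            toward /= np.linalg.norm(toward)
            align, _ = Rotation.align_vectors(toward[None, :], _TMA_C0_DIR[None, :])
            spin = Rotation.from_rotvec(rng.uniform(0, 2 * np.pi) * toward)
            placements.append((site, spin * align))
        for site, rot in zip(
            rng.uniform(0, box, size=(n_free, 3)), Rotation.random(n_free, rng=rng)
        ):
            placements.append((site, rot))
        for site, rot in placements:
            place(tma_xyz, tma_labels, np.asarray(site), rot)

        for center, rot in zip(
            rng.uniform(0, box, size=(n_water, 3)), Rotation.random(n_water, rng=rng)
        ):
            place(wat_xyz, wat_labels, center, rot)
        for center in rng.uniform(0, box, size=(n_chloride, 3)):
            positions.append(center[None, :])
            labels.append("Cl")
            mol_ids.append(mol)
            mol += 1

        pos = np.vstack(positions) % box
        frames.append(
            Configuration(
                box=np.full(3, float(box)),
                labels=np.array(labels),
                molecule_ids=np.array(mol_ids),
                positions=pos,
            )
        )
        bound_record.append(bound.copy())

    truth = {
        "binding_distance": binding_distance,
        "binding_probability": binding_probability,
        "binding_mode": binding_mode,
        "jitter": jitter,
        "bound": bound_record,
        "seed": seed,
        "bound_fraction": float(np.mean([b.mean() for b in bound_record])),
    }
    return frames, truth


# ---------------------------------------------------------------------------
# analytic profiles and noisy curves


def analytic_rdf(
    profile: str = "gaussian_peak",
    r_max: float = 15.0,
    dr: float = 0.02,
    r0: float = 4.0,
    amplitude: float = 1.0,
    width2: float = 0.5,
    shell_area: float = 0.1,
    pair: tuple[str, str] = ("A", "B"),
    total_density: float = 0.1,
) -> RadialDistribution:
    """Analytic g(r) on a histogram grid: 'unity', 'gaussian_peak' or 'delta_shell'.

    gaussian_peak: g = 1 + amplitude * exp(-(r - r0)^2 / width2).
    delta_shell:   g = 1 everywhere except the single bin containing r0,
                   which carries area ``shell_area`` (g - 1 = area / dr there).
    """
    r = np.arange(dr / 2.0, r_max, dr)
    if profile == "unity":
        g = np.ones_like(r)
        truth: dict = {}
    elif profile == "gaussian_peak":
        g = 1.0 + amplitude * np.exp(-((r - r0) ** 2) / width2)
        truth = {"r0": r0, "amplitude": amplitude, "width2": width2}
    elif profile == "delta_shell":
        g = np.ones_like(r)
        i0 = int(np.argmin(np.abs(r - r0)))
        g[i0] += shell_area / dr
        truth = {"r0": float(r[i0]), "shell_area": shell_area, "bin": i0}
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return RadialDistribution(
        pair=pair,
        r=r,
        g=g,
        total_density=total_density,
        meta={"profile": profile, **truth},
    )


def smooth_difference_curve(Q: np.ndarray, amplitude: float = 0.5, r0: float = 3.5,
                            decay: float = 0.08) -> np.ndarray:
    """A structure-factor-like smooth curve: damped shell oscillation."""
    Q = np.asarray(Q, dtype=float)
    x = Q * r0
    return amplitude * np.where(x != 0, np.sin(x) / x, 1.0) * np.exp(-decay * Q**2) \
        + 0.2 * np.exp(-((Q - 2.0) ** 2) / 2.0)


def noisy_difference(
    truth_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    sigma: float = 0.037,
    n: int = 800,
    Q_min: float = 0.5,
    Q_max: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """A noisy "experimental" curve: smooth truth plus white noise of known sigma."""
    if n <= 0 or sigma < 0:
        raise ValueError("n must be positive and sigma non-negative")
    rng = np.random.default_rng(seed)
    Q = np.linspace(Q_min, Q_max, n)
    f = truth_fn if truth_fn is not None else smooth_difference_curve
    clean = f(Q)
    y = clean + rng.normal(0.0, sigma, size=n)
    return Q, y, {"sigma": sigma, "clean": clean, "seed": seed}
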