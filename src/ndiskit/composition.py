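"""Solution composition, atomic fractions, and NDIS difference-function weights.

Neutron diffraction with isotopic substitution (NDIS) isolates the pair
correlations of a substituted nucleus by subtracting the diffraction patterns
of chemically identical solutions that differ only in isotopic labelling.
The first-order difference is a weighted sum of Faber-Ziman partial structure
factors,

    dS(Q) = sum_X  A_X * (S_subX(Q) - 1),

where each prefactor A_X is fixed by the solution composition and the coherent
scattering lengths:

    A_X    = 2 * c_sub * c_X * (b_D - b_H) * b_X     (X != substituted class)
    A_self =     c_sub**2    * (b_D**2 - b_H**2)

with c the atomic fractions and b the coherent bound scattering lengths (fm);
coefficients are stored in millibarn (1 fm^2 = 10 mbarn).  For exchangeable
hydrogens (water hydrogens, hydroxyl hydrogens) b_X follows the solvent
isotope, which is what makes the D2O- and H2O-solvent weight sets differ, and
the difference of the two first-order functions -- the second-order difference
-- isolates the substituted-hydrogen / water-hydrogen correlation with weight
2 * c_sub * c_HW * (b_D - b_H)**2.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "ScatteringLengthTable",
    "AtomClass",
    "Species",
    "SolutionComposition",
    "PairWeight",
    "DifferenceWeights",
    "ChargeReport",
    "atomic_fractions",
    "difference_weights",
    "second_order_weight",
    "validate_charge_set",
    "tma_pyridine_composition",
    "FM2_TO_MBARN",
]

#: 1 fm^2 = 10 mbarn (1 barn = 100 fm^2, 1 mbarn = 0.1 fm^2)
FM2_TO_MBARN = 10.0

#: tolerance used for "terms cancel" checks, at the printed precision of weights
CANCEL_TOL_MBARN = 0.05


class ScatteringLengthTable:
    """Coherent bound neutron scattering lengths, keyed by element/isotope label.

    The packaged default carries natural-abundance coherent values
    (H = -3.739 fm, D = 6.671 fm, C = 6.646 fm, N = 9.36 fm, O = 5.803 fm,
    Cl = 9.577 fm, ...); a user table in the same two-column format can
    override or extend it.
    """

    def __init__(self, entries: Mapping[str, float]):
        for label, b in entries.items():
            if not _finite(b):
                raise ValueError(f"non-finite scattering length for {label!r}")
        self.entries = dict(entries)

    def __getitem__(self, label: str) -> float:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(
                f"no scattering length for element/isotope {label!r}"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    @classmethod
    def from_file(cls, path: str | Path) -> "ScatteringLengthTable":
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, value = line.split()[:2]
            entries[label] = float(value)
        return cls(entries)

    @classmethod
    def default(cls) -> "ScatteringLengthTable":
        """The packaged Sears-compilation table."""
        ref = importlib.resources.files("ndiskit.data") / "scattering_lengths.tsv"
        entries = {}
        for line in ref.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, value = line.split()[:2]
            entries[label] = float(value)
        return cls(entries)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class AtomClass:
    """One correlation partner: a set of chemically equivalent atoms.

    ``substitutable`` marks the class whose H/D labelling is varied between
    samples (necessarily hydrogen).  ``exchangeable`` hydrogens trade protons
    with the solvent and therefore carry the solvent's isotope; non-exchangeable
    hydrogens keep the fixed ``isotope`` label (default: the element itself).
    """

    label: str
    element: str
    exchangeable: bool = False
    substitutable: bool = False
    isotope: str | None = None

    def __post_init__(self):
        if self.substitutable and self.element != "H":
            raise ValueError(
                f"substitutable class {self.label!r} must be hydrogen, got "
                f"element {self.element!r}"
            )


@dataclass(frozen=True)
class Species:
    """A molecular species with its mole ratio and per-formula-unit atom counts."""

    name: str
    mole_ratio: float
    atoms: Mapping[str, int]

    def __post_init__(self):
        if self.mole_ratio <= 0:
            raise ValueError(f"species {self.name!r}: mole ratio must be > 0")
        for cls, n in self.atoms.items():
            if not isinstance(n, int) or n <= 0:
                raise ValueError(
                    f"species {self.name!r}: atom count for {cls!r} must be a "
                    f"positive integer"
                )


@dataclass
class SolutionComposition:
    """A solution as mole ratios of species plus atom-class definitions."""

    species: list[Species]
    classes: dict[str, AtomClass]
    solvent_isotope: str = "D2O"
    temperature: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.solvent_isotope not in ("H2O", "D2O"):
            raise ValueError(
                f"solvent_isotope must be 'H2O' or 'D2O', got {self.solvent_isotope!r}"
            )
        for sp in self.species:
            for cls in sp.atoms:
                if cls not in self.classes:
                    raise ValueError(
                        f"species {sp.name!r} references undefined atom class {cls!r}"
                    )

    def with_solvent(self, solvent_isotope: str) -> "SolutionComposition":
        """The chemically identical composition in the other solvent."""
        return SolutionComposition(
            species=self.species,
            classes=self.classes,
            solvent_isotope=solvent_isotope,
            temperature=self.temperature,
            label=self.label,
        )

    def fingerprint(self) -> tuple:
        """Solvent-independent identity used to check weight-set compatibility."""
        return tuple(
            (sp.name, sp.mole_ratio, tuple(sorted(sp.atoms.items())))
            for sp in self.species
        )


def atomic_fractions(comp: SolutionComposition) -> dict[str, float]:
    """Atomic fraction of every atom class: (mole ratio x count) / total atom moles."""
    if not comp.species:
        raise ValueError("no species in composition")
    moles: dict[str, float] = {}
    for sp in comp.species:
        for cls, n in sp.atoms.items():
            moles[cls] = moles.get(cls, 0.0) + sp.mole_ratio * n
    total = sum(moles.values())
    if total <= 0:
        raise ValueError("composition has zero total atoms")
    return {cls: m / total for cls, m in moles.items()}


@dataclass(frozen=True)
class PairWeight:
    """Coefficient (mbarn) multiplying one partial structure factor.

    Each partial enters a difference function as S - 1, so the constant
    subtracted from the weighted sum of S values equals the coefficient itself.
    """

    pair: tuple[str, str]
    coefficient: float

    @property
    def constant_contribution(self) -> float:
        return self.coefficient


@dataclass
class DifferenceWeights:
    """The full weight set of one first-order difference function."""

    weights: list[PairWeight]
    solvent_isotope: str
    substituted: str
    solvent_hydrogen: str | None
    composition_fingerprint: tuple = field(default_factory=tuple)

    @property
    def constant(self) -> float:
        """Constant term (mbarn); equals the coefficient sum by construction."""
        return sum(w.coefficient for w in self.weights)

    def coefficient(self, partner: str) -> float:
        for w in self.weights:
            if w.pair[1] == partner:
                return w.coefficient
        raise KeyError(f"no weight for partner class {partner!r}")

    def render(self, name: str = "dS(Q)") -> str:
        """Human-readable difference equation with coefficients to one decimal."""
        terms = []
        for i, w in enumerate(self.weights):
            c = w.coefficient
            sign = "-" if c < 0 else ("+" if i else "")
            terms.append(f"{sign}{abs(c):.1f}*S[{w.pair[0]},{w.pair[1]}](Q)")
        return f"{name} = " + " ".join(terms) + f" - {self.constant:.1f}"


def _effective_b(
    cls: AtomClass, table: ScatteringLengthTable, solvent_isotope: str
) -> float:
    """Scattering length of a partner class, honouring exchange with the solvent."""
    if cls.element == "H":
        if cls.exchangeable:
            return table["D"] if solvent_isotope == "D2O" else table["H"]
        return table[cls.isotope or "H"]
    return table[cls.element]


def difference_weights(
    comp: SolutionComposition,
    table: ScatteringLengthTable | None = None,
    substituted: str = "H_TMA",
) -> DifferenceWeights:
    """Exact prefactors of the first-order difference for one solvent isotope.

    Parameters
    ----------
    comp
        The solution; its ``solvent_isotope`` selects which weight set is built.
    table
        Scattering lengths; the packaged table by default.
    substituted
        Label of the atom class whose H/D labelling differs between samples.
    """
    if table is None:
        table = ScatteringLengthTable.default()
    if substituted not in comp.classes:
        raise ValueError(f"unknown substituted class {substituted!r}")
    sub = comp.classes[substituted]
    if not sub.substitutable:
        raise ValueError(f"class {substituted!r} is not marked substitutable")

    fractions = atomic_fractions(comp)
    c_sub = fractions.get(substituted, 0.0)
    b_H, b_D = table["H"], table["D"]
    contrast = b_D - b_H

    weights: list[PairWeight] = []
    solvent_hydrogen = None
    for label, c_x in fractions.items():
        cls = comp.classes[label]
        if label == substituted:
            coeff = c_sub**2 * (b_D**2 - b_H**2) * FM2_TO_MBARN
        else:
            b_x = _effective_b(cls, table, comp.solvent_isotope)
            coeff = 2.0 * c_sub * c_x * contrast * b_x * FM2_TO_MBARN
        if cls.element == "H" and cls.exchangeable:
            solvent_hydrogen = label
        weights.append(PairWeight(pair=(substituted, label), coefficient=coeff))

    # deterministic order: largest coefficient magnitude first, self term last
    weights.sort(key=lambda w: (w.pair[1] == substituted, -abs(w.coefficient)))
    return DifferenceWeights(
        weights=weights,
        solvent_isotope=comp.solvent_isotope,
        substituted=substituted,
        solvent_hydrogen=solvent_hydrogen,
        composition_fingerprint=comp.fingerprint(),
    )


def second_order_weight(
    w_d2o: DifferenceWeights, w_h2o: DifferenceWeights
) -> float:
    """Weight (mbarn) multiplying (S_sub,HW - 1) in the second-order difference.

    All partner terms except the solvent-hydrogen one must cancel between the
    two weight sets; a residual above 0.05 mbarn means the compositions differ.
    """
    if w_d2o.composition_fingerprint != w_h2o.composition_fingerprint:
        raise ValueError("compositions differ: weight sets are not comparable")
    hw = w_d2o.solvent_hydrogen
    if hw is None or hw != w_h2o.solvent_hydrogen:
        raise ValueError("weight sets do not share a solvent-hydrogen class")
    partners_d = {w.pair[1]: w.coefficient for w in w_d2o.weights}
    partners_h = {w.pair[1]: w.coefficient for w in w_h2o.weights}
    if set(partners_d) != set(partners_h):
        raise ValueError("compositions differ: partner classes do not match")
    for partner in partners_d:
        if partner == hw:
            continue
        if abs(partners_d[partner] - partners_h[partner]) > CANCEL_TOL_MBARN:
            raise ValueError(
                f"compositions differ: {partner!r} term does not cancel "
                f"({partners_d[partner]:.3f} vs {partners_h[partner]:.3f} mbarn)"
            )
    return partners_d[hw] - partners_h[hw]


@dataclass(frozen=True)
class ChargeReport:
    total: float
    expected: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return f"total charge {self.total:+.4f} (expected {self.expected:+.4f}): {status}"


def validate_charge_set(
    charges: Mapping[str, float],
    counts: Mapping[str, int],
    expected_total: float,
    tol: float = 1e-6,
) -> ChargeReport:
    """Check that per-atom partial charges sum to the expected molecular charge.

    Used to book-keep electronic-continuum-corrected (ECC) charge sets, where
    ionic charges are uniformly scaled (by ~0.75 in water) to embed electronic
    polarization in a nonpolarizable force field.
    """
    for cls, n in counts.items():
        if n <= 0:
            raise ValueError(f"count for {cls!r} must be positive")
        if cls not in charges:
            raise ValueError(f"no charge given for atom class {cls!r}")
    total = sum(charges[cls] * n for cls, n in counts.items())
    return ChargeReport(
        total=total, expected=expected_total, passed=abs(total - expected_total) <= tol
    )


def tma_pyridine_composition(
    solvent_isotope: str = "D2O",
    water_ratio: float = 55.508,
    tma_ratio: float = 2.0,
    pyridine_ratio: float = 2.0,
) -> SolutionComposition:
    """The 2 m TMACl + 2 m pyridine aqueous solution (mole ratios per kg water).

    Tetramethylammonium hydrogens (12 per cation, non-exchangeable) are the
    substituted class; pyridine ring hydrogens are non-exchangeable protons;
    water hydrogens follow the solvent isotope.  All carbons and all nitrogens
    are lumped into single classes, mirroring the single substituted-H/C and
    substituted-H/N correlation terms the measurement can resolve.
    """
    classes = {
        "H_TMA": AtomClass("H_TMA", "H", exchangeable=False, substitutable=True),
        "H_Py": AtomClass("H_Py", "H", exchangeable=False, isotope="H"),
        "H_W": AtomClass("H_W", "H", exchangeable=True),
        "O": AtomClass("O", "O"),
        "C": AtomClass("C", "C"),
        "N": AtomClass("N", "N"),
        "Cl": AtomClass("Cl", "Cl"),
    }
    species = [
        Species("water", water_ratio, {"H_W": 2, "O": 1}),
        Species("TMA", tma_ratio, {"N": 1, "C": 4, "H_TMA": 12}),
        Species("chloride", tma_ratio, {"Cl": 1}),
        Species("pyridine", pyridine_ratio, {"C": 5, "N": 1, "H_Py": 5}),
    ]
    return SolutionComposition(
        species=species,
        classes=classes,
        solvent_isotope=solvent_isotope,
        temperature=296.15,
        label="2 m TMACl + 2 m pyridine",
    )
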