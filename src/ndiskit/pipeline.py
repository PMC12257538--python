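"""Assembly of first- and second-order NDIS difference functions.

A first-order difference is the weighted sum of partial structure factors,
each entering as (S - 1) so that the function decays to zero at large Q.  The
second-order difference (D2O-solvent minus H2O-solvent) cancels every term
except the substituted-hydrogen / water-hydrogen one; dividing by its weight
and adding 1 recovers that single partial.  A flat second-order difference on
experimental input is the standard internal-consistency check that the
inelasticity (Placzek) background has cancelled between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import DifferenceWeights
from .structure import PartialStructureFactor

__all__ = [
    "DifferenceFunction",
    "FlatnessReport",
    "assemble_difference",
    "second_order",
    "flatness_check",
]

KINDS = ("first_order_D2O", "first_order_H2O", "second_order")


@dataclass
class DifferenceFunction:
    """A difference function in mbarn on a shared Q grid, with provenance."""

    kind: str
    Q: np.ndarray  # A^-1
    values: np.ndarray  # mbarn
    provenance: dict = field(default_factory=dict)
    extracted_S_HW: np.ndarray | None = None  # second_order only

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.Q = np.asarray(self.Q, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.Q.shape != self.values.shape:
            raise ValueError("Q and values must match in shape")


def assemble_difference(
    partials: dict[tuple[str, str], PartialStructureFactor],
    w: DifferenceWeights,
) -> DifferenceFunction:
    """dS(Q) = sum_i A_i * (S_i(Q) - 1) from partials and a weight set."""
    Q = None
    total = None
    for pw in w.weights:
        if pw.pair not in partials:
            raise KeyError(f"no partial structure factor for pair {pw.pair}")
        sq = partials[pw.pair]
        if Q is None:
            Q = sq.Q
            total = np.zeros_like(Q)
        elif sq.Q.shape != Q.shape or not np.allclose(sq.Q, Q):
            raise ValueError(f"Q-grid mismatch for pair {pw.pair}")
        total += pw.coefficient * (sq.S - 1.0)
    kind = "first_order_D2O" if w.solvent_isotope == "D2O" else "first_order_H2O"
    return DifferenceFunction(
        kind=kind,
        Q=Q,
        values=total,
        provenance={
            "weights": {pw.pair: pw.coefficient for pw in w.weights},
            "constant": w.constant,
            "solvent_isotope": w.solvent_isotope,
        },
    )


def second_order(
    d_d2o: DifferenceFunction,
    d_h2o: DifferenceFunction,
    w2: float,
) -> DifferenceFunction:
    """ddS(Q) = dS_D2O(Q) - dS_H2O(Q); also extracts S_HW = ddS/w2 + 1."""
    if d_d2o.kind != "first_order_D2O" or d_h2o.kind != "first_order_H2O":
        raise ValueError(
            f"kind mismatch: expected (first_order_D2O, first_order_H2O), got "
            f"({d_d2o.kind}, {d_h2o.kind})"
        )
    if d_d2o.Q.shape != d_h2o.Q.shape or not np.allclose(d_d2o.Q, d_h2o.Q):
        raise ValueError("Q-grid mismatch between the two first-order differences")
    values = d_d2o.values - d_h2o.values
    return DifferenceFunction(
        kind="second_order",
        Q=d_d2o.Q,
        values=values,
        provenance={"hw_weight_mbarn": w2},
        extracted_S_HW=values / w2 + 1.0,
    )


@dataclass(frozen=True)
class FlatnessReport:
    mean: float
    slope: float  # per A^-1, ordinary least squares
    rms: float  # rms deviation about the mean
    n_points: int
    Q_min: float
    threshold: float
    passed: bool

    def __str__(self) -> str:
        status = "flat" if self.passed else "NOT flat"
        return (
            f"Q >= {self.Q_min:g}: mean {self.mean:.4g}, slope {self.slope:.4g}, "
            f"rms {self.rms:.4g} vs threshold {self.threshold:g} -> {status}"
        )


def flatness_check(
    d: DifferenceFunction, Q_min: float = 0.5, threshold: float = 0.05
) -> FlatnessReport:
    """Report mean, straight-line slope and rms deviation over Q >= Q_min.

    Passing (rms below threshold) on an experimental second-order difference
    indicates no detectable residual background, i.e. the isotopically
    substituted solutions were chemically identical.
    """
    mask = d.Q >= Q_min
    if int(mask.sum()) < 10:
        raise ValueError(f"fewer than 10 points above Q_min={Q_min:g}")
    q = d.Q[mask]
    y = d.values[mask]
    slope, intercept = np.polyfit(q, y, 1)
    mean = float(np.mean(y))
    rms = float(np.sqrt(np.mean((y - mean) ** 2)))
    return FlatnessReport(
        mean=mean,
        slope=float(slope),
        rms=rms,
        n_points=int(mask.sum()),
        Q_min=Q_min,
        threshold=threshold,
        passed=rms <= threshold,
    )
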