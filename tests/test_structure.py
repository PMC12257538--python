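"""RDF estimation and the Fourier-Bessel transform pair."""

import numpy as np
import pytest

from ndiskit import synth
from ndiskit.structure import (
    Configuration,
    RadialDistribution,
    compute_rdf,
    rdf_to_sq,
    sq_to_rdf,
)


def _pair_conf(d=5.0, box=100.0):
    return Configuration(
        box=np.full(3, box),
        labels=np.array(["A", "B"]),
        molecule_ids=np.array([0, 1]),
        positions=np.array([[10.0, 10.0, 10.0], [10.0 + d, 10.0, 10.0]]),
    )


def test_two_particles_single_bin():
    rdf = compute_rdf([_pair_conf(d=5.0)], ("A", "B"), bin_width=0.1, r_max=20.0)
    nonzero = np.nonzero(rdf.g)[0]
    assert len(nonzero) == 1
    assert abs(rdf.r[nonzero[0]] - 5.0) <= 0.05


def test_minimum_image_distance():
    # separation 95 in a 100 A box is 5 A by minimum image
    rdf = compute_rdf([_pair_conf(d=95.0)], ("A", "B"), bin_width=0.1, r_max=20.0)
    nonzero = np.nonzero(rdf.g)[0]
    assert abs(rdf.r[nonzero[0]] - 5.0) <= 0.05


def test_intramolecular_pairs_excluded():
    conf = _pair_conf(d=5.0)
    conf.molecule_ids = np.array([7, 7])
    rdf = compute_rdf([conf], ("A", "B"), bin_width=0.1, r_max=20.0)
    assert np.all(rdf.g == 0.0)
    rdf2 = compute_rdf([conf], ("A", "B"), bin_width=0.1, r_max=20.0,
                       exclude_intramolecular=False)
    assert np.any(rdf2.g > 0.0)


def test_ideal_gas_is_flat():
    """Uniform particles: g = 1 within 3-sigma Poisson bands, <g> within 1%."""
    frames = synth.ideal_gas(n=1000, box=30.0, n_frames=50, seed=5)
    rdf = compute_rdf(frames, ("X", "X"), bin_width=0.1, r_max=15.0)
    rho = 1000 / 30.0**3
    # expected pair counts per bin over all frames
    expected = 4 * np.pi * rdf.r**2 * 0.1 * rho * 1000 * 50
    mask = rdf.r >= 2.0
    sigma = 3.0 * np.sqrt(2.0 / expected[mask])  # ordered pairs double-count
    assert np.all(np.abs(rdf.g[mask] - 1.0) <= np.maximum(sigma, 0.05))
    assert abs(rdf.g[mask].mean() - 1.0) < 0.01


def test_lattice_shell_coordination():
    """Simple cubic lattice: shells at a and a*sqrt(2) hold 6 and 12 neighbours."""
    a = 4.0
    conf = synth.cubic_lattice(n_per_side=6, spacing=a)
    rdf = compute_rdf([conf], ("X", "X"), bin_width=0.05, r_max=a * 1.6)
    rho = conf.n_atoms / conf.volume
    shell_counts = 4 * np.pi * rdf.r**2 * 0.05 * rho * rdf.g
    first = shell_counts[(rdf.r > 0.9 * a) & (rdf.r < 1.1 * a)].sum()
    second = shell_counts[(rdf.r > 1.3 * a) & (rdf.r < 1.5 * a)].sum()
    assert first == pytest.approx(6.0, rel=1e-6)
    assert second == pytest.approx(12.0, rel=1e-6)


def test_rdf_preconditions():
    conf = _pair_conf()
    with pytest.raises(ValueError, match="half"):
        compute_rdf([conf], ("A", "B"), bin_width=0.1, r_max=60.0)
    with pytest.raises(ValueError, match="absent"):
        compute_rdf([conf], ("A", "Z"), bin_width=0.1, r_max=20.0)
    with pytest.raises(ValueError, match="bin width"):
        compute_rdf([conf], ("A", "B"), bin_width=0.0, r_max=20.0)


# --- transforms -------------------------------------------------------------


def test_unity_g_gives_unity_s():
    rdf = synth.analytic_rdf("unity")
    sq = rdf_to_sq(rdf, Q=np.arange(0.5, 25, 0.05))
    assert np.allclose(sq.S, 1.0, atol=1e-12)


def test_delta_shell_closed_form():
    """A single-bin shell transforms exactly to its sinc closed form."""
    rdf = synth.analytic_rdf("delta_shell", r0=4.0, shell_area=0.1)
    Q = np.arange(0.1, 25, 0.05)
    sq = rdf_to_sq(rdf, Q=Q)
    r0, area = rdf.meta["r0"], rdf.meta["shell_area"]
    expected = 1 + 4 * np.pi * rdf.total_density * r0**2 * area * np.sin(Q * r0) / (Q * r0)
    assert np.max(np.abs(sq.S - expected)) < 1e-6


def test_gaussian_peak_vs_refined_quadrature():
    """Histogram-grid transform matches a 10x finer quadrature to 1e-4."""
    coarse = synth.analytic_rdf("gaussian_peak", dr=0.02)
    fine = synth.analytic_rdf("gaussian_peak", dr=0.002)
    Q = np.arange(0.5, 25, 0.1)
    s_coarse = rdf_to_sq(coarse, Q=Q).S
    s_fine = rdf_to_sq(fine, Q=Q).S
    assert np.max(np.abs(s_coarse - s_fine)) < 1e-4


def test_transform_matches_direct_sum_oracle():
    """The vectorised transform equals an explicit per-bin loop to 1e-10."""
    rdf = synth.analytic_rdf("gaussian_peak", r_max=10.0, dr=0.05)
    Q = np.arange(0.5, 20, 0.5)
    S = rdf_to_sq(rdf, Q=Q).S
    rho0 = rdf.total_density
    dr = rdf.bin_width
    for iq, q in enumerate(Q):
        acc = 0.0
        for r, g in zip(rdf.r, rdf.g):
            acc += r**2 * (g - 1.0) * np.sin(q * r) / (q * r) * dr
        expected = 1.0 + 4.0 * np.pi * rho0 * acc
        assert S[iq] == pytest.approx(expected, rel=1e-10, abs=1e-10)


def test_transform_linearity():
    base = synth.analytic_rdf("gaussian_peak", amplitude=0.5)
    double = synth.analytic_rdf("gaussian_peak", amplitude=1.0)
    Q = np.arange(0.5, 25, 0.05)
    s1 = rdf_to_sq(base, Q=Q).S
    s2 = rdf_to_sq(double, Q=Q).S
    assert np.allclose(s2 - 1.0, 2.0 * (s1 - 1.0), atol=1e-10)


def test_shell_form_factor_extremum():
    """First interior S(Q) maximum of a planted shell sits near 7.725 / r0."""
    r0 = 4.0
    rdf = synth.analytic_rdf("delta_shell", r0=r0, shell_area=0.1)
    Q = np.arange(0.5, 25, 0.025)
    S = rdf_to_sq(rdf, Q=Q).S
    interior_max = np.nonzero((S[1:-1] > S[:-2]) & (S[1:-1] > S[2:]))[0] + 1
    assert len(interior_max) > 0
    assert abs(Q[interior_max[0]] - 7.725 / r0) <= 0.025 + 1e-9


def test_q_grid_validation():
    rdf = synth.analytic_rdf("unity")
    with pytest.raises(ValueError, match="Q"):
        rdf_to_sq(rdf, Q=np.array([0.0, 0.5, 1.0]))
    # the sinc limit handles Q=0 only on request
    s = rdf_to_sq(rdf, Q=np.array([0.0, 0.5]), allow_q0=True)
    assert np.isfinite(s.S).all()


def test_lorch_window_damps_termination_ripple():
    rdf = synth.analytic_rdf("delta_shell", r0=4.0, shell_area=0.2, r_max=8.0)
    Q = np.arange(0.5, 25, 0.05)
    plain = rdf_to_sq(rdf, Q=Q, window="none").S
    lorch = rdf_to_sq(rdf, Q=Q, window="Lorch").S
    # the taper reduces the high-Q oscillation amplitude
    tail = Q > 15
    assert np.abs(lorch[tail] - 1).max() < np.abs(plain[tail] - 1).max()


def test_round_trip_g_to_s_to_g():
    """g -> S -> g reproduces a smooth profile within 2% away from r < 1 A."""
    rdf = synth.analytic_rdf("gaussian_peak")
    Q = np.arange(0.025, 40, 0.025)
    sq = rdf_to_sq(rdf, Q=Q)
    back = sq_to_rdf(sq, rho0=rdf.total_density, r=rdf.r)
    mask = rdf.r >= 1.0
    assert np.max(np.abs(back.g[mask] - rdf.g[mask])) < 0.02


def test_unity_s_round_trip_and_errors():
    sq = rdf_to_sq(synth.analytic_rdf("unity"), Q=np.arange(0.05, 30, 0.05))
    back = sq_to_rdf(sq, rho0=0.1, r=np.arange(0.5, 10, 0.1))
    assert np.allclose(back.g, 1.0, atol=1e-10)
    with pytest.raises(ValueError, match="empty"):
        sq_to_rdf(sq, rho0=0.1, r=np.array([]))


def test_truncated_q_range_flagged():
    sq = rdf_to_sq(synth.analytic_rdf("gaussian_peak"), Q=np.arange(0.05, 10, 0.05))
    with pytest.warns(UserWarning, match="truncated"):
        back = sq_to_rdf(sq, rho0=0.1, r=np.arange(1, 10, 0.1))
    assert back.meta.get("truncated_Q")


def test_nonuniform_tail_warns():
    rdf = synth.analytic_rdf("gaussian_peak", r0=14.0, r_max=15.0)
    with pytest.warns(UserWarning, match="tail"):
        rdf_to_sq(rdf, Q=np.arange(0.5, 10, 0.1))


def test_configuration_validation():
    with pytest.raises(ValueError, match="box"):
        Configuration(box=np.array([10.0, -1.0, 10.0]), labels=np.array(["A"]),
                      molecule_ids=np.array([0]), positions=np.zeros((1, 3)))
    with pytest.raises(ValueError, match="increasing"):
        RadialDistribution(pair=("A", "B"), r=np.array([1.0, 0.5]),
                           g=np.array([1.0, 1.0]))
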