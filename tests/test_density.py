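"""Superposition, density-map accumulation, and binding-geometry reports."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ndiskit import synth
from ndiskit.density import (
    DensityGrid,
    ReferenceFrame,
    accumulate,
    geometry_report,
    superpose,
    write_cube,
    write_opendx,
)


@pytest.fixture(scope="module")
def hexagon():
    return ReferenceFrame.hexagonal_ring()


def test_superpose_identity(hexagon):
    R, t, rmsd = superpose(hexagon.template, hexagon)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(R, np.eye(3), atol=1e-10)
    assert np.allclose(t, 0.0, atol=1e-12)


def test_superpose_recovers_rotation(hexagon):
    rot = Rotation.from_euler("z", 90, degrees=True)
    mobile = rot.apply(hexagon.template) + np.array([3.0, -1.0, 2.0])
    R, t, rmsd = superpose(mobile, hexagon)
    assert rmsd < 1e-10
    assert np.allclose(R, rot.inv().as_matrix(), atol=1e-8)
    assert np.allclose(R @ (mobile - t).T, hexagon.template.T, atol=1e-8)


def test_superpose_matches_brute_force_on_jittered_atoms(hexagon):
    rng = np.random.default_rng(8)
    rot = Rotation.random(rng=rng)
    mobile = rot.apply(hexagon.template + rng.normal(0, 0.1, (6, 3)))
    _, _, rmsd = superpose(mobile, hexagon)

    centred = mobile - mobile.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((centred @ R.T - hexagon.template) ** 2, axis=1)))

    best = min(
        minimize(objective, x0, method="Nelder-Mead",
                 options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}).fun
        for x0 in [np.zeros(3), rng.normal(size=3), rot.inv().as_rotvec()]
    )
    assert rmsd == pytest.approx(best, abs=1e-6)


def test_superpose_rejects_degenerate_input(hexagon):
    line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
    with pytest.raises(ValueError, match="collinear"):
        superpose(line + 1.0, ReferenceFrame(line - line.mean(axis=0)))
    with pytest.raises(ValueError, match="mismatch"):
        superpose(np.zeros((4, 3)), hexagon)


def test_reference_frame_canonicalisation():
    """An arbitrarily rotated ring canonicalises to xy-plane, heteroatom on +x."""
    ring = ReferenceFrame.hexagonal_ring().template
    rot = Rotation.from_euler("xyz", [30, 70, -10], degrees=True)
    frame = ReferenceFrame.from_template(rot.apply(ring) + 5.0)
    assert np.allclose(frame.template[:, 2], 0.0, atol=1e-8)
    assert frame.template[0, 0] > 0
    assert frame.template[0, 1] == pytest.approx(0.0, abs=1e-8)


def test_uniform_targets_give_flat_map():
    """Unbound cations are uniform: far-field normalised density is ~1."""
    frames, _ = synth.planted_complex(
        n_frames=120, n_water=20, binding_probability=0.0, seed=21
    )
    grid = accumulate(frames, ["N_ring", "C_ring"], "C_TMA")
    assert grid.shell_mean(6.0, 8.0) == pytest.approx(1.0, abs=0.05)


def test_rotation_invariance_of_map():
    """Rigidly rotating solute + targets leaves the aligned map unchanged."""
    from ndiskit.structure import Configuration

    rng = np.random.default_rng(4)
    ring = ReferenceFrame.hexagonal_ring().template + 50.0
    targets = rng.uniform(42.0, 58.0, size=(200, 3))
    labels = np.array(["R"] * 6 + ["T"] * 200)
    mols = np.array([0] * 6 + list(range(1, 201)))

    def conf(points):
        return Configuration(box=np.full(3, 100.0), labels=labels,
                             molecule_ids=mols, positions=points)

    base = np.vstack([ring, targets])
    rot = Rotation.random(rng=rng)
    pivot = ring.mean(axis=0)
    rotated = rot.apply(base - pivot) + pivot

    g1 = accumulate([conf(base)], ["R"], "T")
    g2 = accumulate([conf(rotated)], ["R"], "T")
    assert np.array_equal(g1.counts, g2.counts)


def test_count_conservation():
    """Every target inside the grid extent is binned exactly once."""
    frames, _ = synth.planted_complex(
        n_aromatic=2, n_cation=2, n_water=5, n_chloride=2,
        box=9.0, n_frames=3, seed=6,
    )
    grid = accumulate(frames, ["N_ring", "C_ring"], "C_TMA", extent=8.0)
    n_targets = np.sum(frames[0].labels == "C_TMA")
    # box diagonal/2 = 7.8 A < 8 A extent: nothing can fall outside
    assert grid.counts.sum() == grid.n_accumulations * n_targets


def test_face_on_binding_geometry():
    """Planted face-on cations put the density maximum on the ring normal."""
    frames, truth = synth.planted_complex(n_frames=1600, n_water=20, seed=13)
    grid = accumulate(frames, ["N_ring", "C_ring"], "C_TMA")
    rep = geometry_report(grid, level=2.3)
    px, py, pz = rep.peak_position
    assert np.hypot(px, py) < 1.0  # on the normal axis
    # peak within the methyl-carbon shell around the planted cation centre
    # (N-C bond 1.5 A, plus jitter and voxel width)
    d = truth["binding_distance"]
    assert d - 2.0 <= abs(pz) <= d + 2.0
    assert rep.axial_fraction > 0.5


def test_headphone_binding_geometry():
    """In-plane flanking cations leave the normal axis nearly empty."""
    frames, _ = synth.planted_complex(
        n_frames=1600, n_water=20, binding_mode="headphone", seed=14
    )
    grid = accumulate(frames, ["N_ring", "C_ring"], "C_TMA")
    rep = geometry_report(grid, level=2.3)
    assert rep.axial_fraction < 0.2
    px, py, pz = rep.peak_position
    assert np.hypot(px, py) > 2.0  # maxima off-axis
    # on-axis density stays near bulk
    x, yv, z = grid.voxel_centers()
    axis = (np.hypot(x, yv) < 1.0) & (np.abs(z) > 2.0) & (np.abs(z) < 6.0)
    assert grid.normalized[axis].mean() < 1.5


def test_geometry_report_flat_grid():
    grid = DensityGrid(origin=np.full(3, -4.0), spacing=0.5,
                       counts=np.ones((16, 16, 16)), n_accumulations=8,
                       bulk_density=1.0 / (0.5**3 * 8))
    rep = geometry_report(grid, level=2.3)
    assert rep.n_voxels == 0
    assert rep.peak_position is None
    rep2 = geometry_report(grid, level=0.5)
    assert rep2.n_voxels == 16**3


def test_accumulate_input_validation():
    frames, _ = synth.planted_complex(n_frames=1, n_water=5, seed=1)
    with pytest.raises(ValueError, match="absent"):
        accumulate(frames, ["N_ring", "C_ring"], "NOPE")
    with pytest.raises(ValueError, match="alignment"):
        accumulate(frames, ["NOPE"], "C_TMA")


def test_volume_writers_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    counts = rng.poisson(5.0, size=(6, 6, 6)).astype(float)
    grid = DensityGrid(origin=np.full(3, -1.5), spacing=0.5, counts=counts,
                       n_accumulations=10, bulk_density=0.4)
    dx = tmp_path / "map.dx"
    cube = tmp_path / "map.cube"
    write_opendx(grid, dx)
    write_cube(grid, cube, frame=ReferenceFrame.hexagonal_ring())

    # OpenDX: parse the data section back and compare
    lines = dx.read_text().splitlines()
    start = next(i for i, l in enumerate(lines) if "data follows" in l) + 1
    vals = []
    for l in lines[start:]:
        if l.startswith("attribute"):
            break
        vals.extend(float(v) for v in l.split())
    assert np.allclose(np.array(vals).reshape(6, 6, 6), grid.normalized, rtol=1e-5)

    # cube: natoms header and value count
    cube_lines = cube.read_text().splitlines()
    assert int(cube_lines[2].split()[0]) == 6
    data_vals = [v for l in cube_lines[6 + 6:] for v in l.split()]
    assert len(data_vals) == 6**3
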