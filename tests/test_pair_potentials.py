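"""Steric distances, table lookup semantics and FE pair energies."""

import numpy as np
import pytest

from mscl_lattice.meshing import MeshOptions
from mscl_lattice.pair_potentials import (
    OverlapError,
    PairTable,
    build_pair_table,
    min_distance,
    pair_energy,
)
from mscl_lattice.shapes import ProteinShape

from conftest import make_toy_table

CLEAR = 0.5


def test_min_distance_cylinders_closed_form():
    a = ProteinShape(symmetry_order=0, radius=2.0)
    b = ProteinShape(symmetry_order=0, radius=1.5)
    d = min_distance(a, b, 0.0, 0.0, clearance=CLEAR)
    assert d == pytest.approx(2.0 + 1.5 + CLEAR, abs=2e-3)


def test_min_distance_orientation_dependence(tet):
    tip_tip = min_distance(tet, tet, 0.0, 0.0, clearance=CLEAR)
    face_face = min_distance(tet, tet, np.pi / 4, np.pi / 4, clearance=CLEAR)
    assert tip_tip > face_face


def test_min_distance_swap_symmetry(tet, pent):
    d1 = min_distance(tet, pent, 0.3, 0.9, clearance=CLEAR)
    d2 = min_distance(pent, tet, 0.9 + np.pi, 0.3 + np.pi, clearance=CLEAR)
    assert d1 == pytest.approx(d2, abs=2e-3)


def test_lookup_identity_on_grid_points(toy_tet_table):
    t = toy_tet_table
    k, i, j = 4, 2, 5
    val = t.lookup(t.d_grid[k], t.omega1_grid[i], t.omega2_grid[j])
    assert val == pytest.approx(t.energies[k, i, j], rel=1e-12)


def test_lookup_midpoint_is_mean(toy_tet_table):
    t = toy_tet_table
    k, i, j = 4, 1, 3
    d_mid = 0.5 * (t.d_grid[k] + t.d_grid[k + 1])
    val = t.lookup(d_mid, t.omega1_grid[i], t.omega2_grid[j])
    assert val == pytest.approx(
        0.5 * (t.energies[k, i, j] + t.energies[k + 1, i, j]), rel=1e-12)


def test_lookup_zero_beyond_cutoff(toy_tet_table):
    assert toy_tet_table.lookup(toy_tet_table.d_cut + 1.0, 0.1, 0.2) == 0.0


def test_lookup_overlap_raises(toy_tet_table):
    with pytest.raises(OverlapError):
        toy_tet_table.lookup(toy_tet_table.d_min.min() - 0.5, 0.0, 0.0)


def test_lookup_angle_periodicity(toy_pent_table, pent):
    t = toy_pent_table
    sector = pent.sector
    v1 = t.lookup(6.0, 0.31, 0.47)
    v2 = t.lookup(6.0, 0.31 + sector, 0.47 - 2 * sector)
    assert v1 == pytest.approx(v2, rel=1e-12)


def test_table_round_trip(tmp_path, toy_tet_table):
    path = tmp_path / "table"
    toy_tet_table.save(path)
    back = PairTable.load(path)
    assert np.array_equal(back.d_grid, toy_tet_table.d_grid)
    assert np.array_equal(back.energies, toy_tet_table.energies)
    assert back.d_cut == toy_tet_table.d_cut
    assert back.shapeA.symmetry_order == 4


def test_table_long_format_export(toy_tet_table):
    df = toy_tet_table.to_dataframe()
    assert set(df.columns) == {"d", "omega1", "omega2", "E"}
    assert len(df) == toy_tet_table.energies.size


def test_pair_energy_exchange_symmetry(pent, params):
    """Swapping the two sites maps (w1, w2) -> (w2 + pi, w1 + pi)."""
    opts = MeshOptions(contour_points=56)
    d, w1, w2 = 6.1, 0.2, 0.7
    e1 = pair_energy(pent, pent, d, w1, w2, params, opts)
    e2 = pair_energy(pent, pent, d, w2 + np.pi, w1 + np.pi, params, opts)
    assert e1 == pytest.approx(e2, abs=0.05)


def test_pair_energy_overlap_rejected(pent, params):
    with pytest.raises(OverlapError):
        pair_energy(pent, pent, 3.0, 0.0, 0.0, params)


def test_build_pair_table_cylinders_isotropic(cyl, params):
    """Cylinder tables carry a single angular bin and finite energies."""
    tab = build_pair_table(
        cyl, cyl, params, d_step=0.5, n_omega=4, d_cut=10.0, d_max=7.5,
        opts=MeshOptions(contour_points=48))
    assert tab.energies.shape[1:] == (1, 1)
    assert tab.d_min[0, 0] == pytest.approx(2 * cyl.radius + 0.5, abs=5e-3)
    finite = tab.energies[np.isfinite(tab.energies)]
    assert len(finite) > 3
    assert finite.min() < -1.0  # strong attraction at contact


def test_coarse_table_interpolates_fine_table(cyl, params):
    """Halving the d resolution changes interpolated mid-point energies
    by less than 0.1 kBT (grid-convergence guard for the tabulation)."""
    kw = dict(n_omega=4, d_cut=10.0, d_max=7.6,
              opts=MeshOptions(contour_points=48))
    fine = build_pair_table(cyl, cyl, params, d_step=0.25, **kw)
    coarse = build_pair_table(cyl, cyl, params, d_step=0.5, **kw)
    # compare midpoints of fully tabulated coarse intervals (the first
    # interval is clipped by the steric minimum distance)
    for d in np.arange(6.25, 7.3, 0.25):
        assert coarse.lookup(d, 0, 0) == pytest.approx(
            fine.lookup(d, 0, 0), abs=0.1)


def test_nonpairwise_deviation_limits(pent, params):
    """Two-protein configurations have (near) zero non-pairwise
    deviation, as do well-separated triples."""
    import numpy as np

    from mscl_lattice.configuration import Configuration
    from mscl_lattice.pair_potentials import nonpairwise_deviation

    opts = MeshOptions(contour_points=56)
    d = 6.2
    tab = build_pair_table(pent, pent, params, d_step=0.25, n_omega=4,
                           d_cut=12.0, d_max=d + 0.8, opts=opts)
    cfg2 = Configuration(np.array([[0.0, 0.0], [d, 0.0]]), np.zeros(2),
                         np.zeros(2, int), [pent], (60.0, 60.0),
                         periodic=False)
    dev = nonpairwise_deviation(cfg2, tab, params, opts)
    assert abs(dev) < 0.3  # table-interpolation tolerance

    far = Configuration(
        np.array([[0.0, 0.0], [13.0, 0.0], [6.5, 12.5]]), np.zeros(3),
        np.zeros(3, int), [pent], (80.0, 80.0), periodic=False)
    dev3 = nonpairwise_deviation(far, tab, params, opts, per_protein=True)
    assert abs(dev3) < 0.1
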