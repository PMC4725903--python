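"""Monte Carlo engine: energies, Metropolis statistics, order parameters."""

import numpy as np
import pytest

from mscl_lattice.configuration import Configuration
from mscl_lattice.monte_carlo import (
    AnnealSchedule,
    TableSet,
    anneal,
    mc_step,
    order_parameters,
    orientational_relax,
    random_gas,
    total_energy,
)
from mscl_lattice.pair_potentials import OverlapError

from conftest import make_toy_table


def _gas(table, n=20, box=(50.0, 50.0), seed=3):
    return random_gas([table.shapeA], [n], box, TableSet(table), seed=seed)


def test_single_protein_zero_energy(toy_disc_table):
    cfg = Configuration(np.array([[10.0, 10.0]]), np.zeros(1), np.zeros(1, int),
                        [toy_disc_table.shapeA], (40.0, 40.0))
    assert total_energy(cfg, toy_disc_table) == 0.0


def test_distant_pairs_zero_energy(toy_disc_table):
    cfg = Configuration(np.array([[5.0, 5.0], [25.0, 25.0]]), np.zeros(2),
                        np.zeros(2, int), [toy_disc_table.shapeA], (60.0, 60.0))
    assert total_energy(cfg, toy_disc_table) == 0.0


def test_cell_list_matches_direct_sum(toy_tet_table):
    cfg = _gas(toy_tet_table, n=25, box=(45.0, 45.0), seed=9)
    e_cell = total_energy(cfg, toy_tet_table, "cell")
    e_dir = total_energy(cfg, toy_tet_table, "direct")
    assert e_cell == pytest.approx(e_dir, abs=1e-12)


def test_cell_list_matches_direct_sum_mixed_species(toy_tet_table, toy_pent_table,
                                                    tet, pent):
    mixed = make_toy_table(tet, pent, depth=3.0, d_contact=5.15)
    ts = TableSet({(0, 0): toy_tet_table, (1, 1): toy_pent_table, (0, 1): mixed})
    cfg = random_gas([tet, pent], [12, 12], (55.0, 55.0), ts, seed=4)
    assert total_energy(cfg, ts, "cell") == pytest.approx(
        total_energy(cfg, ts, "direct"), abs=1e-12)


def test_overlap_detection(toy_disc_table):
    cfg = Configuration(np.array([[10.0, 10.0], [12.0, 10.0]]), np.zeros(2),
                        np.zeros(2, int), [toy_disc_table.shapeA], (40.0, 40.0))
    with pytest.raises(OverlapError):
        total_energy(cfg, toy_disc_table)


def test_identical_seeds_identical_trajectories(toy_pent_table):
    cfg = _gas(toy_pent_table, seed=5)
    sch = AnnealSchedule(n_steps=500, trace_stride=100)
    out1, tr1, _ = anneal(cfg, toy_pent_table, sch, seed=42)
    out2, tr2, _ = anneal(cfg, toy_pent_table, sch, seed=42)
    assert np.array_equal(out1.positions, out2.positions)
    assert np.array_equal(out1.orientations, out2.orientations)
    assert np.array_equal(tr1, tr2)


def test_zero_temperature_never_increases_energy(toy_pent_table):
    cfg = _gas(toy_pent_table, seed=6)
    sch = AnnealSchedule(n_steps=2000, t_start=1e-7, t_end=1e-9, trace_stride=50)
    _, trace, _ = anneal(cfg, toy_pent_table, sch, seed=1)
    assert np.all(np.diff(trace) <= 1e-9)


def test_metropolis_acceptance_statistics(toy_disc_table):
    """Empirical acceptance of fixed-dE moves matches exp(-dE/T).

    One mobile particle inside the attractive well of a frozen partner:
    the stationary radial distribution over a long fixed-T run must
    follow the Boltzmann weight (chi-square over radial bins).
    """
    from scipy.stats import chisquare

    t = toy_disc_table
    box = (40.0, 40.0)
    cfg = Configuration(np.array([[20.0, 20.0], [26.0, 20.0]]),
                        np.zeros(2), np.zeros(2, int), [t.shapeA], box)
    T = 1.0
    sch = AnnealSchedule(n_steps=60000, t_start=T, t_end=T,
                         unit_displacement=0.8, trace_stride=10**9)
    rs = []
    state = cfg
    from mscl_lattice.monte_carlo import _run

    state, _, _ = _run(state, t, sch, 7, True, True, mobile=[1])
    # sample by chunks to collect positions
    for chunk in range(60):
        state, _, _ = _run(state, t, AnnealSchedule(
            n_steps=500, t_start=T, t_end=T, unit_displacement=0.8,
            trace_stride=10**9), 1000 + chunk, True, True, mobile=[1])
        rs.append(float(np.hypot(*(state.positions[1] - state.positions[0]))))
    rs = np.array(rs)
    # coarse two-state check: bound (near minimum) vs stretched
    d0 = t.d_min[0, 0]
    edges = np.array([d0, d0 + 1.0, d0 + 2.0, d0 + 4.0])
    counts, _ = np.histogram(rs, edges)

    def boltz(lo, hi):
        r = np.linspace(lo, hi, 200)
        e = np.array([t.lookup(x, 0, 0) for x in r])
        return np.trapezoid(r * np.exp(-e / T), r)

    expected = np.array([boltz(*e) for e in zip(edges[:-1], edges[1:])])
    expected = expected / expected.sum() * counts.sum()
    stat, p = chisquare(counts, expected)
    assert p > 0.01


def test_mc_step_bookkeeping(toy_pent_table):
    cfg = _gas(toy_pent_table, seed=8)
    out, trace, stats = mc_step(cfg, toy_pent_table, T=1.0, seed=2)
    assert stats["attempted"][0] == cfg.n
    assert stats["attempted"][1] == cfg.n
    assert 0.0 <= stats["acceptance_displacement"] <= 1.0


def test_orientational_relax_keeps_positions(toy_pent_table):
    cfg = _gas(toy_pent_table, seed=10)
    sch = AnnealSchedule(n_steps=1000, t_start=0.5, t_end=0.01, trace_stride=100)
    out, trace, _ = orientational_relax(cfg, toy_pent_table, sch, seed=3)
    assert np.array_equal(out.positions, cfg.positions)
    assert trace[-1] <= trace[0] + 1e-9


def test_orientational_relax_isotropic_is_neutral(toy_disc_table):
    cfg = _gas(toy_disc_table, n=10, seed=11)
    sch = AnnealSchedule(n_steps=300, t_start=0.5, t_end=0.01, trace_stride=50)
    _, trace, _ = orientational_relax(cfg, toy_disc_table, sch, seed=4)
    assert trace[-1] == pytest.approx(trace[0], abs=1e-10)


def _lattice_config(kind, shape, d=6.0, L=5):
    from mscl_lattice.lattices import LatticeSpec, build_lattice

    spec = LatticeSpec(kind, spacing=d, size=L, orientation_scheme="horizontal")
    return build_lattice(spec, shape)


def test_order_parameters_square_vs_hexagonal(tet):
    sq = _lattice_config("square", tet)
    ops = order_parameters(sq)
    assert ops["psi4"] == pytest.approx(1.0, abs=1e-6)
    assert ops["psi6"] < 0.6
    hx = _lattice_config("hexagonal", tet)
    ops = order_parameters(hx)
    assert ops["psi6"] == pytest.approx(1.0, abs=1e-6)


def test_order_parameters_random_gas_disordered(toy_disc_table):
    cfg = random_gas([toy_disc_table.shapeA], [64], (120.0, 120.0),
                     TableSet(toy_disc_table), seed=1)
    ops = order_parameters(cfg)
    assert ops["psi4"] < 3.0 / np.sqrt(64)
    assert ops["psi6"] < 3.0 / np.sqrt(64)


def test_row_alternation_statistic(pent):
    from mscl_lattice.lattices import LatticeSpec, build_lattice

    aligned = build_lattice(
        LatticeSpec("hexagonal", spacing=6.0, size=4,
                    orientation_scheme="horizontal"), pent)
    anti = build_lattice(
        LatticeSpec("hexagonal", spacing=6.0, size=4,
                    orientation_scheme="alternating-rows"), pent)
    assert order_parameters(aligned)["row_alternation"] == pytest.approx(1.0)
    assert order_parameters(anti)["row_alternation"] < 0.0


def test_random_gas_deterministic_and_valid(toy_tet_table):
    g1 = _gas(toy_tet_table, seed=13)
    g2 = _gas(toy_tet_table, seed=13)
    assert np.array_equal(g1.positions, g2.positions)
    total_energy(g1, toy_tet_table)  # raises on any overlap


def test_schedule_validation():
    with pytest.raises(ValueError):
        AnnealSchedule(n_steps=0)
    with pytest.raises(ValueError):
        AnnealSchedule(t_start=0.1, t_end=0.5)
    with pytest.raises(ValueError):
        AnnealSchedule(cooling="exponential")


def test_orientational_relax_finds_face_on_square(tet, toy_tet_table):
    """Rotation-only annealing of a square tetramer lattice turns every
    protein face-on toward its neighbors (trough along the bond)."""
    from mscl_lattice.lattices import LatticeSpec, build_lattice

    spec = LatticeSpec("square", spacing=5.5, size=4,
                       orientation_scheme="horizontal")
    cfg = build_lattice(spec, tet)
    rng = np.random.default_rng(3)
    cfg.orientations = rng.uniform(0, 2 * np.pi, cfg.n)
    sch = AnnealSchedule(n_steps=4000, t_start=0.5, t_end=0.01,
                         trace_stride=4000)
    out, trace, _ = orientational_relax(cfg, toy_tet_table, sch, seed=5)
    assert trace[-1] < trace[0]
    # face-on alignment: omega ~ pi/4 (mod pi/2) within the table's
    # angular rounding for the bulk of the lattice
    score = np.cos(4 * (out.orientations - np.pi / 4))
    assert np.mean(score > 0.7) > 0.8


def test_mixed_oligomer_annealing_tetramer_orders_more(tet, pent,
                                                       toy_tet_table,
                                                       toy_pent_table):
    """In an annealed 50/50 tetramer/pentamer mixture the tetramer
    sub-cluster shows stronger four-fold bond order than the pentamer
    sub-cluster (four-fold shapes tile a square lattice; five-fold
    shapes frustrate it)."""
    mixed = make_toy_table(tet, pent, depth=3.0, aniso=0.3, d_contact=5.15)
    ts = TableSet({(0, 0): toy_tet_table, (1, 1): toy_pent_table,
                   (0, 1): mixed})
    cfg = random_gas([tet, pent], [24, 24], (52.0, 52.0), ts, seed=6)
    sch = AnnealSchedule(n_steps=30000, t_start=2.0, trace_stride=30000)
    out, _, _ = anneal(cfg, ts, sch, seed=9)

    def sub_psi4(species):
        idx = np.where(out.species == species)[0]
        sub = Configuration(out.positions[idx], out.orientations[idx],
                            np.zeros(len(idx), int), [out.shapes[species]],
                            out.box, periodic=True)
        return order_parameters(sub)["psi4_largest_cluster"]

    assert sub_psi4(0) > sub_psi4(1)
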