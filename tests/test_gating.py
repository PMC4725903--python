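"""Activation barriers, Arrhenius ratios and closed/open mixtures."""

import numpy as np
import pytest

from mscl_lattice.gating import (
    BarrierResult,
    activation_barrier,
    arrhenius_ratio,
    barrier_vs_tension,
    mixed_state_anneal,
)
from mscl_lattice.lattices import LatticeSpec, build_lattice
from mscl_lattice.monte_carlo import AnnealSchedule

from conftest import make_toy_table


def test_arrhenius_identity_and_closed_form():
    assert arrhenius_ratio(2.0, 2.0, 1.0) == 1.0
    assert arrhenius_ratio(np.log(10.0), 0.0, 1.0) == pytest.approx(10.0)
    assert arrhenius_ratio(1.0, 3.0, 1.0) * arrhenius_ratio(3.0, 1.0, 1.0) == \
        pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        arrhenius_ratio(1.0, 2.0, 0.0)


def _toy_gating_tables(tet, depth=4.0, open_scale=1.25):
    """Closed-closed and closed-open sticky tables; the open state is
    bigger, so gating a site requires pushing neighbors apart."""
    from dataclasses import replace

    from mscl_lattice.shapes import GatingState

    open_shape = replace(tet, radius=open_scale * tet.radius,
                         state=GatingState.OPEN, mismatch=-0.35)
    cc = make_toy_table(tet, depth=depth, d_contact=5.2)
    co = make_toy_table(tet, open_shape, depth=0.6,
                        d_contact=5.2 * (1 + open_scale) / 2)
    return open_shape, cc, co


def test_barrier_zero_in_noninteracting_limit(tet):
    open_shape, cc, co = _toy_gating_tables(tet, depth=4.0)
    # spacing beyond d_cut plus the tethered-rearrangement reach
    spec = LatticeSpec("square", spacing=cc.d_cut + 4.0, size=4,
                       orientation_scheme="face-on")
    cfg = build_lattice(spec, tet)
    res = activation_barrier(cfg, open_shape, cc, {(0, 0): cc, (0, 1): co},
                             site="corner", n_restarts=2, relax_steps=500)
    assert res.barrier == pytest.approx(0.0, abs=1e-9)


def test_corner_barrier_not_above_edge(tet):
    open_shape, cc, co = _toy_gating_tables(tet)
    spec = LatticeSpec("square", spacing=5.25, size=5,
                       orientation_scheme="face-on")
    cfg = build_lattice(spec, tet)
    common = dict(n_restarts=3, relax_steps=2000, seed=5)
    corner = activation_barrier(cfg, open_shape, cc, {(0, 0): cc, (0, 1): co},
                                site="corner", **common)
    edge = activation_barrier(cfg, open_shape, cc, {(0, 0): cc, (0, 1): co},
                              site="edge", **common)
    # fewer favorable contacts are broken at a corner than at an edge
    assert corner.barrier <= edge.barrier + 0.3


def test_barrier_vs_tension_requires_varying_grid(tet):
    open_shape, cc, co = _toy_gating_tables(tet)
    spec = LatticeSpec("square", spacing=5.25, size=4,
                       orientation_scheme="face-on")
    cfg = build_lattice(spec, tet)
    with pytest.raises(ValueError):
        barrier_vs_tension(cfg, open_shape, {0.0: (cc, co)})


def test_mixed_anneal_all_closed_fully_segregated(tet):
    open_shape, cc, co = _toy_gating_tables(tet)
    oo = make_toy_table(open_shape, depth=3.0, d_contact=6.5)
    sch = AnnealSchedule(n_steps=3000, t_start=1.0, trace_stride=1000)
    cfg, report = mixed_state_anneal(
        16, 0, (tet, open_shape), {(0, 0): cc, (1, 1): oo, (0, 1): co},
        sch, box=(45.0, 45.0), seed=2)
    assert report["segregation_index"] == 1.0


def test_mixed_anneal_reports_structure(tet):
    open_shape, cc, co = _toy_gating_tables(tet)
    oo = make_toy_table(open_shape, depth=3.0, d_contact=6.5)
    sch = AnnealSchedule(n_steps=4000, t_start=1.0, trace_stride=2000)
    cfg, report = mixed_state_anneal(
        10, 10, (tet, open_shape), {(0, 0): cc, (1, 1): oo, (0, 1): co},
        sch, box=(55.0, 55.0), seed=3)
    assert 0.0 <= report["segregation_index"] <= 1.0
    assert report["segregation_random"] == pytest.approx(0.5, abs=0.03)
    assert report["energy_trace"][-1] < report["energy_trace"][0]


def test_barrier_sign_and_site_ordering_confirmed_by_multibody_fe(tet):
    """The pairwise barrier's sign and corner-vs-edge ordering hold when
    the same relaxed geometries are re-scored by full multi-body FE."""
    from mscl_lattice.fe_core import BilayerParams
    from mscl_lattice.gating import activation_barrier, ground_state_cluster
    from mscl_lattice.meshing import MeshOptions
    from mscl_lattice.pair_potentials import build_pair_table, multibody_energy
    from mscl_lattice.shapes import mscl_shape

    params = BilayerParams()
    opts = MeshOptions(contour_points=48)
    kw = dict(d_step=0.5, n_omega=4, d_cut=12.0, opts=opts)
    tet_o = mscl_shape("tetramer", "open")
    cc = build_pair_table(tet, tet, params, d_max=8.0, **kw)
    co = build_pair_table(tet, tet_o, params, d_max=10.5, **kw)
    cluster = ground_state_cluster("tetramer", tet, cc, L=3)
    dg = {}
    dg_fe = {}
    for site in ("corner", "edge"):
        res = activation_barrier(cluster, tet_o, cc, {(0, 0): cc, (0, 1): co},
                                 site=site, n_restarts=2, relax_steps=1500,
                                 seed=2)
        dg[site] = res.barrier
        e_g = multibody_energy(res.ground_config, params, opts)
        e_o = multibody_energy(res.open_config, params, opts)
        dg_fe[site] = e_o - e_g
    for site in ("corner", "edge"):
        assert dg[site] > 0
        assert dg_fe[site] > 0       # same sign in multi-body mode
    assert dg["corner"] <= dg["edge"] + 0.5
    assert dg_fe["corner"] <= dg_fe["edge"] + 2.0
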