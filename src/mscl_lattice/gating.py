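"""Lattice activation barriers and gating kinetics of MscL clusters.

Opening an MscL enlarges its cross-sectional footprint, so a protein
inside a densely packed cluster cannot gate without an energetically
costly lattice rearrangement; a protein on the cluster perimeter only
needs a minor local rearrangement.  The lattice activation barrier is

    dG = min_rearrangement E_int[site open, neighbors relaxed]
         - E_int[all closed ground state]

using interaction energies only — the isolated-protein gating energy is
the same in both states of the cluster calculation and drops out.  The
barrier grows with membrane tension because tension thins the bilayer,
deepening the hydrophobic mismatch of (thick) closed MscL and hence the
favorable closed-closed contacts that must be broken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .configuration import Configuration
from .lattices import LatticeSpec, build_lattice, face_on_angle
from .monte_carlo import (
    AnnealSchedule,
    TableSet,
    anneal,
    order_parameters,
    random_gas,
    total_energy,
)
from .shapes import ProteinShape


@dataclass
class BarrierResult:
    tension: float          # kBT/nm^2
    site: str               # "corner" | "edge"
    oligomer: str
    barrier: float          # kBT
    ground_energy: float    # kBT (total, all closed)
    open_energy: float      # kBT (total, site open, relaxed)
    ground_config: Configuration | None = None
    open_config: Configuration | None = None


def _perimeter_site(config: Configuration, site: str) -> int:
    """Pick the protein closest to a bounding-box corner or edge midpoint."""
    pos = config.positions
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    if site == "corner":
        target = lo
    elif site == "edge":
        target = np.array([0.5 * (lo[0] + hi[0]), lo[1]])
    else:
        raise ValueError("site must be 'corner' or 'edge'")
    return int(np.argmin(np.linalg.norm(pos - target, axis=1)))


def _shell_of(config: Configuration, k: int, radius: float) -> np.ndarray:
    d = np.array([np.hypot(*config.displacement(k, j)) for j in range(config.n)])
    d[k] = 0.0
    return np.where(d <= radius)[0]


class InfeasibleSiteError(RuntimeError):
    """No steric accommodation found for the open state at this site."""


def _resolve_overlaps(config: Configuration, site: int, ts: TableSet,
                      pad: float = 0.03, max_iter: int = 400):
    """Push proteins apart until no steric violation remains.

    Each iteration moves the partner farther from the gating site outward
    along the pair axis by the deficit; the cascade terminates at the
    cluster perimeter.  Returns (feasible config, set of moved indices).
    """
    cfg = config.copy()
    moved: set[int] = set()
    for _ in range(max_iter):
        worst = None
        for i in range(cfg.n):
            for j in range(i + 1, cfg.n):
                dvec = cfg.displacement(i, j)
                d = float(np.hypot(*dvec))
                if d > ts.d_cut_max:
                    continue
                si, sj = int(cfg.species[i]), int(cfg.species[j])
                tab = ts.table_list[ts.tid_map[si, sj]]
                a, b = (j, i) if ts.swap_map[si, sj] else (i, j)
                dv = cfg.displacement(a, b)
                alpha = np.arctan2(dv[1], dv[0])
                dmin = tab.min_distance_of(cfg.orientations[a] - alpha,
                                           cfg.orientations[b] - alpha)
                deficit = dmin - d
                if deficit > 0 and (worst is None or deficit > worst[0]):
                    worst = (deficit, i, j)
        if worst is None:
            return cfg, moved
        deficit, i, j = worst
        # move the partner farther from the site
        di = float(np.hypot(*cfg.displacement(site, i)))
        dj = float(np.hypot(*cfg.displacement(site, j)))
        mover, anchor = (i, j) if di > dj else (j, i)
        dvec = cfg.displacement(anchor, mover)
        d = max(float(np.hypot(*dvec)), 1e-9)
        cfg.positions[mover] += (deficit + pad) * dvec / d
        moved.add(mover)
    raise InfeasibleSiteError("overlap resolution did not converge")


def activation_barrier(
    config: Configuration,
    open_shape: ProteinShape,
    tables_closed,
    tables_mixed,
    site: str = "corner",
    shell_radius_factor: float = 2.3,
    tether: float = 1.5,
    n_restarts: int = 5,
    relax_steps: int = 4000,
    seed: int = 0,
    site_index: int | None = None,
) -> BarrierResult:
    """Barrier for gating one perimeter protein of an all-closed cluster.

    ``config`` is the all-closed ground-state cluster (species 0 =
    closed); ``tables_closed`` scores it.  ``tables_mixed`` must map
    species pairs {(0,0): closed-closed, (0,1)/(1,0): closed-open} for
    the cluster with the gated site switched to ``open_shape`` (species
    1).  The site and its neighbors within ``shell_radius_factor`` times
    the modal nearest-neighbor distance are relaxed by low-temperature
    annealing from ``n_restarts`` seeds; the best (lowest) relaxed
    energy defines the barrier.
    """
    ts_closed = tables_closed if isinstance(tables_closed, TableSet) \
        else TableSet(tables_closed)
    # locally relax the all-closed cluster first so the barrier compares
    # two locally minimized states (constructed lattices can carry small
    # boundary strains that would otherwise bias dG, even negative)
    g_sch = AnnealSchedule(n_steps=max(relax_steps // 2, 500), t_start=0.2,
                           t_end=0.01, unit_displacement=0.15,
                           unit_rotation=0.1, trace_stride=10**9)
    config, _, _ = anneal(config, ts_closed, g_sch, seed=seed + 13,
                          max_dev=0.75)
    e_ground = total_energy(config, ts_closed)

    k = site_index if site_index is not None else _perimeter_site(config, site)
    ops = order_parameters(config)
    d_nn = float(np.median(ops["nn_distances"]))
    shell = _shell_of(config, k, shell_radius_factor * d_nn)

    opened = config.copy()
    opened.shapes = [config.shapes[0], open_shape]
    opened.species = opened.species.copy()
    opened.species[k] = 1
    if not isinstance(tables_mixed, TableSet):
        tables_mixed = dict(tables_mixed)
        # a single gated site never meets another open protein, but the
        # packed table set must cover the (open, open) slot
        tables_mixed.setdefault((1, 1), tables_mixed[(0, 1)])
    ts_mixed = tables_mixed if isinstance(tables_mixed, TableSet) \
        else TableSet(tables_mixed)

    # candidate accommodations, each refined by tethered low-temperature
    # annealing of the local shell:
    #  - pop the opening protein outward along the perimeter normal
    #    (minimal rearrangement; the open state is weakly bound at larger
    #    center distances)
    #  - push overlapping neighbors outward (cascading to the perimeter)
    centroid = config.positions.mean(axis=0)
    nhat = opened.positions[k] - centroid
    nhat = nhat / max(np.linalg.norm(nhat), 1e-9)
    starts = []
    for delta in (0.0, 1.0, 2.0, 3.0, 4.0):
        trial = opened.copy()
        trial.positions[k] = trial.positions[k] + delta * nhat
        try:
            trial, pushed = _resolve_overlaps(trial, k, ts_mixed, pad=0.03)
        except InfeasibleSiteError:
            continue
        starts.append((trial, pushed))
    for r in range(max(n_restarts - len(starts), 1)):
        try:
            starts.append(_resolve_overlaps(opened, k, ts_mixed,
                                            pad=0.08 + 0.05 * r))
        except InfeasibleSiteError:
            continue
    best = None
    for r, (trial, pushed) in enumerate(starts):
        mob = sorted(set(shell) | pushed | {k})
        try:
            sch = AnnealSchedule(
                n_steps=relax_steps, t_start=0.4, t_end=0.01,
                unit_displacement=0.2, unit_rotation=0.15,
                trace_stride=relax_steps,
            )
            relaxed, trace, _ = anneal(trial, ts_mixed, sch,
                                       seed=seed + 7919 * (r + 1),
                                       mobile=mob, max_dev=tether)
            e_open = total_energy(relaxed, ts_mixed)
        except Exception:
            continue
        if best is None or e_open < best:
            best = e_open
            best_cfg = relaxed
    if best is None:
        raise InfeasibleSiteError(f"no steric accommodation at site {k}")
    return BarrierResult(
        tension=ts_mixed.table_list[0].params.tension, site=site,
        oligomer=config.shapes[0].label or f"s{config.shapes[0].symmetry_order}",
        barrier=best - e_ground, ground_energy=e_ground, open_energy=best,
        ground_config=config, open_config=best_cfg,
    )


def barrier_vs_tension(configs_by_tau: dict, open_shape: ProteinShape,
                       tables_by_tau: dict, site: str = "corner",
                       seed: int = 0, **kwargs) -> dict:
    """Barriers over a tension grid with a least-squares linear fit.

    ``tables_by_tau`` maps tau -> (closed-closed table, closed-open
    table) tabulated at that tension (the potential itself depends on
    tau, not just the Boltzmann weight); ``configs_by_tau`` maps tau to
    the all-closed ground-state cluster (a single Configuration may be
    shared).  Returns samples, slope, intercept and R^2.
    """
    taus = sorted(tables_by_tau)
    if len(taus) < 3:
        raise ValueError("need at least 3 tension values")
    if np.allclose(taus, taus[0]):
        raise ValueError("degenerate tension grid")
    barriers = []
    results = []
    for tau in taus:
        cc, co = tables_by_tau[tau]
        cfg = configs_by_tau[tau] if isinstance(configs_by_tau, dict) \
            else configs_by_tau
        res = activation_barrier(
            cfg, open_shape, cc, {(0, 0): cc, (0, 1): co}, site=site,
            seed=seed, **kwargs)
        barriers.append(res.barrier)
        results.append(res)
    from scipy.stats import linregress

    fit = linregress(taus, barriers)
    return {
        "tau": np.asarray(taus), "barrier": np.asarray(barriers),
        "slope": float(fit.slope), "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2), "results": results,
    }


def arrhenius_ratio(dg_a: float, dg_b: float, temperature: float = 1.0) -> float:
    """Rate ratio k_B / k_A = exp((dG_A - dG_B) / T).

    Barriers in kBT at room temperature, T in units of room temperature;
    the returned factor is how much faster lattice B activates than A.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp((dg_a - dg_b) / temperature)


# -- mixed closed / open clusters -----------------------------------------


def mixed_state_anneal(
    n_closed: int,
    n_open: int,
    shapes: tuple[ProteinShape, ProteinShape],
    tables,
    schedule: AnnealSchedule,
    box: tuple[float, float] | None = None,
    seed: int = 0,
):
    """Anneal a closed/open mixture and report state segregation.

    ``tables`` maps {(0,0): closed-closed, (1,1): open-open, (0,1):
    closed-open}.  The segregation index is the fraction of neighbor
    pairs sharing a gating state; under random mixing its expectation is
    p_cc + p_oo from the pair-count fractions.  Also reported: the modal
    closed-open neighbor distance and per-state sub-cluster order
    parameters.
    """
    ts = tables if isinstance(tables, TableSet) else TableSet(tables)
    closed, open_ = shapes
    if box is None:
        from .shapes import enclosed_area

        area = n_closed * enclosed_area(closed) + n_open * enclosed_area(open_)
        side = math.sqrt(area / 0.3)
        box = (side, side)
    cfg0 = random_gas([closed, open_], [n_closed, n_open], box, ts, seed=seed)
    cfg, trace, stats = anneal(cfg0, ts, schedule, seed=seed)

    # neighbor criterion per pair type: closed-open neighbors sit at a
    # characteristic distance well beyond the same-state contact (the
    # closed-open potential is repulsive at short range), so a single
    # global cutoff would miss the closed/open interface entirely
    co_tab = ts.table_list[ts.tid_map[0, 1]]
    fin = np.where(np.isfinite(co_tab.energies), co_tab.energies, np.nan)
    k_star = np.unravel_index(np.nanargmin(fin), fin.shape)[0]
    d_co_star = float(co_tab.d_grid[k_star])

    n = cfg.n
    dmat = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = float(np.hypot(*cfg.displacement(i, j)))
    cuts = {}
    for s in (0, 1):
        idx = np.where(cfg.species == s)[0]
        if len(idx) > 1:
            nn = dmat[np.ix_(idx, idx)].min(axis=1)
            cuts[s] = 1.35 * float(np.median(nn))
    cut_cross = 1.3 * d_co_star
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = int(cfg.species[i]), int(cfg.species[j])
            cut = cuts.get(si, 0.0) if si == sj else cut_cross
            if dmat[i, j] < cut:
                pairs.append((i, j))
    same = sum(1 for i, j in pairs if cfg.species[i] == cfg.species[j])
    seg = same / len(pairs) if pairs else np.nan
    fc, fo = n_closed / n, n_open / n
    seg_random = fc * fc + fo * fo

    co_d = [dmat[i, j] for i, j in pairs if cfg.species[i] != cfg.species[j]]

    def sub_ops(species):
        idx = np.where(cfg.species == species)[0]
        if len(idx) < 4:
            return None
        sub = Configuration(
            cfg.positions[idx], cfg.orientations[idx],
            np.zeros(len(idx), int), [cfg.shapes[species]], cfg.box,
            periodic=cfg.periodic)
        return order_parameters(sub)

    # connected components of the state-aware neighbor graph
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    if pairs:
        ii, jj = np.array(pairs).T
        adj = sp.coo_matrix((np.ones(len(pairs)), (ii, jj)), shape=(n, n))
        ncomp, labels = connected_components(adj, directed=False)
    else:
        ncomp, labels = n, np.arange(n)
    sizes = np.bincount(labels)
    big = np.where(labels == sizes.argmax())[0]

    report = {
        "segregation_index": float(seg),
        "segregation_random": float(seg_random),
        "closed_open_neighbor_distance": float(np.median(co_d)) if co_d else np.nan,
        "n_clusters": int(ncomp),
        "largest_cluster_size": int(sizes.max()),
        "largest_cluster_mixed": len({int(cfg.species[m]) for m in big}) > 1,
        "closed_sub": sub_ops(0),
        "open_sub": sub_ops(1),
        "energy_trace": trace,
    }
    return cfg, report


def ground_state_cluster(oligomer: str, shape: ProteinShape, table,
                         L: int = 5, phi: float | None = None) -> Configuration:
    """All-closed ground-state cluster: face-on square for tetramers,
    distorted hexagonal (alternating rows) for pentamers."""
    if shape.symmetry_order == 4:
        d = table.min_distance_of(face_on_angle(shape), face_on_angle(shape))
        spec = LatticeSpec("square", spacing=d + 0.02, size=L,
                           orientation_scheme="face-on")
        return build_lattice(spec, shape)
    if shape.symmetry_order == 5:
        from .lattices import max_packing_fraction, optimize_distorted_a

        if phi is None:
            phi = max_packing_fraction(shape, "distorted-A", table=table,
                                       size=L) - 0.01
        spec, _ = optimize_distorted_a(shape, table, phi, size=L, n_starts=2)
        return build_lattice(spec, shape)
    raise ValueError("ground-state cluster defined for tetramer/pentamer")
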