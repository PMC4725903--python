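"""Metropolis Monte Carlo of protein diffusion with simulated annealing.

Proteins move by translational and rotational trial moves driven by
tabulated pair potentials (:class:`~mscl_lattice.pair_potentials.PairTable`).
A single Monte Carlo step performs one displacement and one rotation
trial per protein on average (2N trials in random order); trials are
accepted by the Metropolis rule at temperature T measured in units of
room temperature, with pair energies in kBT, and rejected outright on
steric (d_min) violations.  Temperature decreases linearly over the run
during simulated annealing.

The inner loop is compiled with numba and uses a linked-cell grid
(cell edge about half the interaction reach, 5x5 neighbor scans), with a
direct pair loop as fallback for boxes too small for the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .configuration import Configuration
from .pair_potentials import OverlapError, PairTable

__all__ = [
    "AnnealSchedule", "TableSet", "anneal", "mc_step", "orientational_relax",
    "total_energy", "order_parameters", "random_gas", "Configuration",
]


@dataclass
class AnnealSchedule:
    """Linear cooling schedule; temperatures in units of room temperature."""

    n_steps: int = 100_000
    t_start: float = 2.5
    t_end: float = 0.01
    cooling: str = "linear"
    unit_displacement: float = 0.5   # nm
    unit_rotation: float = 0.2       # rad
    trace_stride: int = 1000

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.cooling != "linear":
            raise ValueError("only linear cooling is implemented")


class TableSet:
    """Pack one or more PairTables into flat arrays for the compiled kernel.

    ``tables`` maps an ordered species pair (i, j) to its PairTable; a
    missing (j, i) entry reuses table (i, j) with the protein roles
    swapped.  A single PairTable may be passed for one-species systems.
    """

    def __init__(self, tables, n_species: int | None = None):
        if isinstance(tables, PairTable):
            tables = {(0, 0): tables}
        self.tables = tables
        ns = n_species or (max(max(k) for k in tables) + 1)
        self.n_species = ns
        tids = {}
        self.table_list: list[PairTable] = []
        self.tid_map = np.full((ns, ns), -1, np.int64)
        self.swap_map = np.zeros((ns, ns), np.int64)
        for (i, j), tab in tables.items():
            if id(tab) not in tids:
                tids[id(tab)] = len(self.table_list)
                self.table_list.append(tab)
            t = tids[id(tab)]
            self.tid_map[i, j] = t
        for i in range(ns):
            for j in range(ns):
                if self.tid_map[i, j] < 0 and self.tid_map[j, i] >= 0:
                    self.tid_map[i, j] = self.tid_map[j, i]
                    self.swap_map[i, j] = 0 if i == j else 1
        if (self.tid_map < 0).any():
            missing = np.argwhere(self.tid_map < 0)
            raise ValueError(f"no table for species pairs {missing.tolist()}")

        nt = len(self.table_list)
        nd = max(len(t.d_grid) for t in self.table_list)
        n1 = max(len(t.omega1_grid) for t in self.table_list)
        n2 = max(len(t.omega2_grid) for t in self.table_list)
        self.E = np.zeros((nt, nd, n1, n2))
        self.DMIN = np.zeros((nt, n1, n2))
        self.D0 = np.zeros(nt)
        self.DSTEP = np.ones(nt)
        self.ND = np.zeros(nt, np.int64)
        self.N1 = np.zeros(nt, np.int64)
        self.N2 = np.zeros(nt, np.int64)
        self.SEC1 = np.zeros(nt)
        self.SEC2 = np.zeros(nt)
        self.DCUT = np.zeros(nt)
        for t, tab in enumerate(self.table_list):
            a, b = len(tab.d_grid), len(tab.omega1_grid)
            c = len(tab.omega2_grid)
            # finite sentinel for sterically forbidden entries: the
            # fastmath kernels must never see inf/nan
            self.E[t, :a, :b, :c] = np.nan_to_num(tab.energies, posinf=1e30)
            self.DMIN[t, :b, :c] = tab.d_min
            self.D0[t] = tab.d_grid[0]
            self.DSTEP[t] = tab.d_grid[1] - tab.d_grid[0] if a > 1 else 1.0
            self.ND[t] = a
            self.N1[t] = b
            self.N2[t] = c
            self.SEC1[t] = tab.shapeA.sector
            self.SEC2[t] = tab.shapeB.sector
            self.DCUT[t] = tab.d_cut
        self.d_cut_max = float(self.DCUT.max())

    def as_args(self):
        return (
            self.tid_map, self.swap_map, self.E, self.DMIN, self.D0,
            self.DSTEP, self.ND, self.N1, self.N2, self.SEC1, self.SEC2,
            self.DCUT,
        )


# -- compiled kernels ------------------------------------------------------


@njit(cache=True, inline="always")
def _table_lookup(tid, d, w1, w2, E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT):
    """Rounded-angle, d-interpolated lookup. Returns (energy, feasible)."""
    if d > DCUT[tid]:
        return 0.0, True
    n1 = N1[tid]
    n2 = N2[tid]
    i = int(round((w1 % SEC1[tid]) / SEC1[tid] * n1)) % n1
    j = int(round((w2 % SEC2[tid]) / SEC2[tid] * n2)) % n2
    if d < DMIN[tid, i, j]:
        return 0.0, False
    nd = ND[tid]
    t = (d - D0[tid]) / DSTEP[tid]
    k = int(math.floor(t))
    dlast = D0[tid] + (nd - 1) * DSTEP[tid]
    if k >= nd - 1:
        e = E[tid, nd - 1, i, j]
        if DCUT[tid] > dlast:
            e *= 1.0 - (d - dlast) / (DCUT[tid] - dlast)
        return e, True
    if k < 0:
        k = 0
        t = 0.0
    frac = t - k
    e0 = E[tid, k, i, j]
    e1 = E[tid, k + 1, i, j]
    if e0 > 1e29:
        e0 = e1  # d >= d_min but below the first finite row: flat
    return (1.0 - frac) * e0 + frac * e1, True


@njit(cache=True, inline="always")
def _pair_energy_at(k, xk, yk, wk, m, pos, ang, spec, boxW, boxH, periodic,
                    tid_map, swap_map, E, DMIN, D0, DSTEP, ND, N1, N2,
                    SEC1, SEC2, DCUT):
    """Energy of particle k (virtually at xk, yk, wk) with particle m."""
    dx = pos[m, 0] - xk
    dy = pos[m, 1] - yk
    if periodic:
        dx -= boxW * round(dx / boxW)
        dy -= boxH * round(dy / boxH)
    d = math.sqrt(dx * dx + dy * dy)
    sk = spec[k]
    sm = spec[m]
    tid = tid_map[sk, sm]
    if swap_map[sk, sm] == 0:
        alpha = math.atan2(dy, dx)
        return _table_lookup(tid, d, wk - alpha, ang[m] - alpha,
                             E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT)
    alpha = math.atan2(-dy, -dx)
    return _table_lookup(tid, d, ang[m] - alpha, wk - alpha,
                         E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT)


@njit(cache=True, inline="always")
def _cell_index(x, y, ox, oy, cw, ch, ncx, ncy):
    cx = int(math.floor((x - ox) / cw))
    cy = int(math.floor((y - oy) / ch))
    if cx < 0:
        cx = 0
    elif cx >= ncx:
        cx = ncx - 1
    if cy < 0:
        cy = 0
    elif cy >= ncy:
        cy = ncy - 1
    return cx, cy


@njit(cache=True, fastmath=True)
def _local_energy(k, xk, yk, wk, pos, ang, spec, head, nxt, ox, oy, cw, ch,
                  ncx, ncy, boxW, boxH, periodic, use_cells, mw, tid_map, swap_map,
                  E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT):
    """Total pair energy of particle k placed at (xk, yk, wk)."""
    etot = 0.0
    if not use_cells:
        for m in range(pos.shape[0]):
            if m == k:
                continue
            e, ok = _pair_energy_at(
                k, xk, yk, wk, m, pos, ang, spec, boxW, boxH, periodic,
                tid_map, swap_map, E, DMIN, D0, DSTEP, ND, N1, N2,
                SEC1, SEC2, DCUT)
            if not ok:
                return 0.0, False
            etot += e
        return etot, True
    cx, cy = _cell_index(xk, yk, ox, oy, cw, ch, ncx, ncy)
    for ddx in range(-mw, mw + 1):
        for ddy in range(-mw, mw + 1):
            gx = cx + ddx
            gy = cy + ddy
            if periodic:
                gx %= ncx
                gy %= ncy
            elif gx < 0 or gx >= ncx or gy < 0 or gy >= ncy:
                continue
            m = head[gx * ncy + gy]
            while m >= 0:
                if m != k:
                    e, ok = _pair_energy_at(
                        k, xk, yk, wk, m, pos, ang, spec, boxW, boxH, periodic,
                        tid_map, swap_map, E, DMIN, D0, DSTEP, ND, N1, N2,
                        SEC1, SEC2, DCUT)
                    if not ok:
                        return 0.0, False
                    etot += e
                m = nxt[m]
    return etot, True


@njit(cache=True, fastmath=True)
def _total_energy_kernel(pos, ang, spec, head, nxt, ox, oy, cw, ch, ncx, ncy,
                         boxW, boxH, periodic, use_cells, m, tid_map, swap_map,
                         E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT):
    tot = 0.0
    for k in range(pos.shape[0]):
        e, ok = _local_energy(k, pos[k, 0], pos[k, 1], ang[k], pos, ang, spec,
                              head, nxt, ox, oy, cw, ch, ncx, ncy, boxW, boxH,
                              periodic, use_cells, m, tid_map, swap_map, E, DMIN,
                              D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT)
        tot += e
    return 0.5 * tot


@njit(cache=True)
def _build_cells(pos, ox, oy, cw, ch, ncx, ncy):
    n = pos.shape[0]
    head = np.full(ncx * ncy, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    for k in range(n):
        cx, cy = _cell_index(pos[k, 0], pos[k, 1], ox, oy, cw, ch, ncx, ncy)
        c = cx * ncy + cy
        nxt[k] = head[c]
        head[c] = k
    return head, nxt


@njit(cache=True)
def _cell_geometry(boxW, boxH, periodic, reach, m):
    """Cell grid (origin, cell sizes, counts, use_cells flag).

    Cells have edge ~reach/m and neighbor scans cover (2m+1)^2 cells, so
    every pair within ``reach`` is found; smaller cells (m=2) visit
    fewer irrelevant candidates than the classic 3x3 scheme.
    """
    if periodic:
        cell = reach / m
        ncx = max(1, int(boxW // cell))
        ncy = max(1, int(boxH // cell))
        cw = boxW / ncx
        ch = boxH / ncy
        ox = 0.0
        oy = 0.0
        use = ncx >= 2 * m + 1 and ncy >= 2 * m + 1
    else:
        cell = reach / m
        ox = -reach
        oy = -reach
        ncx = max(1, int((boxW + 2 * reach) // cell))
        ncy = max(1, int((boxH + 2 * reach) // cell))
        cw = cell
        ch = cell
        use = True
    return ox, oy, cw, ch, ncx, ncy, use


@njit(cache=True, fastmath=True)
def _trial_delta(k, xn, yn, wn, moved, pos, ang, spec, head, nxt,
                 ox, oy, cw, ch, ncx, ncy, boxW, boxH, periodic, use_cells, m,
                 tid_map, swap_map, E, DMIN, D0, DSTEP, ND, N1, N2,
                 SEC1, SEC2, DCUT, dcut2max):
    """Energy change of moving particle k to (xn, yn, wn), one neighbor scan.

    Valid for displacements smaller than (cell width - d_cut); the scan
    runs over the 3x3 cells around the OLD position, which then covers
    every interaction partner of both states.  Returns (dE, feasible).
    """
    sk = spec[k]
    xo = pos[k, 0]
    yo = pos[k, 1]
    wo = ang[k]
    de = 0.0
    if use_cells:
        cx, cy = _cell_index(xo, yo, ox, oy, cw, ch, ncx, ncy)
        x0, x1 = cx - m, cx + m + 1
        y0, y1 = cy - m, cy + m + 1
    else:
        x0, x1, y0, y1 = 0, 1, 0, 1
    for gx0 in range(x0, x1):
        for gy0 in range(y0, y1):
            if use_cells:
                gx = gx0 % ncx if periodic else gx0
                gy = gy0 % ncy if periodic else gy0
                if gx < 0 or gx >= ncx or gy < 0 or gy >= ncy:
                    continue
                m = head[gx * ncy + gy]
            else:
                m = -2  # sentinel: iterate all particles
            midx = 0
            while True:
                if not use_cells:
                    if midx >= pos.shape[0]:
                        break
                    mm = midx
                    midx += 1
                else:
                    if m < 0:
                        break
                    mm = m
                    m = nxt[m]
                if mm == k:
                    continue
                sm = spec[mm]
                tid = tid_map[sk, sm]
                swap = swap_map[sk, sm]
                dxn = pos[mm, 0] - xn
                dyn = pos[mm, 1] - yn
                if periodic:
                    dxn -= boxW * round(dxn / boxW)
                    dyn -= boxH * round(dyn / boxH)
                d2n = dxn * dxn + dyn * dyn
                if not moved:
                    # rotation trial: same geometry, one angle evaluation
                    if d2n > dcut2max:
                        continue
                    dn = math.sqrt(d2n)
                    if swap == 0:
                        al = math.atan2(dyn, dxn)
                        e, ok = _table_lookup(tid, dn, wn - al, ang[mm] - al,
                                              E, DMIN, D0, DSTEP, ND, N1, N2,
                                              SEC1, SEC2, DCUT)
                        if not ok:
                            return 0.0, False
                        e_old, _ = _table_lookup(tid, dn, wo - al, ang[mm] - al,
                                                 E, DMIN, D0, DSTEP, ND, N1,
                                                 N2, SEC1, SEC2, DCUT)
                    else:
                        al = math.atan2(-dyn, -dxn)
                        e, ok = _table_lookup(tid, dn, ang[mm] - al, wn - al,
                                              E, DMIN, D0, DSTEP, ND, N1, N2,
                                              SEC1, SEC2, DCUT)
                        if not ok:
                            return 0.0, False
                        e_old, _ = _table_lookup(tid, dn, ang[mm] - al, wo - al,
                                                 E, DMIN, D0, DSTEP, ND, N1,
                                                 N2, SEC1, SEC2, DCUT)
                    de += e - e_old
                    continue
                # displacement trial: new-state contribution
                if d2n <= dcut2max:
                    dn = math.sqrt(d2n)
                    if swap == 0:
                        al = math.atan2(dyn, dxn)
                        e, ok = _table_lookup(tid, dn, wn - al, ang[mm] - al,
                                              E, DMIN, D0, DSTEP, ND, N1, N2,
                                              SEC1, SEC2, DCUT)
                    else:
                        al = math.atan2(-dyn, -dxn)
                        e, ok = _table_lookup(tid, dn, ang[mm] - al, wn - al,
                                              E, DMIN, D0, DSTEP, ND, N1, N2,
                                              SEC1, SEC2, DCUT)
                    if not ok:
                        return 0.0, False
                    de += e
                # displacement trial: old-state contribution
                dxo = pos[mm, 0] - xo
                dyo = pos[mm, 1] - yo
                if periodic:
                    dxo -= boxW * round(dxo / boxW)
                    dyo -= boxH * round(dyo / boxH)
                d2o = dxo * dxo + dyo * dyo
                if d2o <= dcut2max:
                    do = math.sqrt(d2o)
                    if swap == 0:
                        al = math.atan2(dyo, dxo)
                        e, _ = _table_lookup(tid, do, wo - al, ang[mm] - al,
                                             E, DMIN, D0, DSTEP, ND, N1, N2,
                                             SEC1, SEC2, DCUT)
                    else:
                        al = math.atan2(-dyo, -dxo)
                        e, _ = _table_lookup(tid, do, ang[mm] - al, wo - al,
                                             E, DMIN, D0, DSTEP, ND, N1, N2,
                                             SEC1, SEC2, DCUT)
                    de -= e
    return de, True


@njit(cache=True, fastmath=True)
def _run_mc(pos, ang, spec, boxW, boxH, periodic,
            tid_map, swap_map, E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT,
            n_steps, t_start, t_end, disp, rot, do_disp, do_rot,
            seed, stride, cell, mobile_idx, ref_pos, max_dev):
    """Annealing main loop.  Returns (energy trace, acceptance counts).

    Only particles listed in ``mobile_idx`` receive trial moves; the
    rest form a frozen background (used for local-rearrangement
    relaxation around a gating site).
    """
    np.random.seed(seed)
    n = mobile_idx.shape[0]
    # cell edge: d_cut plus trial-move slack so one 3x3 scan covers both states
    mcell = 2
    ox, oy, cw, ch, ncx, ncy, use_cells = _cell_geometry(
        boxW, boxH, periodic, cell + 2.0 * disp, mcell)
    head, nxt = _build_cells(pos, ox, oy, cw, ch, ncx, ncy)
    dcut2max = cell * cell

    n_trace = n_steps // stride + 1
    trace = np.empty(n_trace + 1)
    acc = np.zeros(2, np.int64)
    tot = np.zeros(2, np.int64)
    order = np.empty(2 * n, np.int64)
    itr = 0

    for step in range(n_steps):
        if n_steps > 1:
            T = t_start + (t_end - t_start) * step / (n_steps - 1.0)
        else:
            T = t_start
        if step % stride == 0:
            trace[itr] = _total_energy_kernel(
                pos, ang, spec, head, nxt, ox, oy, cw, ch, ncx, ncy,
                boxW, boxH, periodic, use_cells, mcell, tid_map, swap_map,
                E, DMIN, D0, DSTEP, ND, N1, N2, SEC1, SEC2, DCUT)
            itr += 1
        for t in range(2 * n):
            order[t] = t
        for t in range(2 * n - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            tmp = order[t]
            order[t] = order[u]
            order[u] = tmp
        for t in range(2 * n):
            k = mobile_idx[order[t] >> 1]
            mt = order[t] & 1
            if mt == 0:
                if not do_disp:
                    continue
                xn = pos[k, 0] + disp * (2.0 * np.random.random() - 1.0)
                yn = pos[k, 1] + disp * (2.0 * np.random.random() - 1.0)
                wn = ang[k]
            else:
                if not do_rot:
                    continue
                xn = pos[k, 0]
                yn = pos[k, 1]
                wn = ang[k] + rot * (2.0 * np.random.random() - 1.0)
            if periodic:
                xn %= boxW
                yn %= boxH
            elif mt == 0 and max_dev < 1e17:
                # tethered relaxation: moves stay near the reference state
                rx = xn - ref_pos[k, 0]
                ry = yn - ref_pos[k, 1]
                if rx * rx + ry * ry > max_dev * max_dev:
                    continue
            tot[mt] += 1
            de, ok = _trial_delta(
                k, xn, yn, wn, mt == 0, pos, ang, spec, head, nxt, ox, oy,
                cw, ch, ncx, ncy, boxW, boxH, periodic, use_cells, mcell,
                tid_map, swap_map, E, DMIN, D0, DSTEP, ND, N1, N2, SEC1,
                SEC2, DCUT, dcut2max)
            if not ok:
                continue
            if de > 0.0:
                arg = de / T
                if arg > 700.0 or np.random.random() >= math.exp(-arg):
                    continue
            acc[mt] += 1
            if mt == 0:
                ocx, ocy = _cell_index(pos[k, 0], pos[k, 1], ox, oy, cw, ch, ncx, ncy)
                ncx2, ncy2 = _cell_index(xn, yn, ox, oy, cw, ch, ncx, ncy)
                pos[k, 0] = xn
                pos[k, 1] = yn
                if ocx != ncx2 or ocy != ncy2:
                    co = ocx * ncy + ocy
                    cn = ncx2 * ncy + ncy2
                    m = head[co]
                    if m == k:
                        head[co] = nxt[k]
                    else:
                        while nxt[m] != k:
                            m = nxt[m]
                        nxt[m] = nxt[k]
                    nxt[k] = head[cn]
                    head[cn] = k
            else:
                ang[k] = wn % 6.283185307179586
    trace[itr] = _total_energy_kernel(
        pos, ang, spec, head, nxt, ox, oy, cw, ch, ncx, ncy, boxW, boxH,
        periodic, use_cells, mcell, tid_map, swap_map, E, DMIN, D0, DSTEP,
        ND, N1, N2, SEC1, SEC2, DCUT)
    return trace[: itr + 1], acc, tot


# -- public API ------------------------------------------------------------


def total_energy(config: Configuration, tables, method: str = "cell") -> float:
    """Sum of tabulated pair energies; 'cell' (linked cells) or 'direct'.

    Both paths evaluate the identical lookup and agree exactly.
    """
    ts = tables if isinstance(tables, TableSet) else TableSet(tables)
    _check_overlaps(config, ts)
    if method == "direct":
        from .pair_potentials import pairwise_sum

        tabs = ts.tables if len(ts.tables) > 1 else ts.table_list[0]
        return pairwise_sum(config, tabs)
    W, H = config.box
    ox, oy, cw, ch, ncx, ncy, use = _cell_geometry(
        float(W), float(H), config.periodic, ts.d_cut_max, 2)
    head, nxt = _build_cells(config.positions, ox, oy, cw, ch, ncx, ncy)
    return float(_total_energy_kernel(
        config.positions, config.orientations, config.species.astype(np.int64),
        head, nxt, ox, oy, cw, ch, ncx, ncy, float(W), float(H),
        config.periodic, use, 2, *ts.as_args()))


def _check_overlaps(config: Configuration, ts: TableSet) -> None:
    for i in range(config.n):
        for j in range(i + 1, config.n):
            dvec = config.displacement(i, j)
            d = float(np.hypot(*dvec))
            if d > ts.d_cut_max:
                continue
            si, sj = int(config.species[i]), int(config.species[j])
            tab = ts.table_list[ts.tid_map[si, sj]]
            a, b = (j, i) if ts.swap_map[si, sj] else (i, j)
            dv = config.displacement(a, b)
            alpha = np.arctan2(dv[1], dv[0])
            if d < tab.min_distance_of(config.orientations[a] - alpha,
                                       config.orientations[b] - alpha):
                raise OverlapError(f"pair ({i}, {j}) at d = {d:.3f} overlaps")


def _run(config, tables, schedule, seed, do_disp, do_rot, mobile=None,
         max_dev=None):
    ts = tables if isinstance(tables, TableSet) else TableSet(tables)
    cfg = config.copy()
    seed = int(seed if seed is not None else (config.rng_seed or 0)) % (2**31)
    mobile_idx = (np.arange(cfg.n, dtype=np.int64) if mobile is None
                  else np.asarray(mobile, np.int64))
    trace, acc, tot = _run_mc(
        cfg.positions, cfg.orientations, cfg.species.astype(np.int64),
        float(cfg.box[0]), float(cfg.box[1]), cfg.periodic, *ts.as_args(),
        int(schedule.n_steps), float(schedule.t_start), float(schedule.t_end),
        float(schedule.unit_displacement), float(schedule.unit_rotation),
        do_disp, do_rot, seed, int(schedule.trace_stride),
        float(ts.d_cut_max), mobile_idx, config.positions.copy(),
        float(max_dev if max_dev is not None else 1e18),
    )
    cfg.rng_seed = seed
    stats = {
        "acceptance_displacement": acc[0] / max(1, tot[0]),
        "acceptance_rotation": acc[1] / max(1, tot[1]),
        "accepted": acc.tolist(),
        "attempted": tot.tolist(),
    }
    return cfg, np.asarray(trace), stats


def anneal(config: Configuration, tables, schedule: AnnealSchedule,
           seed: int | None = None, mobile=None, max_dev=None):
    """Simulated annealing; returns (final config, energy trace, stats).

    Deterministic for a given seed (defaults to config.rng_seed).
    ``mobile`` optionally restricts trial moves to a subset of proteins;
    ``max_dev`` tethers displacements to within that radius of each
    protein's starting position (local-rearrangement relaxations).
    """
    if config.n <= 1:
        return config.copy(), np.zeros(1), {
            "acceptance_displacement": 0.0, "acceptance_rotation": 0.0,
            "accepted": [0, 0], "attempted": [0, 0]}
    return _run(config, tables, schedule, seed, True, True, mobile, max_dev)


def mc_step(config: Configuration, tables, T: float,
            schedule: AnnealSchedule | None = None, seed: int | None = None):
    """One Monte Carlo step (N displacement + N rotation trials) at fixed T."""
    schedule = schedule or AnnealSchedule()
    one = AnnealSchedule(
        n_steps=1, t_start=T, t_end=T,
        unit_displacement=schedule.unit_displacement,
        unit_rotation=schedule.unit_rotation, trace_stride=1,
    )
    return _run(config, tables, one, seed, True, True)


def orientational_relax(config: Configuration, tables,
                        schedule: AnnealSchedule, seed: int | None = None):
    """Rotation-only annealing; positions are returned bit-identical."""
    cfg, trace, stats = _run(config, tables, schedule, seed, False, True)
    assert np.array_equal(cfg.positions, config.positions)
    return cfg, trace, stats


# -- structure analysis ----------------------------------------------------


def _neighbor_pairs(config: Configuration, cutoff_factor: float = 1.35):
    """Nearest-neighbor pairs by distance cutoff (min-image under PBC)."""
    n = config.n
    dmat = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*config.displacement(i, j)))
            dmat[i, j] = dmat[j, i] = d
    nn = dmat.min(axis=1)
    ref = np.median(nn[np.isfinite(nn)])
    cut = cutoff_factor * ref
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if dmat[i, j] < cut]
    return pairs, dmat, cut


def order_parameters(config: Configuration, cutoff_factor: float = 1.35) -> dict:
    """Bond-orientational order, neighbor statistics and row alternation.

    psi4/psi6: modulus of the mean k-fold bond-angle phase factor,
    averaged per protein over its nearest neighbors and then over
    proteins (1 for a perfect square / hexagonal lattice).  The
    row-alternation statistic is the mean of cos(s (w_i - w_j)) over
    same-species neighbor pairs: +1 for aligned neighbors, -1 for
    anti-aligned (alternating-row) order.  ``*_largest_cluster`` metrics
    restrict to the biggest connected cluster of the neighbor graph.
    """
    if config.n < 2:
        raise ValueError("need at least 2 proteins")
    pairs, dmat, cut = _neighbor_pairs(config, cutoff_factor)
    n = config.n
    neighbors = [[] for _ in range(n)]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)

    def psi(k, members=None):
        sel = range(n) if members is None else members
        vals = []
        for i in sel:
            nb = [j for j in neighbors[i] if members is None or j in members]
            if not nb:
                continue
            ph = 0.0 + 0.0j
            for j in nb:
                dx, dy = config.displacement(i, j)
                ph += np.exp(1j * k * np.arctan2(dy, dx))
            vals.append(ph / len(nb))
        return float(abs(np.mean(vals))) if vals else 0.0

    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    if pairs:
        ii, jj = np.array(pairs).T
        adj = sp.coo_matrix((np.ones(len(pairs)), (ii, jj)), shape=(n, n))
        ncomp, labels = connected_components(adj, directed=False)
    else:
        ncomp, labels = n, np.arange(n)
    sizes = np.bincount(labels)
    big = set(np.where(labels == sizes.argmax())[0])

    alt_vals = []
    for i, j in pairs:
        if config.species[i] != config.species[j]:
            continue
        s = config.shapes[config.species[i]].symmetry_order
        if s > 0:
            alt_vals.append(np.cos(s * (config.orientations[i] - config.orientations[j])))

    nn_d = [dmat[i, j] for i, j in pairs]
    return {
        "psi4": psi(4),
        "psi6": psi(6),
        "psi4_largest_cluster": psi(4, big),
        "psi6_largest_cluster": psi(6, big),
        "row_alternation": float(np.mean(alt_vals)) if alt_vals else np.nan,
        "nn_distances": np.asarray(nn_d),
        "nn_cutoff": cut,
        "n_clusters": int(ncomp),
        "largest_cluster_size": int(sizes.max()),
        "largest_cluster_members": sorted(big),
    }


# -- initial configurations ------------------------------------------------


def random_gas(shapes, counts, box, tables, seed: int = 0,
               max_tries: int = 200000) -> Configuration:
    """Random non-overlapping configuration (sequential insertion).

    ``counts[i]`` proteins of ``shapes[i]`` in a periodic box; raises
    after ``max_tries`` failed placements.
    """
    ts = tables if isinstance(tables, TableSet) else TableSet(tables)
    rng = np.random.default_rng(seed)
    W, H = box
    pos: list = []
    ori: list = []
    spc: list = []
    tries = 0
    for s, cnt in enumerate(counts):
        for _ in range(cnt):
            while True:
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        f"could not place {sum(counts)} proteins in {box}")
                x, y = rng.uniform(0, W), rng.uniform(0, H)
                w = rng.uniform(0, 2 * np.pi)
                ok = True
                for (px, py), pw, psx in zip(pos, ori, spc):
                    dx = px - x - W * round((px - x) / W)
                    dy = py - y - H * round((py - y) / H)
                    d = math.hypot(dx, dy)
                    tab = ts.table_list[ts.tid_map[s, psx]]
                    if d > tab.d_cut:
                        continue
                    alpha = math.atan2(dy, dx)
                    if ts.swap_map[s, psx]:
                        w1, w2 = pw - (alpha + np.pi), w - (alpha + np.pi)
                    else:
                        w1, w2 = w - alpha, pw - alpha
                    if d < tab.min_distance_of(w1, w2) + 0.05:
                        ok = False
                        break
                if ok:
                    pos.append((x, y))
                    ori.append(w)
                    spc.append(s)
                    break
    return Configuration(np.array(pos), np.array(ori), np.array(spc),
                         list(shapes), box, periodic=True, rng_seed=seed)
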