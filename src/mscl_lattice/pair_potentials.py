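"""Thickness-mediated pair interaction tables over (d, omega1, omega2).

The interaction energy of two proteins at center-to-center distance d
with orientations omega1, omega2 (measured from the center line) is

    E_int(d, w1, w2) = E[both] - E[A alone] - E[B alone],

each term a finite-element minimization of the thickness-deformation
energy.  Energies are tabulated on a uniform d grid and one angular
symmetry sector [0, 2 pi / s) per protein, together with the sterically
minimal center distance d_min(w1, w2); beyond the cutoff d_cut the
interaction is treated as exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Polygon

from .configuration import Configuration
from .fe_core import BilayerParams, NodalField, solve_field
from .meshing import MeshOptions, mesh_patch
from .shapes import ProteinShape, contour_points, package_defaults


class OverlapError(ValueError):
    """Configuration violates the steric minimum distance."""


def default_clearance() -> float:
    return package_defaults()["steric"]["edge_clearance"]["value"]


def default_cutoff() -> float:
    return package_defaults()["pair_table"]["d_cut"]


# -- steric minimum distance ----------------------------------------------


def min_distance(
    shapeA: ProteinShape, shapeB: ProteinShape, w1: float, w2: float,
    clearance: float | None = None, n_contour: int = 256,
) -> float:
    """Smallest center distance with edge-to-edge gap >= clearance.

    Protein A sits at the origin with orientation w1, B on the positive
    x-axis with orientation w2; the gap is the distance between the two
    contour polygons, found by bisection in the rigid separation.
    """
    if clearance is None:
        clearance = default_clearance()
    pa = Polygon(contour_points(shapeA.with_orientation(w1), n=n_contour))
    pb0 = contour_points(shapeB.with_orientation(w2), n=n_contour)

    def gap(d):
        pb = Polygon(pb0 + np.array([d, 0.0]))
        if pa.intersects(pb):
            return -clearance - 1e-6
        return pa.distance(pb) - clearance

    lo = 0.5 * (shapeA.radius + shapeB.radius)
    hi = shapeA.max_radius + shapeB.max_radius + clearance + 0.5
    while gap(lo) > 0 and lo > 1e-3:
        lo *= 0.7
    return float(brentq(gap, lo, hi, xtol=1e-4))


# -- direct FE pair energy -------------------------------------------------

_single_cache: dict = {}


def isolated_energy(
    shape: ProteinShape, params: BilayerParams, opts: MeshOptions | None = None
) -> float:
    """Deformation energy of one isolated protein (orientation-independent)."""
    opts = opts or MeshOptions()
    key = (
        shape.symmetry_order, round(shape.radius, 12), round(shape.undulation, 12),
        round(shape.mismatch, 12), params, opts.contour_points,
        opts.far_field_factor, opts.grade_distance, opts.outer_clearance,
    )
    if key not in _single_cache:
        mesh = mesh_patch([(shape.with_orientation(0.0), (0.0, 0.0))], opts=opts)
        _single_cache[key] = solve_field(mesh, params, {0: shape.mismatch}).energy
    return _single_cache[key]


def pair_energy(
    shapeA: ProteinShape, shapeB: ProteinShape, d: float, w1: float, w2: float,
    params: BilayerParams, opts: MeshOptions | None = None,
    clearance: float | None = None,
) -> float:
    """Interaction energy of one pair by three FE solves (in kBT)."""
    opts = opts or MeshOptions()
    if d < min_distance(shapeA, shapeB, w1, w2, clearance):
        raise OverlapError(f"d = {d} below steric minimum distance")
    mesh = mesh_patch(
        [
            (shapeA.with_orientation(w1), (-d / 2.0, 0.0)),
            (shapeB.with_orientation(w2), (d / 2.0, 0.0)),
        ],
        opts=opts,
    )
    e2 = solve_field(mesh, params, {0: shapeA.mismatch, 1: shapeB.mismatch}).energy
    return e2 - isolated_energy(shapeA, params, opts) - isolated_energy(shapeB, params, opts)


# -- tabulation ------------------------------------------------------------


@dataclass
class PairTable:
    """Gridded pair energies and steric minimum distances.

    energies[k, i, j] is E_int at d_grid[k], omega1_grid[i], omega2_grid[j];
    entries below d_min(i, j) hold +inf (sterically forbidden).
    """

    shapeA: ProteinShape
    shapeB: ProteinShape
    params: BilayerParams
    d_grid: np.ndarray
    omega1_grid: np.ndarray
    omega2_grid: np.ndarray
    energies: np.ndarray
    d_min: np.ndarray
    d_cut: float
    clearance: float

    @property
    def identical(self) -> bool:
        a, b = self.shapeA, self.shapeB
        return (
            a.symmetry_order == b.symmetry_order
            and np.isclose(a.radius, b.radius)
            and np.isclose(a.undulation, b.undulation)
            and np.isclose(a.mismatch, b.mismatch)
        )

    # -- lookup -----------------------------------------------------------

    def _angle_index(self, w, grid, sector):
        n = len(grid)
        return int(np.rint(np.mod(w, sector) / sector * n)) % n

    def lookup(self, d: float, w1: float, w2: float, angle_interp: bool = False) -> float:
        """Energy at (d, w1, w2): angles rounded to the grid (or bilinearly
        interpolated with ``angle_interp``), linear interpolation in d,
        exactly zero beyond d_cut."""
        if d > self.d_cut:
            return 0.0
        sA = 2 * np.pi if self.shapeA.symmetry_order == 0 else 2 * np.pi / self.shapeA.symmetry_order
        sB = 2 * np.pi if self.shapeB.symmetry_order == 0 else 2 * np.pi / self.shapeB.symmetry_order
        if not angle_interp:
            i = self._angle_index(w1, self.omega1_grid, sA)
            j = self._angle_index(w2, self.omega2_grid, sB)
            if d < self.d_min[i, j]:
                raise OverlapError(f"d = {d:.3f} < d_min = {self.d_min[i, j]:.3f}")
            return self._interp_d(d, i, j)
        # bilinear in angles (off by default; used by smooth optimizers)
        out = 0.0
        n1, n2 = len(self.omega1_grid), len(self.omega2_grid)
        t1 = np.mod(w1, sA) / sA * n1
        t2 = np.mod(w2, sB) / sB * n2
        i0, j0 = int(np.floor(t1)) % n1, int(np.floor(t2)) % n2
        f1, f2 = t1 - np.floor(t1), t2 - np.floor(t2)
        for di, wi in ((0, 1 - f1), (1, f1)):
            for dj, wj in ((0, 1 - f2), (1, f2)):
                i, j = (i0 + di) % n1, (j0 + dj) % n2
                if d < self.d_min[i, j]:
                    raise OverlapError(f"d = {d:.3f} < d_min = {self.d_min[i, j]:.3f}")
                out += wi * wj * self._interp_d(d, i, j)
        return out

    def _interp_d(self, d: float, i: int, j: int) -> float:
        dg = self.d_grid
        if d <= dg[0]:
            raise OverlapError(f"d = {d:.3f} below tabulated range")
        if d >= dg[-1]:
            # interpolate toward zero at d_cut
            if self.d_cut > dg[-1]:
                t = (d - dg[-1]) / (self.d_cut - dg[-1])
                return float(self.energies[-1, i, j] * (1 - t))
            return float(self.energies[-1, i, j])
        k = int(np.searchsorted(dg, d) - 1)
        t = (d - dg[k]) / (dg[k + 1] - dg[k])
        e0, e1 = self.energies[k, i, j], self.energies[k + 1, i, j]
        if not np.isfinite(e0):
            if d >= self.d_min[i, j] - 1e-9:
                e0 = e1  # first finite row reached by d_min; flat extrapolation
            else:
                raise OverlapError(f"d = {d:.3f} < d_min = {self.d_min[i, j]:.3f}")
        return float((1 - t) * e0 + t * e1)

    def min_distance_of(self, w1: float, w2: float) -> float:
        sA = 2 * np.pi if self.shapeA.symmetry_order == 0 else 2 * np.pi / self.shapeA.symmetry_order
        sB = 2 * np.pi if self.shapeB.symmetry_order == 0 else 2 * np.pi / self.shapeB.symmetry_order
        i = self._angle_index(w1, self.omega1_grid, sA)
        j = self._angle_index(w2, self.omega2_grid, sB)
        return float(self.d_min[i, j])

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Binary container (.npz) with a JSON metadata sidecar (.json)."""
        path = str(path)
        np.savez_compressed(
            path if path.endswith(".npz") else path + ".npz",
            d_grid=self.d_grid, omega1_grid=self.omega1_grid,
            omega2_grid=self.omega2_grid, energies=self.energies,
            d_min=self.d_min,
        )
        meta = {
            "schema": 1,
            "shapeA": self.shapeA.to_dict(),
            "shapeB": self.shapeB.to_dict(),
            "params": {
                "bending_rigidity": self.params.bending_rigidity,
                "thickness_modulus": self.params.thickness_modulus,
                "half_thickness": self.params.half_thickness,
                "tension": self.params.tension,
                "tension_couples_thickness": self.params.tension_couples_thickness,
            },
            "d_cut": self.d_cut,
            "clearance": self.clearance,
        }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "PairTable":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        arrs = np.load(base + ".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        return cls(
            shapeA=ProteinShape.from_dict(meta["shapeA"]),
            shapeB=ProteinShape.from_dict(meta["shapeB"]),
            params=BilayerParams(**meta["params"]),
            d_grid=arrs["d_grid"], omega1_grid=arrs["omega1_grid"],
            omega2_grid=arrs["omega2_grid"], energies=arrs["energies"],
            d_min=arrs["d_min"], d_cut=meta["d_cut"], clearance=meta["clearance"],
        )

    def to_dataframe(self):
        """Long-format (d, omega1, omega2, E) table."""
        import pandas as pd

        K, I, J = np.meshgrid(
            np.arange(len(self.d_grid)), np.arange(len(self.omega1_grid)),
            np.arange(len(self.omega2_grid)), indexing="ij",
        )
        return pd.DataFrame({
            "d": self.d_grid[K.ravel()],
            "omega1": self.omega1_grid[I.ravel()],
            "omega2": self.omega2_grid[J.ravel()],
            "E": self.energies.ravel(),
        })


def build_pair_table(
    shapeA: ProteinShape,
    shapeB: ProteinShape,
    params: BilayerParams,
    d_step: float | None = None,
    n_omega: int | None = None,
    d_cut: float | None = None,
    clearance: float | None = None,
    opts: MeshOptions | None = None,
    d_max: float | None = None,
    progress: bool = False,
) -> PairTable:
    """Tabulate E_int and d_min on the (d, omega1, omega2) grid by FE solves.

    One angular sector per protein exploits the exact 2 pi / s symmetry.
    For identical shapes the exchange symmetry
    E(d, w1, w2) = E(d, w2 + pi, w1 + pi) halves the number of solves.
    ``d_max`` stops the explicit tabulation early (energies then ramp to
    zero at ``d_cut`` in the lookup); default is d_cut itself.
    """
    dflt = package_defaults()["pair_table"]
    d_step = d_step if d_step is not None else dflt["d_step"]
    n_omega = n_omega if n_omega is not None else dflt["omega_points_per_sector"]
    d_cut = d_cut if d_cut is not None else dflt["d_cut"]
    clearance = clearance if clearance is not None else default_clearance()
    opts = opts or MeshOptions()

    def sector(sh):
        return 2 * np.pi if sh.symmetry_order == 0 else 2 * np.pi / sh.symmetry_order

    n1 = 1 if shapeA.symmetry_order == 0 else n_omega
    n2 = 1 if shapeB.symmetry_order == 0 else n_omega
    w1g = np.arange(n1) * sector(shapeA) / n1
    w2g = np.arange(n2) * sector(shapeB) / n2

    dmin = np.empty((n1, n2))
    for i, w1 in enumerate(w1g):
        for j, w2 in enumerate(w2g):
            dmin[i, j] = min_distance(shapeA, shapeB, w1, w2, clearance)

    d_hi = d_max if d_max is not None else d_cut
    d0 = np.floor(dmin.min() / d_step) * d_step
    d_grid = np.arange(d0, d_hi + 0.5 * d_step, d_step)

    identical = (
        shapeA.symmetry_order == shapeB.symmetry_order
        and np.isclose(shapeA.radius, shapeB.radius)
        and np.isclose(shapeA.undulation, shapeB.undulation)
        and np.isclose(shapeA.mismatch, shapeB.mismatch)
        and n1 == n2
    )

    E = np.full((len(d_grid), n1, n2), np.inf)
    sA = sector(shapeA)
    half_shift = int(round(np.mod(np.pi, sA) / sA * n1)) % n1 if identical else 0

    for i, w1 in enumerate(w1g):
        for j, w2 in enumerate(w2g):
            if identical:
                # exchange partner (w2 + pi, w1 + pi) on the grid
                ii, jj = (j + half_shift) % n1, (i + half_shift) % n2
                if (ii, jj) < (i, j) and np.isfinite(E[-1, ii, jj]):
                    E[:, i, j] = E[:, ii, jj]
                    continue
            for k, d in enumerate(d_grid):
                if d < dmin[i, j] - 1e-9:
                    continue
                E[k, i, j] = pair_energy(
                    shapeA, shapeB, d, w1, w2, params, opts, clearance
                )
            if progress:
                print(f"pair table: w1={w1:.3f} w2={w2:.3f} done", flush=True)

    return PairTable(
        shapeA=shapeA.with_orientation(0.0), shapeB=shapeB.with_orientation(0.0),
        params=params, d_grid=d_grid, omega1_grid=w1g, omega2_grid=w2g,
        energies=E, d_min=dmin, d_cut=d_cut, clearance=clearance,
    )


# -- multi-body check ------------------------------------------------------


def multibody_energy(
    config: Configuration, params: BilayerParams, opts: MeshOptions | None = None
) -> float:
    """Full-cluster interaction energy from a single FE solve.

    E_multi = E[all proteins] - sum_i E[protein i alone].
    """
    opts = opts or MeshOptions()
    mesh = mesh_patch(config.placements(), opts=opts)
    bcs = {k: sh.mismatch for k, (sh, _) in enumerate(config.placements())}
    e_all = solve_field(mesh, params, bcs).energy
    e_singles = sum(
        isolated_energy(sh, params, opts) for sh, _ in config.placements()
    )
    return e_all - e_singles


def pairwise_sum(
    config: Configuration, tables, angle_interp: bool = False
) -> float:
    """Sum of tabulated pair energies over all pairs within d_cut.

    ``tables`` maps a species pair (i, j) to a PairTable, or is a single
    PairTable applied to all pairs.
    """
    total = 0.0
    for i in range(config.n):
        for j in range(i + 1, config.n):
            total += pair_lookup(config, tables, i, j, angle_interp)
    return total


def pair_lookup(config: Configuration, tables, i: int, j: int,
                angle_interp: bool = False) -> float:
    """Tabulated interaction of pair (i, j) in the configuration's frame.

    The table stores energies with protein A at the origin and B on the
    +x axis, so the lookup angles are the orientations measured from the
    center line; a (B, A)-ordered query swaps the roles.
    """
    if isinstance(tables, PairTable):
        table = tables
    else:
        si, sj = int(config.species[i]), int(config.species[j])
        if (si, sj) in tables:
            table = tables[(si, sj)]
        else:
            table = tables[(sj, si)]
            i, j = j, i
    dvec = config.displacement(i, j)
    d = float(np.hypot(*dvec))
    if d > table.d_cut:
        return 0.0
    alpha = float(np.arctan2(dvec[1], dvec[0]))
    return table.lookup(
        d, config.orientations[i] - alpha, config.orientations[j] - alpha,
        angle_interp,
    )


def nonpairwise_deviation(
    config: Configuration, tables, params: BilayerParams,
    opts: MeshOptions | None = None, per_protein: bool = False,
) -> float:
    """Difference between the multi-body FE energy and the two-body sum."""
    if config.n < 2:
        raise ValueError("need at least 2 proteins")
    dev = multibody_energy(config, params, opts) - pairwise_sum(config, tables)
    return dev / config.n if per_protein else dev
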