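"""Candidate lattice architectures of MscL clusters and their energies.

Finite clusters are scored by summing tabulated pair potentials (or by a
full multi-body FE solve for small clusters); infinite lattices by FE
solves on rectangular mirror-symmetry unit cells whose edges carry zero
normal slope of the thickness field.

Orientation schemes are defined geometrically with respect to the bond
along +x: "face-on" points a lobe trough (contour minimum) at the
neighbor, "tip-on" a lobe peak, "horizontal" keeps omega = 0, and
"alternating-rows" gives consecutive rows orientations omega0 and
omega0 + pi/s (anti-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .configuration import Configuration
from .fe_core import BilayerParams, solve_field
from .meshing import MeshOptions, mesh_unit_cell
from .pair_potentials import OverlapError, min_distance
from .shapes import ProteinShape, enclosed_area

FAMILIES = ("honeycomb", "square", "shifted-square", "hexagonal",
            "distorted-A", "distorted-B")
SCHEMES = ("face-on", "tip-on", "horizontal", "optimized", "alternating-rows")


class SymmetryViolationError(ValueError):
    """Orientation scheme incompatible with the unit cell's mirror lines."""


class PackingError(ValueError):
    """Requested packing violates steric constraints."""


@dataclass
class LatticeSpec:
    family: str
    spacing: float | None = None           # nearest-neighbor d (nm)
    packing_fraction: float | None = None  # phi, for distorted families
    orientation_scheme: str = "face-on"
    size: int = 4                          # linear size L (N ~ L^2)
    infinite: bool = False
    # free parameters of the distorted families (optimized if None)
    distort_params: tuple | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.orientation_scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.orientation_scheme!r}")
        distorted = self.family.startswith("distorted")
        if distorted and self.packing_fraction is None:
            raise ValueError("distorted families are parameterized by phi")
        if not distorted and self.spacing is None and not self.infinite:
            raise ValueError("spacing d required for regular families")


def face_on_angle(shape: ProteinShape) -> float:
    """Orientation pointing a contour minimum along +x (pi/s)."""
    s = shape.symmetry_order
    return 0.0 if s == 0 else np.pi / s


def tip_on_angle(shape: ProteinShape) -> float:
    return 0.0


def _scheme_angle(scheme: str, shape: ProteinShape) -> float:
    if scheme == "face-on":
        return face_on_angle(shape)
    if scheme in ("tip-on", "horizontal", "alternating-rows", "optimized"):
        return tip_on_angle(shape) if scheme == "tip-on" else 0.0
    raise ValueError(scheme)


# -- site generators -------------------------------------------------------


def _sites(family: str, d: float, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Site positions and row indices for ~L^2 sites of a regular family."""
    if family == "square":
        ij = np.array([(i, j) for j in range(L) for i in range(L)], float)
        pos = ij * d
        rows = ij[:, 1].astype(int)
    elif family == "shifted-square":
        pos = []
        rows = []
        for j in range(L):
            for i in range(L):
                pos.append(((i + 0.5 * (j % 2)) * d, j * d))
                rows.append(j)
        pos = np.array(pos)
        rows = np.array(rows)
    elif family == "hexagonal":
        pos = []
        rows = []
        for j in range(L):
            for i in range(L):
                pos.append(((i + 0.5 * (j % 2)) * d, j * d * np.sqrt(3) / 2))
                rows.append(j)
        pos = np.array(pos)
        rows = np.array(rows)
    elif family == "honeycomb":
        # rectangular 4-site tiling cell (sqrt(3) d x 3 d)
        base = np.array([(0.0, 0.5), (0.0, 2.5), (np.sqrt(3) / 2, 1.0),
                         (np.sqrt(3) / 2, 2.0)]) * d
        reps = max(1, int(np.ceil(L / 2)))
        pos = []
        rows = []
        for cx in range(reps):
            for cy in range(reps):
                for b, (bx, by) in enumerate(base):
                    pos.append((bx + cx * np.sqrt(3) * d, by + cy * 3 * d))
                    rows.append(2 * cy + (b > 1))
        pos = np.array(pos)
        rows = np.array(rows)
        n_target = L * L
        if len(pos) > n_target:
            center = pos.mean(axis=0)
            order = np.argsort(np.linalg.norm(pos - center, axis=1), kind="stable")
            keep = np.sort(order[:n_target])
            pos, rows = pos[keep], rows[keep]
    else:
        raise ValueError(family)
    return pos, np.asarray(rows)


def build_lattice(spec: LatticeSpec, shape: ProteinShape,
                  clearance: float | None = None) -> Configuration:
    """Construct a finite lattice cluster as a (non-periodic) Configuration."""
    if spec.family == "distorted-A":
        return _build_distorted_a(spec, shape)
    if spec.family == "distorted-B":
        return _build_distorted_b(spec, shape)
    d, L = spec.spacing, spec.size
    pos, rows = _sites(spec.family, d, L)
    w0 = _scheme_angle(spec.orientation_scheme, shape)
    if spec.orientation_scheme == "alternating-rows" and shape.symmetry_order:
        ori = w0 + (rows % 2) * np.pi / shape.symmetry_order
    else:
        ori = np.full(len(pos), w0)
    return _as_config(pos, ori, shape)


def _as_config(pos, ori, shape) -> Configuration:
    pos = np.asarray(pos, float)
    margin = 2 * shape.max_radius + 14.0
    pos = pos - pos.min(axis=0) + margin
    box = tuple(pos.max(axis=0) + margin)
    return Configuration(pos, np.asarray(ori, float),
                         np.zeros(len(pos), int), [shape], box, periodic=False)


def _build_distorted_a(spec: LatticeSpec, shape: ProteinShape) -> Configuration:
    """Distorted hexagonal lattice, alternate rows anti-aligned.

    Parameterized by (aspect, shift, omega0): row pitch hy and in-row
    spacing dx with dx * hy = A_protein / phi, alternate rows offset by
    shift * dx and rotated by pi/s.
    """
    phi = spec.packing_fraction
    area = enclosed_area(shape)
    aspect, shift, w0 = spec.distort_params or (2 / np.sqrt(3), 0.5, 0.0)
    dx = np.sqrt(area / phi * aspect)
    hy = area / phi / dx
    s = shape.symmetry_order
    L = spec.size
    pos = []
    ori = []
    for j in range(L):
        for i in range(L):
            pos.append((i * dx + (j % 2) * shift * dx, j * hy))
            ori.append(w0 + (j % 2) * (np.pi / s if s else 0.0))
    return _as_config(pos, ori, shape)


def _build_distorted_b(spec: LatticeSpec, shape: ProteinShape) -> Configuration:
    """Face-on triangles of three proteins tiled on a hexagonal superlattice.

    Parameterized by (t_rel, omega0): the triangle edge t = t_rel *
    d_face-face; the superlattice constant follows from phi.
    """
    phi = spec.packing_fraction
    area = enclosed_area(shape)
    s = shape.symmetry_order
    t_rel, w0 = spec.distort_params or (1.0, 0.0)
    d_ff = min_distance(shape, shape, np.pi / s if s else 0.0, 0.0)
    t = t_rel * d_ff
    # 3 proteins per supercell of area (sqrt(3)/2) A^2 -> A from phi
    A = np.sqrt(3 * area / phi / (np.sqrt(3) / 2))
    tri = t / np.sqrt(3) * np.array(
        [(np.cos(a), np.sin(a)) for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                                          np.pi / 2 + 4 * np.pi / 3)])
    # orient each protein to face the triangle center (inward bonds)
    base_ori = []
    for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
        inward = a + np.pi
        base_ori.append(inward + (np.pi / s if s else 0.0) + w0)
    L = max(2, int(np.ceil(spec.size / np.sqrt(3))))
    pos = []
    ori = []
    for j in range(L):
        for i in range(L):
            cx = (i + 0.5 * (j % 2)) * A
            cy = j * A * np.sqrt(3) / 2
            for (tx, ty), bo in zip(tri, base_ori):
                pos.append((cx + tx, cy + ty))
                ori.append(bo)
    n_target = spec.size**2
    pos = np.asarray(pos)
    ori = np.asarray(ori)
    if len(pos) > n_target:
        center = pos.mean(axis=0)
        order = np.argsort(np.linalg.norm(pos - center, axis=1), kind="stable")
        keep = np.sort(order[:n_target])
        pos, ori = pos[keep], ori[keep]
    return _as_config(pos, ori, shape)


def check_steric(config: Configuration, clearance: float | None = None) -> float:
    """Smallest contour-to-contour gap over near pairs; < 0 means overlap."""
    from shapely.geometry import Polygon

    from .shapes import contour_points

    polys = [Polygon(contour_points(sh.with_orientation(w), center=c, n=128))
             for (sh, c), w in zip(config.placements(), config.orientations)]
    reach = 2 * max(sh.max_radius for sh in config.shapes) + 1.0
    gap = np.inf
    for i in range(config.n):
        for j in range(i + 1, config.n):
            if float(np.hypot(*config.displacement(i, j))) > reach:
                continue
            if polys[i].intersects(polys[j]):
                return -1.0
            gap = min(gap, polys[i].distance(polys[j]))
    return float(gap)


# -- energies --------------------------------------------------------------


def lattice_energy_finite(spec: LatticeSpec, shape: ProteinShape, scorer,
                          mode: str = "pairwise",
                          opts: MeshOptions | None = None) -> float:
    """Interaction energy per protein of a finite cluster.

    ``scorer`` is a PairTable/TableSet (pairwise mode) or BilayerParams
    (multibody-FE mode, practical for N up to ~25).
    """
    config = build_lattice(spec, shape)
    return configuration_energy(config, scorer, mode, opts) / config.n


def configuration_energy(config: Configuration, scorer, mode: str = "pairwise",
                         opts: MeshOptions | None = None) -> float:
    if mode == "pairwise":
        from .monte_carlo import total_energy

        return total_energy(config, scorer)
    if mode == "multibody-FE":
        from .pair_potentials import multibody_energy

        return multibody_energy(config, scorer, opts)
    raise ValueError(mode)


_CELL_BUILDERS = {}


def _cell_square(d):
    sites = [(0.0, 0.0), (d, 0.0), (0.0, d), (d, d)]
    return (d, d), sites, [0, 0, 0, 0]


def _cell_shifted_square(d):
    sites = [(0, 0), (d, 0), (0, 2 * d), (d, 2 * d), (d / 2, d),
             (-d / 2, d), (3 * d / 2, d), (d / 2, -d), (d / 2, 3 * d)]
    rows = [0, 0, 0, 0, 1, 1, 1, 1, 1]
    return (d, 2 * d), sites, rows


def _cell_hexagonal(d):
    w, h = d, d * np.sqrt(3)
    sites = [(0, 0), (d, 0), (0, h), (d, h), (d / 2, h / 2),
             (-d / 2, h / 2), (3 * d / 2, h / 2)]
    rows = [0, 0, 0, 0, 1, 1, 1]
    return (w, h), sites, rows


def _cell_honeycomb(d):
    w, h = d * np.sqrt(3), 3 * d
    sites = [(0, 0.5 * d), (0, 2.5 * d), (w / 2, d), (w / 2, 2 * d),
             (w, 0.5 * d), (w, 2.5 * d), (0, -0.5 * d), (0, 3.5 * d),
             (w, -0.5 * d), (w, 3.5 * d), (-w / 2, d), (-w / 2, 2 * d),
             (3 * w / 2, d), (3 * w / 2, 2 * d)]
    rows = [0] * len(sites)
    return (w, h), sites, rows


def lattice_energy_infinite(spec: LatticeSpec, shape: ProteinShape,
                            params: BilayerParams,
                            opts: MeshOptions | None = None) -> float:
    """Energy per protein of an infinite lattice from a symmetry unit cell.

    The rectangular cell's edges are mirror lines of the lattice, so the
    thickness field has zero normal slope there; the FE energy of the
    cell divided by the protein area fraction gives the energy per
    protein, and the isolated-protein energy is subtracted to leave the
    interaction part.
    """
    mesh, frac = build_symmetry_cell(spec, shape, opts)
    field = solve_field(mesh, params,
                        {k: shape.mismatch for k in
                         range(int(mesh.node_tags.max()))})
    from .pair_potentials import isolated_energy

    e_single = isolated_energy(shape, params, opts)
    return field.energy / frac - e_single


def build_symmetry_cell(spec: LatticeSpec, shape: ProteinShape,
                        opts: MeshOptions | None = None):
    """Mesh the mirror-symmetry unit cell; returns (mesh, protein fraction).

    Raises SymmetryViolationError for orientation schemes that break the
    cell's mirror lines (any five-fold shape; schemes other than
    face-on / tip-on / horizontal for four-fold shapes).
    """
    d = spec.spacing
    if d is None:
        raise ValueError("infinite lattices need a spacing d")
    s = shape.symmetry_order
    if s == 5:
        raise SymmetryViolationError(
            "five-fold contours break the rectangular cell mirror lines")
    if spec.orientation_scheme in ("optimized", "alternating-rows"):
        raise SymmetryViolationError(
            f"{spec.orientation_scheme} scheme has no mirror-symmetric cell here")
    builders = {
        "square": _cell_square, "shifted-square": _cell_shifted_square,
        "hexagonal": _cell_hexagonal, "honeycomb": _cell_honeycomb,
    }
    if spec.family not in builders:
        raise SymmetryViolationError(f"no symmetry cell for {spec.family}")
    (w, h), sites, rows = builders[spec.family](d)
    w0 = _scheme_angle(spec.orientation_scheme, shape)
    placements = []
    for (x, y), r in zip(sites, rows):
        placements.append((shape.with_orientation(w0), (x, y)))
    reach = shape.max_radius
    placements = [
        (sh, (x, y)) for sh, (x, y) in placements
        if -reach < x < w + reach and -reach < y < h + reach
    ]
    mesh = mesh_unit_cell(placements, (0.0, 0.0), (w, h), opts)
    return mesh, mesh.protein_fraction


# -- scans and rankings ----------------------------------------------------


def ground_state_scan(shape: ProteinShape, candidates: list[LatticeSpec],
                      scorer, d_values=None, mode: str = "pairwise",
                      params: BilayerParams | None = None,
                      opts: MeshOptions | None = None):
    """Score candidate lattices over a d (or phi) range; rank the minima.

    Returns a pandas DataFrame with one row per (candidate, d) and a
    summary ranking by minimum energy; deterministic in candidate order.
    """
    import pandas as pd

    rows = []
    for ci, spec in enumerate(candidates):
        vals = d_values if d_values is not None else [spec.spacing]
        for v in vals:
            sp = replace(spec, spacing=v) if not spec.family.startswith("distorted") \
                else replace(spec, packing_fraction=v)
            try:
                if sp.infinite:
                    e = lattice_energy_infinite(sp, shape, params, opts)
                else:
                    e = lattice_energy_finite(sp, shape, scorer, mode, opts)
            except (OverlapError, PackingError):
                e = np.inf
            rows.append({
                "candidate": ci, "family": sp.family,
                "scheme": sp.orientation_scheme, "x": v, "energy": e,
            })
    df = pd.DataFrame(rows)
    best = df.loc[df.groupby("candidate")["energy"].idxmin()]
    best = best.sort_values("energy").reset_index(drop=True)
    best["rank"] = np.arange(1, len(best) + 1)
    return df, best


def crossover_spacings(df) -> list[dict]:
    """Sign changes of pairwise energy differences on the scan grid."""
    out = []
    cands = sorted(df["candidate"].unique())
    for a in cands:
        for b in cands:
            if b <= a:
                continue
            da = df[df.candidate == a].sort_values("x")
            db = df[df.candidate == b].sort_values("x")
            x = np.intersect1d(da["x"], db["x"])
            ea = da.set_index("x").loc[x, "energy"].to_numpy()
            eb = db.set_index("x").loc[x, "energy"].to_numpy()
            diff = ea - eb
            ok = np.isfinite(diff)
            x, diff = x[ok], diff[ok]
            for k in range(len(diff) - 1):
                if diff[k] * diff[k + 1] < 0:
                    t = diff[k] / (diff[k] - diff[k + 1])
                    out.append({"a": a, "b": b,
                                "x": float(x[k] + t * (x[k + 1] - x[k]))})
    return out


def boundary_scaling(spec_a: LatticeSpec, spec_b: LatticeSpec,
                     shape: ProteinShape, L_values, scorer,
                     mode: str = "pairwise") -> dict:
    """Finite-size decay of the per-protein energy difference of two families.

    Fits dE(L) = dE_inf + c * L^(-p); returns samples and fit parameters.
    """
    L_values = list(L_values)
    if len(L_values) < 3:
        raise ValueError("need at least 3 cluster sizes")
    diffs = []
    for L in L_values:
        ea = lattice_energy_finite(replace(spec_a, size=L), shape, scorer, mode)
        eb = lattice_energy_finite(replace(spec_b, size=L), shape, scorer, mode)
        diffs.append(ea - eb)
    diffs = np.asarray(diffs)
    from scipy.optimize import curve_fit

    def model(L, dinf, c, p):
        return dinf + c * np.asarray(L, float) ** (-p)

    p0 = (diffs[-1], (diffs[0] - diffs[-1]) * L_values[0], 1.0)
    try:
        popt, _ = curve_fit(model, L_values, diffs, p0=p0, maxfev=20000)
        dinf, c, p = popt
    except RuntimeError:
        dinf, c, p = diffs[-1], np.nan, np.nan
    return {"L": np.asarray(L_values), "dE": diffs, "dE_inf": float(dinf),
            "prefactor": float(c), "exponent": float(p)}


# -- distorted-family optimization ----------------------------------------


def optimize_distorted_a(shape: ProteinShape, table, phi: float,
                         size: int = 9, n_starts: int = 4, seed: int = 0):
    """Minimize the distorted-A energy per protein over (aspect, shift, w0).

    Bound-constrained Nelder-Mead from several starts; returns
    (best LatticeSpec, energy per protein). Infeasible (sterically
    overlapping) parameter points score +inf.
    """
    from scipy.optimize import minimize

    from .monte_carlo import total_energy

    rng = np.random.default_rng(seed)
    s = shape.symmetry_order

    def objective(x):
        aspect, shift, w0 = x
        if not (0.5 <= aspect <= 2.5 and 0.0 <= shift <= 1.0):
            return 1e6
        spec = LatticeSpec("distorted-A", packing_fraction=phi, size=size,
                           distort_params=(aspect, shift, w0 % (np.pi / s)))
        cfg = build_lattice(spec, shape)
        try:
            return total_energy(cfg, table) / cfg.n
        except OverlapError:
            return 1e6

    # candidate starts: the canonical hexagonal shear points probed by
    # the packing-feasibility search, plus random perturbations; only
    # feasible starts seed the simplex (the objective is +1e6 on the
    # infeasible set, where Nelder-Mead cannot move)
    starts = [(a, sh, w) for a in (1.0, 2 / np.sqrt(3), 1.4)
              for sh in (0.5, 0.3) for w in (0.0, 0.5 * np.pi / s)]
    for _ in range(max(n_starts, 2)):
        starts.append((rng.uniform(0.7, 1.8), rng.uniform(0.1, 0.9),
                       rng.uniform(0, np.pi / s)))
    scored = sorted(starts, key=objective)
    best = None
    for x0 in scored[:max(n_starts, 2)]:
        if objective(x0) >= 1e6:
            continue
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": 150, "xatol": 1e-3, "fatol": 1e-3})
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise PackingError(f"no feasible distorted-A parameterization at phi={phi}")
    aspect, shift, w0 = best.x
    spec = LatticeSpec("distorted-A", packing_fraction=phi, size=size,
                       distort_params=(aspect, shift, w0 % (np.pi / s)))
    return spec, float(best.fun)


def max_packing_fraction(shape: ProteinShape, family: str, table=None,
                         clearance: float | None = None, size: int = 9,
                         tol: float = 1e-3) -> float:
    """Largest feasible phi for a lattice family, by bisection on phi.

    For regular families the spacing is reduced to the steric limit; for
    distorted-A the free parameters are re-optimized for feasibility at
    each phi (energy-blind: any non-overlapping configuration counts).
    Feasibility uses the exact contour gaps, or the table's
    rounded-angle d_min rule when a PairTable is given (the same steric
    model the Monte Carlo and table-scored energies apply).
    """
    from .pair_potentials import default_clearance

    if clearance is None:
        clearance = default_clearance()
    area = enclosed_area(shape)

    def config_ok(cfg):
        if table is None:
            return check_steric(cfg) >= clearance - 1e-6
        from .monte_carlo import total_energy

        try:
            total_energy(cfg, table)
            return True
        except OverlapError:
            return False

    def feasible(phi):
        if family == "distorted-A":
            # try default and a few shifted parameterizations
            s = shape.symmetry_order
            for aspect in (1.0, 2 / np.sqrt(3), 1.4):
                for shift in (0.5, 0.3):
                    spec = LatticeSpec("distorted-A", packing_fraction=phi,
                                       size=size, distort_params=(aspect, shift, 0.0))
                    cfg = build_lattice(spec, shape)
                    if config_ok(cfg):
                        return True
            return False
        if family == "hexagonal":
            d = np.sqrt(area / phi / (np.sqrt(3) / 2))
            spec = LatticeSpec("hexagonal", spacing=d, size=size,
                               orientation_scheme="horizontal")
            cfg = build_lattice(spec, shape)
            return config_ok(cfg)
        raise ValueError(family)

    lo, hi = 0.2, 0.95
    if not feasible(lo):
        raise PackingError("lower packing bound already infeasible")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo
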