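"""Triangulation of the membrane patch around protein footprints.

The bilayer midplane region outside the protein contours is meshed with
graded conforming triangles: contour-offset rings (via polygon buffering)
resolve the elastic boundary layer near each protein, grading into a
coarser hexagonal background point set in the far field; the point cloud
is triangulated by Delaunay and triangles covering protein interiors are
removed.  Boundary edges are tagged ``protein:k``, ``outer`` or
``symmetry:x`` / ``symmetry:y`` (mirror lines of a lattice unit cell).

All coordinates are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .shapes import ProteinShape, contour_points, perimeter

TAG_INTERIOR = 0
TAG_OUTER = -1
TAG_SYM_X = -2   # edge with normal along x: fix d u/d x
TAG_SYM_Y = -3   # edge with normal along y: fix d u/d y
TAG_GAP = -9     # transient: gap-refinement points (become interior)
# protein k -> tag k+1



def _cross2(a, b):
    """z-component of the cross product of 2-D vectors (batched)."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

class GeometryError(ValueError):
    """Overlapping contours or otherwise invalid input geometry."""


class DomainTooSmallError(ValueError):
    """Outer boundary too close to a protein contour."""


@dataclass
class MeshOptions:
    """Mesh grading controls.

    h_near defaults to (contour perimeter)/contour_points per protein;
    h_far = far_field_factor * h_near.  The grading ramps linearly from
    h_near at a contour to h_far at distance grade_distance.
    """

    contour_points: int = 100
    far_field_factor: float = 4.0
    grade_distance: float = 3.0     # nm, boundary-layer extent (~3 decay lengths)
    outer_clearance: float = 9.0    # nm beyond outermost contour (~10 decay lengths)
    smooth_iters: int = 1


@dataclass
class TriMesh:
    nodes: np.ndarray               # (N, 2)
    triangles: np.ndarray           # (M, 3), CCW
    node_tags: np.ndarray           # (N,) int, see TAG_* / protein k+1
    boundary_edges: np.ndarray      # (E, 2)
    boundary_edge_tags: np.ndarray  # (E,) int
    protein_fraction: float = 1.0   # proteins contained in the domain (unit cells < full count)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def validate(self) -> None:
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            raise GeometryError(f"{np.sum(areas <= 0)} non-positive-area triangles")
        # conformity: interior edges shared by exactly 2 triangles
        edges = _all_edges(self.triangles)
        uniq, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
        if np.any(counts > 2):
            raise GeometryError("non-conforming mesh: edge shared by >2 triangles")


def _all_edges(tris: np.ndarray) -> np.ndarray:
    return np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])


def _boundary_edges(tris: np.ndarray) -> np.ndarray:
    edges = np.sort(_all_edges(tris), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq[counts == 1]


def _resample_ring(coords: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polyline at ~uniform arclength spacing."""
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[:1]])
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / spacing)), 8)
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, arc, coords[:, 0])
    y = np.interp(t, arc, coords[:, 1])
    return np.column_stack([x, y])


def _hex_grid(bounds, spacing: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    dy = spacing * np.sqrt(3) / 2
    rows = []
    y = ymin
    row = 0
    while y <= ymax:
        xs = np.arange(xmin + (0.5 * spacing if row % 2 else 0.0), xmax + 1e-12, spacing)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


@dataclass
class _Placed:
    shape: ProteinShape
    center: tuple
    polygon: Polygon
    h_near: float     # target interior spacing near the contour
    h_contour: float  # actual contour sampling (>= 40 s points per turn)


def _place(placements, opts: MeshOptions) -> list[_Placed]:
    out = []
    for shape, center in placements:
        per = perimeter(shape)
        h_near = per / opts.contour_points
        # lobe tips are sharply curved: never sample the contour itself
        # below 40 points per symmetry repeat
        n_contour = max(opts.contour_points, 40 * max(1, shape.symmetry_order))
        ring = contour_points(shape, center=center, n=n_contour)
        out.append(_Placed(shape, tuple(center), Polygon(ring), h_near,
                           per / n_contour))
    return out


def _check_overlaps(placed: list[_Placed], clearance: float = 0.0) -> None:
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            dist = placed[i].polygon.distance(placed[j].polygon)
            if placed[i].polygon.intersects(placed[j].polygon) or dist < clearance:
                raise GeometryError(
                    f"protein contours {i} and {j} overlap or violate clearance "
                    f"(gap {dist:.3f} nm)"
                )


def _near_field_points(p: _Placed, h_far: float, grade: float):
    """Graded point bands around one contour: hex grids of increasing
    spacing restricted to distance bands from the contour.

    Distance-based bands (rather than offset curves) fill the concave
    valleys between lobes reliably; the target spacing ramps linearly
    from h_near at the contour to h_far at ``grade``.
    """
    bands = []
    h0, ratio = p.h_near, 1.45
    d_lo = 0.45 * h0
    level = 0
    while d_lo < grade + h_far:
        spacing = min(h0 * ratio**level, h_far)
        # band where the sizing function is ~this spacing
        d_hi = grade * (spacing * ratio - h0) / max(h_far - h0, 1e-9)
        d_hi = max(d_hi, d_lo + spacing)
        outer = p.polygon.buffer(d_hi)
        cand = _hex_grid(outer.bounds, spacing)
        if len(cand):
            dist = shapely.distance(
                shapely.points(cand[:, 0], cand[:, 1]), p.polygon)
            keep = (dist > d_lo) & (dist <= d_hi)
            if keep.any():
                bands.append((cand[keep], spacing))
        d_lo = d_hi
        level += 1
        if spacing >= h_far:
            break
    return bands


def _dedupe(groups: Sequence[np.ndarray], spacings: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Accept points group by group, dropping points too close to accepted ones.

    Returns (points, group_index). Earlier groups have priority.
    """
    accepted = []
    gidx = []
    tree = None
    for g, (pts, sp) in enumerate(zip(groups, spacings)):
        if len(pts) == 0:
            continue
        if tree is None:
            keep = np.ones(len(pts), bool)
        else:
            d, _ = tree.query(pts, k=1)
            keep = d > 0.55 * sp
        pts = pts[keep]
        # thin within the group as well
        if len(pts):
            sub = cKDTree(pts)
            pairs = sub.query_pairs(0.45 * sp, output_type="ndarray")
            drop = np.zeros(len(pts), bool)
            for a, b in pairs:
                if not drop[a] and not drop[b]:
                    drop[b] = True
            pts = pts[~drop]
        accepted.append(pts)
        gidx.append(np.full(len(pts), g))
        allpts = np.vstack(accepted)
        tree = cKDTree(allpts)
    return np.vstack(accepted), np.concatenate(gidx)


def _build_mesh(
    placed: list[_Placed],
    outer_pts: np.ndarray,
    outer_tag_fn,
    domain_poly: Polygon,
    opts: MeshOptions,
    protein_fraction: float,
) -> TriMesh:
    h_nears = [p.h_near for p in placed]
    h_far = opts.far_field_factor * (max(h_nears) if h_nears else 1.0)

    groups: list[np.ndarray] = []
    spacings: list[float] = []
    tags: list[int] = []

    # 1) contour nodes (highest priority), clipped to the domain
    for k, p in enumerate(placed):
        ring = np.asarray(p.polygon.exterior.coords)[:-1]
        inside = shapely.contains_xy(domain_poly.buffer(1e-9), ring[:, 0], ring[:, 1])
        pts = ring[inside]
        # contour / domain-edge crossings must be mesh nodes
        inter = p.polygon.exterior.intersection(domain_poly.exterior)
        if not inter.is_empty:
            xpts = np.asarray(
                [g.coords[0] for g in getattr(inter, "geoms", [inter]) if g.geom_type == "Point"]
            )
            if len(xpts):
                pts = np.vstack([pts, xpts])
        groups.append(pts)
        spacings.append(p.h_contour)
        tags.append(k + 1)

    # 2) outer / symmetry boundary nodes
    groups.append(outer_pts)
    spacings.append(0.8 * h_far)
    tags.append(TAG_OUTER)  # refined per-node below via outer_tag_fn

    # 2b) extra points in narrow inter-protein gaps: without them,
    # elements span the gap and the bending energy is grossly wrong
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            pi, pj = placed[i], placed[j]
            h = min(pi.h_near, pj.h_near)
            g = pi.polygon.distance(pj.polygon)
            if g <= 0 or g > 4.0 * h:
                continue
            h_gap = max(g / 3.0, 0.25 * h)
            pad = g + 2.0 * h
            zone = pi.polygon.buffer(pad).intersection(pj.polygon.buffer(pad))
            if zone.is_empty:
                continue
            cand = _hex_grid(zone.bounds, h_gap)
            if not len(cand):
                continue
            inside = shapely.contains_xy(zone, cand[:, 0], cand[:, 1])
            cand = cand[inside]
            keep = np.ones(len(cand), bool)
            for p in (pi, pj):
                dist = shapely.distance(
                    shapely.points(cand[:, 0], cand[:, 1]), p.polygon)
                keep &= dist > 0.4 * h_gap
            groups.append(cand[keep])
            spacings.append(h_gap)
            tags.append(TAG_GAP)

    # 3) graded rings
    for p in placed:
        for band_pts, band_h in _near_field_points(p, h_far, opts.grade_distance):
            groups.append(band_pts)
            spacings.append(band_h)
            tags.append(TAG_INTERIOR)

    # 4) background grid
    groups.append(_hex_grid(domain_poly.bounds, h_far))
    spacings.append(h_far)
    tags.append(TAG_INTERIOR)

    pts, gidx = _dedupe(groups, spacings)
    node_tags = np.array([tags[g] for g in gidx])

    # drop free points outside the domain or inside a protein
    margin = 0.35 * h_far
    free = node_tags == TAG_INTERIOR
    ok = np.ones(len(pts), bool)
    dom_shrunk = domain_poly.buffer(-margin)
    ok[free] &= shapely.contains_xy(dom_shrunk, pts[free, 0], pts[free, 1])
    for p in placed:
        blocked = p.polygon.buffer(0.55 * p.h_near)
        ok[free] &= ~shapely.contains_xy(blocked, pts[free, 0], pts[free, 1])
    pts, node_tags = pts[ok], node_tags[ok]
    # gap-refinement points behave as ordinary interior nodes from here on
    node_tags = np.where(node_tags == TAG_GAP, TAG_INTERIOR, node_tags)

    tris = _triangulate_and_clean(pts, placed, domain_poly)

    # Laplacian smoothing of free interior nodes, then re-triangulate
    for _ in range(opts.smooth_iters):
        pts = _smooth(pts, tris, node_tags)
        tris = _triangulate_and_clean(pts, placed, domain_poly)

    # drop nodes that lost all triangles
    used = np.zeros(len(pts), bool)
    used[tris.ravel()] = True
    remap = -np.ones(len(pts), int)
    remap[used] = np.arange(used.sum())
    pts, node_tags = pts[used], node_tags[used]
    tris = remap[tris]

    # bandwidth-reducing node order (keeps sparse factorizations cheap)
    pts, node_tags, tris = _rcm_renumber(pts, node_tags, tris)

    bedges = _boundary_edges(tris)
    bet = np.empty(len(bedges), int)
    for i, (na, nb) in enumerate(bedges):
        ta, tb = node_tags[na], node_tags[nb]
        if ta == tb and ta > 0:
            bet[i] = ta
        elif ta > 0 or tb > 0:
            bet[i] = max(ta, tb)
        else:
            bet[i] = outer_tag_fn(pts[na], pts[nb])
    # refine tags of non-protein boundary nodes: a node on two
    # perpendicular mirror lines must fix both gradient components
    seen_x = np.zeros(len(pts), bool)
    seen_y = np.zeros(len(pts), bool)
    seen_out = np.zeros(len(pts), bool)
    for (na, nb), t in zip(bedges, bet):
        if t == TAG_SYM_X:
            seen_x[[na, nb]] = True
        elif t == TAG_SYM_Y:
            seen_y[[na, nb]] = True
        elif t == TAG_OUTER:
            seen_out[[na, nb]] = True
    nonprot = node_tags <= 0
    node_tags = np.where(nonprot & seen_out, TAG_OUTER, node_tags)
    node_tags = np.where(nonprot & seen_x & ~seen_y, TAG_SYM_X, node_tags)
    node_tags = np.where(nonprot & seen_y & ~seen_x, TAG_SYM_Y, node_tags)
    node_tags = np.where(nonprot & seen_x & seen_y, TAG_SYM_XY, node_tags)

    mesh = TriMesh(pts, tris, node_tags, bedges, bet, protein_fraction)
    mesh.validate()
    return mesh


TAG_SYM_XY = TAG_SYM_X * 10 + TAG_SYM_Y  # both gradient components fixed


def _rcm_renumber(pts, node_tags, tris):
    import scipy.sparse as sp
    from scipy.sparse.csgraph import reverse_cuthill_mckee

    n = len(pts)
    i = np.concatenate([tris[:, [0, 1, 2]].ravel(), tris[:, [1, 2, 0]].ravel()])
    j = np.concatenate([tris[:, [1, 2, 0]].ravel(), tris[:, [0, 1, 2]].ravel()])
    adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    perm = reverse_cuthill_mckee(adj, symmetric_mode=True)
    inv = np.empty(n, int)
    inv[perm] = np.arange(n)
    return pts[perm], node_tags[perm], inv[tris]


def _triangulate_and_clean(pts, placed, domain_poly) -> np.ndarray:
    tri = Delaunay(pts)
    simplices = tri.simplices
    p = pts[simplices]
    cent = p.mean(axis=1)
    areas = np.abs(0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    keep = np.ones(len(simplices), bool)
    for pl in placed:
        # remove triangles covered >= 50% by the protein footprint; the
        # exact-overlap rule keeps thin lipid slivers at the contour that
        # point-membership heuristics would wrongly cull
        cx, cy = pl.polygon.centroid.x, pl.polygon.centroid.y
        reach = pl.shape.max_radius + 4.0 * pl.h_near + \
            np.hypot(pl.center[0] - cx, pl.center[1] - cy)
        cand = np.where(
            keep & (np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) < reach))[0]
        if not len(cand):
            continue
        tri_polys = shapely.polygons(p[cand])
        overlap = shapely.area(shapely.intersection(tri_polys, pl.polygon))
        keep[cand] &= overlap < 0.5 * areas[cand]
    if not domain_poly.convex_hull.equals(domain_poly):
        out = domain_poly.buffer(1e-9)
        keep &= shapely.contains_xy(out, cent[:, 0], cent[:, 1])
    simplices = simplices[keep]
    # enforce CCW
    p = pts[simplices]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]
    # drop degenerate slivers
    p = pts[simplices]
    areas = np.abs(0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    el = np.linalg.norm(p - np.roll(p, -1, axis=1), axis=2).max(axis=1)
    simplices = simplices[areas > 1e-6 * el**2]
    return simplices


def _smooth(pts, tris, node_tags) -> np.ndarray:
    n = len(pts)
    nbr_sum = np.zeros((n, 2))
    nbr_cnt = np.zeros(n)
    edges = _all_edges(tris)
    for a, b in ((0, 1), (1, 0)):
        np.add.at(nbr_sum, edges[:, a], pts[edges[:, b]])
        np.add.at(nbr_cnt, edges[:, a], 1.0)
    free = (node_tags == TAG_INTERIOR) & (nbr_cnt > 0)
    out = pts.copy()
    out[free] = nbr_sum[free] / nbr_cnt[free, None]
    return out


def mesh_patch(
    placements: Iterable[tuple[ProteinShape, tuple]],
    outer_shape: str = "disc",
    outer_size: float | None = None,
    opts: MeshOptions | None = None,
    decay_length: float | None = None,
    min_clearance: float = 0.0,
) -> TriMesh:
    """Mesh a disc (or rectangle) containing the given protein footprints.

    ``outer_size`` is the disc radius (or (W, H) rectangle) measured from
    the centroid of the placements; by default the disc extends
    ``opts.outer_clearance`` beyond the outermost contour.  With
    ``decay_length`` given, a clearance below 5 decay lengths raises
    :class:`DomainTooSmallError`.
    """
    opts = opts or MeshOptions()
    placed = _place(placements, opts)
    if not placed:
        raise GeometryError("no protein placements given")
    _check_overlaps(placed, min_clearance)

    centers = np.array([p.center for p in placed])
    mid = centers.mean(axis=0)
    reach = max(
        np.hypot(*(np.array(p.center) - mid)) + p.shape.max_radius for p in placed
    )
    if outer_shape == "disc":
        R_out = outer_size if outer_size is not None else reach + opts.outer_clearance
        if decay_length is not None and R_out - reach < 5 * decay_length:
            raise DomainTooSmallError(
                f"outer clearance {R_out - reach:.2f} nm < 5 decay lengths"
            )
        h_far = opts.far_field_factor * max(p.h_near for p in placed)
        nth = max(int(round(2 * np.pi * R_out / h_far)), 16)
        th = np.linspace(0, 2 * np.pi, nth, endpoint=False)
        outer_pts = mid + R_out * np.column_stack([np.cos(th), np.sin(th)])
        domain = Polygon(outer_pts)
        tag_fn = lambda a, b: TAG_OUTER
    elif outer_shape == "rectangle":
        W, H = outer_size
        domain = Polygon(
            [mid + (-W / 2, -H / 2), mid + (W / 2, -H / 2),
             mid + (W / 2, H / 2), mid + (-W / 2, H / 2)]
        )
        outer_pts, tag_fn = _rect_boundary(mid, W, H, placed, opts)
    else:
        raise ValueError(f"unknown outer_shape {outer_shape!r}")
    return _build_mesh(placed, outer_pts, tag_fn, domain, opts, float(len(placed)))


def _rect_boundary(mid, W, H, placed, opts):
    """Boundary sample points of an axis-aligned rectangle, skipping
    stretches covered by protein footprints, plus a tagger for its edges."""
    h_far = opts.far_field_factor * max(p.h_near for p in placed)
    x0, y0 = mid[0] - W / 2, mid[1] - H / 2
    x1, y1 = mid[0] + W / 2, mid[1] + H / 2

    def local_h(pt):
        d = min(p.polygon.distance(shapely.Point(pt)) for p in placed)
        hn = min(p.h_near for p in placed)
        return min(h_far, hn + (h_far - hn) * d / opts.grade_distance)

    pts = []
    for (ax, ay), (bx, by) in [((x0, y0), (x1, y0)), ((x1, y0), (x1, y1)),
                               ((x1, y1), (x0, y1)), ((x0, y1), (x0, y0))]:
        L = np.hypot(bx - ax, by - ay)
        ux, uy = (bx - ax) / L, (by - ay) / L
        t = 0.0
        while t < L - 1e-9:
            pts.append((ax + t * ux, ay + t * uy))
            t += local_h((ax + t * ux, ay + t * uy))
    pts = np.asarray(pts)
    # drop points strictly inside any protein footprint
    keep = np.ones(len(pts), bool)
    for p in placed:
        keep &= ~shapely.contains_xy(p.polygon.buffer(-1e-9), pts[:, 0], pts[:, 1])
    pts = pts[keep]

    tol = 1e-9

    def tag_fn(a, b):
        m = 0.5 * (np.asarray(a) + np.asarray(b))
        if abs(m[0] - x0) < 1e-6 or abs(m[0] - x1) < 1e-6:
            return TAG_SYM_X
        if abs(m[1] - y0) < 1e-6 or abs(m[1] - y1) < 1e-6:
            return TAG_SYM_Y
        return TAG_OUTER

    return pts, tag_fn


def mesh_unit_cell(
    placements: Iterable[tuple[ProteinShape, tuple]],
    cell_origin: tuple,
    cell_size: tuple,
    opts: MeshOptions | None = None,
) -> TriMesh:
    """Mesh an axis-aligned rectangular lattice unit cell.

    ``placements`` lists every protein whose footprint intersects the
    cell (including images centered outside it); footprints are clipped
    by the rectangle.  The cell edges are tagged as mirror-symmetry lines
    (zero normal slope).  ``protein_fraction`` is the total protein area
    inside the cell divided by one full protein area.
    """
    opts = opts or MeshOptions()
    placed = _place(placements, opts)
    if not placed:
        raise GeometryError("no protein placements given")
    _check_overlaps(placed)

    (cx, cy), (W, H) = cell_origin, cell_size
    rect = Polygon([(cx, cy), (cx + W, cy), (cx + W, cy + H), (cx, cy + H)])
    # keep only proteins that actually intersect the cell
    placed = [p for p in placed if p.polygon.intersects(rect)]
    if not placed:
        raise GeometryError("no protein footprint intersects the unit cell")
    area_one = placed[0].polygon.area
    frac = sum(p.polygon.intersection(rect).area for p in placed) / area_one

    mid = np.array([cx + W / 2, cy + H / 2])
    outer_pts, tag_fn = _rect_boundary(mid, W, H, placed, opts)
    return _build_mesh(placed, outer_pts, tag_fn, rect, opts, float(frac))


# -- text serialization (Gmsh MSH 2.2 ASCII) ------------------------------


def write_msh(mesh: TriMesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII, tags in element attributes."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        fh.write(f"{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.nodes, 1):
            fh.write(f"{i} {x:.12g} {y:.12g} 0\n")
        fh.write("$EndNodes\n$Elements\n")
        n_el = len(mesh.triangles) + len(mesh.boundary_edges)
        fh.write(f"{n_el}\n")
        eid = 1
        for (a, b), t in zip(mesh.boundary_edges, mesh.boundary_edge_tags):
            fh.write(f"{eid} 1 2 {t} {t} {a + 1} {b + 1}\n")
            eid += 1
        for a, b, c in mesh.triangles:
            fh.write(f"{eid} 2 2 0 0 {a + 1} {b + 1} {c + 1}\n")
            eid += 1
        fh.write("$EndElements\n")
        fh.write("$NodeData\n1\n\"node_tag\"\n1\n0.0\n3\n0\n1\n"
                 f"{mesh.n_nodes}\n")
        for i, t in enumerate(mesh.node_tags, 1):
            fh.write(f"{i} {t}\n")
        fh.write("$EndNodeData\n")


def read_msh(path) -> TriMesh:
    """Read a mesh previously written by :func:`write_msh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = lines.index("$Nodes")
    n = int(lines[i + 1])
    nodes = np.array(
        [[float(v) for v in lines[i + 2 + j].split()[1:3]] for j in range(n)]
    )
    i = lines.index("$Elements")
    n_el = int(lines[i + 1])
    tris, bedges, bet = [], [], []
    for j in range(n_el):
        parts = lines[i + 2 + j].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        tags = [int(v) for v in parts[3:3 + ntags]]
        conn = [int(v) - 1 for v in parts[3 + ntags:]]
        if etype == 1:
            bedges.append(conn)
            bet.append(tags[0])
        elif etype == 2:
            tris.append(conn)
    node_tags = np.zeros(n, int)
    if "$NodeData" in lines:
        i = lines.index("$NodeData")
        k = i + 1
        nstr = int(lines[k]); k += 1 + nstr      # string tags
        nreal = int(lines[k]); k += 1 + nreal    # real tags
        nint = int(lines[k]); k += 1             # integer tags, one per line
        count = int(lines[k + nint - 1])
        k += nint
        for j in range(count):
            a, b = lines[k + j].split()
            node_tags[int(a) - 1] = int(float(b))
    return TriMesh(
        nodes, np.asarray(tris, int), node_tags,
        np.asarray(bedges, int).reshape(-1, 2), np.asarray(bet, int),
    )
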