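"""Finite-element minimization of the bilayer thickness-deformation energy.

The thickness deformation field u (one-half the local hydrophobic
thickness mismatch) costs an elastic energy

    E[u] = Int dA [ kb/2 (lap u)^2 + Kt/(2 a^2) u^2
                    + tau ( u/a + |grad u|^2 / 2 ) ]

with kb the bending rigidity, Kt the thickness deformation modulus, a
the unperturbed bilayer half-thickness and tau the membrane tension,
which couples both to thickness changes (u/a) and to the excess area of
the deformed leaflet surfaces.  Completing the square in u shows that a
tensed bilayer prefers the uniform thickness u_eq = -tau a / Kt; the
solver therefore works with the shifted field v = u - u_eq, for which

    E_def[v] = Int dA [ kb/2 (lap v)^2 + Kt/(2 a^2) v^2 + tau/2 |grad v|^2 ]

is a positive quadratic functional vanishing in the unperturbed state,
and protein boundary values become the tension-shifted effective
mismatch U_eff = U + tau a / Kt.  All reported energies are E_def
(deformation energy relative to the uniform tensed bilayer); the
extensive background -tau^2 A/(2 Kt) cancels in all interaction
energies.

Discretization: 3 degrees of freedom per node (v and its two gradient
components).  The curvature term uses the discrete Kirchhoff triangle
(DKT) plate element; the stretch and tension-gradient terms use linear
(CST) interpolation of the nodal v only.  Element integrals use the
3-point mid-edge rule, exact for the quadratic integrands involved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import kv

from .meshing import (
    TAG_OUTER,
    TAG_SYM_X,
    TAG_SYM_XY,
    TAG_SYM_Y,
    TriMesh,
)



def _cross2(a, b):
    """z-component of the cross product of 2-D vectors (batched)."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

class SingularSystemError(RuntimeError):
    """Unconstrained floating problem (no Dirichlet data, Kt = tau = 0)."""


@dataclass(frozen=True)
class BilayerParams:
    """Elastic parameters of the lipid bilayer.

    bending_rigidity kb in kBT; thickness_modulus Kt in kBT/nm^2;
    half_thickness a in nm; tension tau in kBT/nm^2.
    ``tension_couples_thickness`` selects whether tau couples to u (the
    default, shifting the preferred thickness) in addition to the
    |grad u|^2 area term.
    """

    bending_rigidity: float = 14.0
    thickness_modulus: float = 56.5
    half_thickness: float = 1.6
    tension: float = 0.0
    tension_couples_thickness: bool = True

    def __post_init__(self):
        if self.bending_rigidity <= 0 or self.thickness_modulus <= 0:
            raise ValueError("moduli must be positive")
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")
        if self.tension < 0:
            raise ValueError("tension must be non-negative")

    @property
    def decay_length(self) -> float:
        """Elastic decay length lambda = (kb a^2 / Kt)^(1/4) in nm."""
        return (
            self.bending_rigidity * self.half_thickness**2 / self.thickness_modulus
        ) ** 0.25

    @property
    def equilibrium_shift(self) -> float:
        """Uniform thickness change u_eq = -tau a / Kt preferred under tension."""
        if not self.tension_couples_thickness:
            return 0.0
        return -self.tension * self.half_thickness / self.thickness_modulus

    def effective_mismatch(self, U: float) -> float:
        """Boundary value of the shifted field: U_eff = U - u_eq."""
        return U - self.equilibrium_shift

    def with_tension(self, tau: float) -> "BilayerParams":
        return replace(self, tension=tau)


@dataclass
class NodalField:
    """Solved thickness deformation: per node (v, dv/dx, dv/dy), energy in kBT."""

    mesh: TriMesh
    dof: np.ndarray      # (3N,) flat DOF vector
    energy: float
    params: BilayerParams

    @property
    def u(self) -> np.ndarray:
        return self.dof[0::3]

    @property
    def grad(self) -> np.ndarray:
        return np.column_stack([self.dof[1::3], self.dof[2::3]])


# -- DKT element ----------------------------------------------------------

_QP = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])  # mid-edge points


def _dkt_b_matrices(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Curvature-displacement matrices for a batch of triangles.

    coords: (M, 3, 2) vertex coordinates.
    Returns (B, area): B of shape (M, 3 qp, 3, 9) mapping the element DOF
    vector (v1, vx1, vy1, v2, ...) to curvatures (v,xx, v,yy, 2 v,xy),
    and the signed areas (M,).

    The rotation fields follow Batoz's discrete Kirchhoff triangle with
    mid-side Kirchhoff constraints; the nodal rotations are expressed
    directly in terms of the gradient DOFs.
    """
    M = coords.shape[0]
    x = coords[..., 0]
    y = coords[..., 1]
    # side k=4: 2-3, k=5: 3-1, k=6: 1-2  (stored in order 4,5,6)
    xij = np.stack([x[:, 1] - x[:, 2], x[:, 2] - x[:, 0], x[:, 0] - x[:, 1]], axis=1)
    yij = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    l2 = xij**2 + yij**2
    P = -6.0 * xij / l2
    q = 3.0 * xij * yij / l2
    t = -6.0 * yij / l2
    r = 3.0 * yij**2 / l2

    x31 = x[:, 2] - x[:, 0]
    x12 = x[:, 0] - x[:, 1]
    y31 = y[:, 2] - y[:, 0]
    y12 = y[:, 0] - y[:, 1]
    area2 = x31 * y12 - x12 * y31  # = 2A

    P4, P5, P6 = P[:, 0], P[:, 1], P[:, 2]
    q4, q5, q6 = q[:, 0], q[:, 1], q[:, 2]
    t4, t5, t6 = t[:, 0], t[:, 1], t[:, 2]
    r4, r5, r6 = r[:, 0], r[:, 1], r[:, 2]
    one = np.ones(M)

    B = np.zeros((M, 3, 3, 9))
    for iq, (xi, eta) in enumerate(_QP):
        Hx_xi = np.stack([
            P6 * (1 - 2 * xi) + (P5 - P6) * eta,
            q6 * (1 - 2 * xi) - (q5 + q6) * eta,
            -4 * one + 6 * (xi + eta) + r6 * (1 - 2 * xi) - eta * (r5 + r6),
            -P6 * (1 - 2 * xi) + eta * (P4 + P6),
            q6 * (1 - 2 * xi) - eta * (q6 - q4),
            -2 * one + 6 * xi + r6 * (1 - 2 * xi) + eta * (r4 - r6),
            -eta * (P5 + P4),
            eta * (q4 - q5),
            -eta * (r5 - r4),
        ], axis=1)
        Hx_eta = np.stack([
            -P5 * (1 - 2 * eta) - xi * (P6 - P5),
            q5 * (1 - 2 * eta) - xi * (q5 + q6),
            -4 * one + 6 * (xi + eta) + r5 * (1 - 2 * eta) - xi * (r5 + r6),
            xi * (P4 + P6),
            xi * (q4 - q6),
            -xi * (r6 - r4),
            P5 * (1 - 2 * eta) - xi * (P4 + P5),
            q5 * (1 - 2 * eta) + xi * (q4 - q5),
            -2 * one + 6 * eta + r5 * (1 - 2 * eta) + xi * (r4 - r5),
        ], axis=1)
        Hy_xi = np.stack([
            t6 * (1 - 2 * xi) + eta * (t5 - t6),
            1 * one + r6 * (1 - 2 * xi) - eta * (r5 + r6),
            -q6 * (1 - 2 * xi) + eta * (q5 + q6),
            -t6 * (1 - 2 * xi) + eta * (t4 + t6),
            -1 * one + r6 * (1 - 2 * xi) + eta * (r4 - r6),
            -q6 * (1 - 2 * xi) - eta * (q4 - q6),
            -eta * (t4 + t5),
            eta * (r4 - r5),
            -eta * (q4 - q5),
        ], axis=1)
        Hy_eta = np.stack([
            -t5 * (1 - 2 * eta) - xi * (t6 - t5),
            1 * one + r5 * (1 - 2 * eta) - xi * (r5 + r6),
            -q5 * (1 - 2 * eta) + xi * (q5 + q6),
            xi * (t4 + t6),
            xi * (r4 - r6),
            -xi * (q4 - q6),
            t5 * (1 - 2 * eta) - xi * (t4 + t5),
            -1 * one + r5 * (1 - 2 * eta) + xi * (r4 - r5),
            -q5 * (1 - 2 * eta) - xi * (q4 - q5),
        ], axis=1)

        inv2A = 1.0 / area2
        B[:, iq, 0, :] = inv2A[:, None] * (y31[:, None] * Hx_xi + y12[:, None] * Hx_eta)
        B[:, iq, 1, :] = inv2A[:, None] * (-x31[:, None] * Hy_xi - x12[:, None] * Hy_eta)
        B[:, iq, 2, :] = inv2A[:, None] * (
            -x31[:, None] * Hx_xi - x12[:, None] * Hx_eta
            + y31[:, None] * Hy_xi + y12[:, None] * Hy_eta
        )

    # Batoz DOF order per node is (w, theta_x, theta_y) with
    # theta_x = dw/dy and theta_y = -dw/dx; convert to (v, vx, vy).
    T = np.zeros((9, 9))
    for n in range(3):
        T[3 * n + 0, 3 * n + 0] = 1.0
        T[3 * n + 1, 3 * n + 2] = 1.0   # theta_x  <-  vy
        T[3 * n + 2, 3 * n + 1] = -1.0  # theta_y  <- -vx
    B = np.einsum("mqij,jk->mqik", B, T)
    return B, 0.5 * area2


def element_matrices(coords: np.ndarray, params: BilayerParams):
    """Element stiffness (M,9,9) and internal-tension load (M,9) blocks.

    ``coords`` may be a single triangle (3,2) or a batch (M,3,2).  The
    stiffness combines the DKT curvature block (bending rigidity), the
    CST mass block (thickness stretch, Kt/a^2) and the CST gradient
    block (tension).  The load vector carries the linear tau*u/a
    coupling; it is zero in the shifted-field convention used by
    :func:`solve_field` and is exposed for the unshifted form of the
    energy.
    """
    single = coords.ndim == 2
    coords = coords[None] if single else coords
    if np.any(np.abs(_cross2(coords[:, 1] - coords[:, 0],
                              coords[:, 2] - coords[:, 0])) < 1e-14):
        raise ValueError("degenerate triangle")
    B, area = _dkt_b_matrices(coords)
    kb = params.bending_rigidity
    D = kb * np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
    # bending: K = 2A * (1/6) * sum_q B^T D B
    K = np.einsum("m,mqci,cd,mqdj->mij", 2 * area / 6.0, B, D, B, optimize=True)

    # stretch (Kt/a^2) mass matrix on the v DOFs
    kt_a2 = params.thickness_modulus / params.half_thickness**2
    Mm = (np.ones((3, 3)) + np.eye(3)) / 12.0
    vidx = np.array([0, 3, 6])
    K[:, vidx[:, None], vidx[None, :]] += kt_a2 * area[:, None, None] * Mm

    # tension gradient term on the v DOFs
    tau = params.tension
    if tau != 0.0:
        x = coords[..., 0]
        y = coords[..., 1]
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        G = (
            np.einsum("mi,mj->mij", b, b) + np.einsum("mi,mj->mij", c, c)
        ) / (4.0 * area)[:, None, None]
        K[:, vidx[:, None], vidx[None, :]] += tau * G

    # internal tension load: tau/a * Int v dA  ->  tau/a * A/3 per node
    f = np.zeros((coords.shape[0], 9))
    if tau != 0.0 and params.tension_couples_thickness:
        f[:, vidx] = (tau / params.half_thickness) * (area / 3.0)[:, None]

    if single:
        return K[0], f[0]
    return K, f


def assemble(mesh: TriMesh, params: BilayerParams):
    """Assemble the global stiffness matrix (CSR, 3N x 3N)."""
    coords = mesh.nodes[mesh.triangles]
    Ke, _ = element_matrices(coords, params)
    M = len(mesh.triangles)
    dof_map = (3 * mesh.triangles[:, :, None] + np.arange(3)[None, None, :]).reshape(M, 9)
    rows = np.repeat(dof_map, 9, axis=1).ravel()
    cols = np.tile(dof_map, (1, 9)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    ).tocsr()
    return K


def _constraints(mesh: TriMesh, params: BilayerParams, bcs: dict[int, float]):
    """Fixed-DOF mask and values from mesh tags.

    bcs maps protein index k (0-based) to the *raw* mismatch U; the
    tension shift to U_eff is applied here.
    """
    n = mesh.n_nodes
    fixed = np.zeros(3 * n, bool)
    vals = np.zeros(3 * n)
    tags = mesh.node_tags
    for k, U in bcs.items():
        sel = tags == k + 1
        ueff = params.effective_mismatch(U)
        idx = np.where(sel)[0]
        fixed[3 * idx] = True
        vals[3 * idx] = ueff
        fixed[3 * idx + 1] = True
        fixed[3 * idx + 2] = True
    for tag, comp in ((TAG_SYM_X, 1), (TAG_SYM_Y, 2)):
        idx = np.where(tags == tag)[0]
        fixed[3 * idx + comp] = True
    idx = np.where(tags == TAG_SYM_XY)[0]
    fixed[3 * idx + 1] = True
    fixed[3 * idx + 2] = True
    return fixed, vals


def solve_field(
    mesh: TriMesh, params: BilayerParams, bcs: dict[int, float]
) -> NodalField:
    """Minimize the deformation energy subject to protein boundary data.

    ``bcs`` maps protein index -> mismatch U (nm).  Protein boundary
    nodes are clamped (v = U_eff, grad v = 0); rectangle mirror edges fix
    the normal gradient component; outer disc boundaries are natural.
    Returns the minimizing field and its energy in kBT.
    """
    missing = {int(t) - 1 for t in np.unique(mesh.node_tags) if t > 0} - set(bcs)
    if missing:
        raise ValueError(f"no boundary condition for protein(s) {sorted(missing)}")
    K = assemble(mesh, params)
    fixed, vals = _constraints(mesh, params, bcs)
    if not fixed.any() and params.thickness_modulus == 0 and params.tension == 0:
        raise SingularSystemError("floating domain with no constraints")
    free = ~fixed
    x = vals.copy()
    if free.any():
        Kff = K[free][:, free].tocsc()
        rhs = -K[free][:, fixed] @ vals[fixed]
        try:
            x[free] = splu(Kff).solve(rhs)
        except RuntimeError as err:  # pragma: no cover - singular factorization
            raise SingularSystemError(str(err)) from err
    energy = 0.5 * float(x @ (K @ x))
    return NodalField(mesh=mesh, dof=x, energy=energy, params=params)


def energy_by_quadrature(field: NodalField) -> float:
    """Recompute the energy by direct quadrature of the density over the field.

    Evaluates bending, stretch and tension densities at the element
    quadrature points from the solved DOFs; serves as an independent
    bookkeeping check on the assembled quadratic form.
    """
    mesh, params = field.mesh, field.params
    coords = mesh.nodes[mesh.triangles]
    B, area = _dkt_b_matrices(coords)
    M = len(mesh.triangles)
    dof_map = (3 * mesh.triangles[:, :, None] + np.arange(3)[None, None, :]).reshape(M, 9)
    Ue = field.dof[dof_map]                      # (M, 9)
    curv = np.einsum("mqij,mj->mqi", B, Ue)      # (M, 3qp, 3)
    lap = curv[:, :, 0] + curv[:, :, 1]
    e_bend = params.bending_rigidity / 2.0 * (lap**2).mean(axis=1) * area

    v_nodes = Ue[:, [0, 3, 6]]
    # v at mid-edge quadrature points (linear interpolation)
    vq = 0.5 * (v_nodes + np.roll(v_nodes, -1, axis=1))
    kt_a2 = params.thickness_modulus / params.half_thickness**2
    e_stretch = kt_a2 / 2.0 * (vq**2).mean(axis=1) * area

    e_tension = np.zeros(M)
    if params.tension != 0.0:
        x = coords[..., 0]
        y = coords[..., 1]
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        gx = np.einsum("mi,mi->m", b, v_nodes) / (2 * area)
        gy = np.einsum("mi,mi->m", c, v_nodes) / (2 * area)
        e_tension = params.tension / 2.0 * (gx**2 + gy**2) * area
    return float((e_bend + e_stretch + e_tension).sum())


def gradient_validity_check(field: NodalField, threshold: float = 0.5) -> dict:
    """Report the largest |grad u| and the flagged-element fraction.

    The leading-order thickness-deformation energy assumes small
    gradients; ``threshold`` is the dimensionless slope above which an
    element counts as violating that assumption.
    """
    mesh = field.mesh
    coords = mesh.nodes[mesh.triangles]
    v_nodes = field.u[mesh.triangles]
    x = coords[..., 0]
    y = coords[..., 1]
    area = 0.5 * _cross2(coords[:, 1] - coords[:, 0], coords[:, 2] - coords[:, 0])
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    gx = np.einsum("mi,mi->m", b, v_nodes) / (2 * area)
    gy = np.einsum("mi,mi->m", c, v_nodes) / (2 * area)
    gmag = np.hypot(gx, gy)
    deformed = gmag > 0
    frac = float(np.mean(gmag > threshold)) if len(gmag) else 0.0
    if threshold == 0.0:
        frac = float(np.mean(deformed)) if len(gmag) else 0.0
    return {
        "max_gradient": float(gmag.max()) if len(gmag) else 0.0,
        "fraction_above_threshold": frac,
        "threshold": threshold,
    }


# -- analytic oracle: single cylinder -------------------------------------


def analytic_cylinder(params: BilayerParams, R0: float, U: float):
    """Exact minimizer and energy for a single cylindrical inclusion.

    The radially symmetric Euler-Lagrange equation
    kb lap^2 v - tau lap v + (Kt/a^2) v = 0 outside r = R0 with
    v(R0) = U_eff, v'(R0) = 0 and decay at infinity is solved by modified
    Bessel functions K0(k r) with kb k^4 - tau k^2 + Kt/a^2 = 0 (the two
    roots are complex conjugate below the overdamping tension; the real
    combination is returned).  The energy follows from integrating the
    functional by parts onto the inner boundary:

        E = pi R0 kb U_eff d/dr(lap v)|_{R0}.

    Returns ``(profile, energy)`` with ``profile(r)`` vectorized.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    kb = params.bending_rigidity
    kt_a2 = params.thickness_modulus / params.half_thickness**2
    tau = params.tension
    ueff = params.effective_mismatch(U)

    disc = np.complex128(tau**2 - 4.0 * kb * kt_a2)
    k2 = np.array([
        (tau + np.sqrt(disc)) / (2 * kb),
        (tau - np.sqrt(disc)) / (2 * kb),
    ])
    k = np.sqrt(k2)
    k = np.where(k.real < 0, -k, k)

    # coefficients: v(R0) = U_eff ; v'(R0) = 0
    A = np.array([
        [kv(0, k[0] * R0), kv(0, k[1] * R0)],
        [-k[0] * kv(1, k[0] * R0), -k[1] * kv(1, k[1] * R0)],
    ])
    cvec = np.linalg.solve(A, np.array([ueff, 0.0], dtype=np.complex128))

    def profile(r):
        r = np.asarray(r, dtype=float)
        out = cvec[0] * kv(0, k[0] * r) + cvec[1] * kv(0, k[1] * r)
        return out.real if out.ndim else float(out.real)

    dlap = -(cvec[0] * k[0] ** 3 * kv(1, k[0] * R0)
             + cvec[1] * k[1] ** 3 * kv(1, k[1] * R0))
    energy = float((np.pi * R0 * kb * ueff * dlap).real)
    return profile, energy


def analytic_cylinder_energy_quadrature(params: BilayerParams, R0: float, U: float,
                                        r_max_lambdas: float = 40.0) -> float:
    """Energy of the analytic profile by direct radial quadrature.

    Independent of the boundary-flux closed form; used to validate it.
    """
    from scipy.integrate import quad

    profile, _ = analytic_cylinder(params, R0, U)
    kb = params.bending_rigidity
    kt_a2 = params.thickness_modulus / params.half_thickness**2
    tau = params.tension
    h = 1e-5

    def density(r):
        vm, v0, vp = profile(r - h), profile(r), profile(r + h)
        d1 = (vp - vm) / (2 * h)
        d2 = (vp - 2 * v0 + vm) / h**2
        lap = d2 + d1 / r
        return (kb / 2 * lap**2 + kt_a2 / 2 * v0**2 + tau / 2 * d1**2) * 2 * np.pi * r

    import warnings

    r_end = R0 + r_max_lambdas * params.decay_length
    with warnings.catch_warnings():
        # the integrand involves second finite differences of Bessel
        # functions; quad's roundoff warning is expected and benign here
        warnings.simplefilter("ignore")
        val, _ = quad(density, R0 + 2 * h, r_end, limit=400)
    return val


# -- output ----------------------------------------------------------------


def write_vtk(field: NodalField, path) -> None:
    """Write the solved field as legacy-ASCII VTK point data (u, |grad u|)."""
    mesh = field.mesh
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nthickness deformation field\n"
                 "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        m = len(mesh.triangles)
        fh.write(f"CELLS {m} {4 * m}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {m}\n" + "5\n" * m)
        fh.write(f"POINT_DATA {mesh.n_nodes}\nSCALARS u double 1\n"
                 "LOOKUP_TABLE default\n")
        for v in field.u:
            fh.write(f"{v:.10g}\n")
        fh.write("SCALARS grad_mag double 1\nLOOKUP_TABLE default\n")
        gm = np.linalg.norm(field.grad, axis=1)
        for v in gm:
            fh.write(f"{v:.10g}\n")
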