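"""Parametric protein footprints and their boundary conditions.

An s-fold symmetric membrane protein is modeled by the polar "clover-leaf"
contour

    r(theta) = R * [1 + eps * cos(s * (theta - omega))]

where ``R`` sets the size, ``eps`` the amplitude of the angular
undulations, ``s`` the rotational symmetry order (5 for pentameric MscL,
4 for tetrameric MscL, 0 for the isotropic cylinder model) and ``omega``
the in-plane orientation.  The protein imprints its hydrophobic belt on
the surrounding bilayer through the boundary conditions

    u = U,   du/dn = 0        on the contour,

with ``U`` one-half the protein hydrophobic thickness minus the
unperturbed bilayer half-thickness ``a`` (hydrophobic mismatch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


class GatingState(str, Enum):
    CLOSED = "closed"
    OPEN = "open"


class InvalidShapeError(ValueError):
    """Raised when contour parameters produce a non-positive radius."""


@dataclass(frozen=True)
class ProteinShape:
    """An s-fold symmetric protein footprint with its mismatch boundary value.

    Parameters
    ----------
    symmetry_order:
        Rotational symmetry s; 0 denotes the cylinder model (eps ignored,
        treated as 0), otherwise 4 or 5.
    radius:
        Mean contour radius R in nm.
    undulation:
        Dimensionless lobe amplitude eps (must satisfy eps < 1).
    orientation:
        In-plane angle omega (radians, counterclockwise from x).
    state:
        Gating state (closed or open); bookkeeping only.
    mismatch:
        Boundary half-mismatch U in nm (protein hydrophobic half-thickness
        minus bilayer half-thickness a).
    label:
        Free-form identifier, e.g. "pentamer".
    """

    symmetry_order: int
    radius: float
    undulation: float = 0.0
    orientation: float = 0.0
    state: GatingState = GatingState.CLOSED
    mismatch: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.symmetry_order not in (0, 4, 5):
            raise InvalidShapeError(
                f"symmetry order must be 0, 4 or 5, got {self.symmetry_order}"
            )
        if self.radius <= 0:
            raise InvalidShapeError("radius must be positive")
        eps = 0.0 if self.symmetry_order == 0 else float(self.undulation)
        if eps < 0 or eps >= 1:
            raise InvalidShapeError("undulation must satisfy 0 <= eps < 1")
        object.__setattr__(self, "undulation", eps)
        if self.symmetry_order == 0:
            object.__setattr__(self, "orientation", 0.0)
        else:
            object.__setattr__(
                self, "orientation", canonical_orientation(self.orientation, self.symmetry_order)
            )
        if not isinstance(self.state, GatingState):
            object.__setattr__(self, "state", GatingState(self.state))

    # -- geometry ---------------------------------------------------------

    @property
    def sector(self) -> float:
        """Angular period 2*pi/s of the contour (2*pi for a cylinder)."""
        s = self.symmetry_order
        return 2.0 * np.pi if s == 0 else 2.0 * np.pi / s

    @property
    def max_radius(self) -> float:
        return self.radius * (1.0 + self.undulation)

    def with_orientation(self, omega: float) -> "ProteinShape":
        return replace(self, orientation=omega)

    def to_dict(self) -> dict:
        return {
            "symmetry_order": self.symmetry_order,
            "radius": self.radius,
            "undulation": self.undulation,
            "orientation": self.orientation,
            "state": self.state.value,
            "mismatch": self.mismatch,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinShape":
        return cls(**{**d, "state": GatingState(d.get("state", "closed"))})


def canonical_orientation(omega: float, symmetry_order: int) -> float:
    """Wrap omega into the canonical range [0, 2*pi/s)."""
    if symmetry_order == 0:
        return 0.0
    sector = 2.0 * np.pi / symmetry_order
    return float(np.mod(omega, sector))


def contour_radius(shape: ProteinShape, theta) -> np.ndarray | float:
    """Polar contour radius r(theta) = R[1 + eps cos(s(theta - omega))]."""
    theta = np.asarray(theta, dtype=float)
    s = shape.symmetry_order
    if s == 0:
        r = np.full_like(theta, shape.radius, dtype=float)
    else:
        r = shape.radius * (
            1.0 + shape.undulation * np.cos(s * (theta - shape.orientation))
        )
    return r if r.ndim else float(r)


def enclosed_area(shape: ProteinShape, numerical: bool = False) -> float:
    """Cross-sectional area enclosed by the contour.

    The closed form is pi R^2 (1 + eps^2/2), independent of the symmetry
    order; with ``numerical=True`` the area is computed by quadrature of
    (1/2) \\int r^2 dtheta instead (used as an internal cross-check).
    """
    if numerical:
        val, _ = quad(
            lambda t: 0.5 * contour_radius(shape, t) ** 2, 0.0, 2.0 * np.pi,
            limit=200,
        )
        return val
    return np.pi * shape.radius**2 * (1.0 + 0.5 * shape.undulation**2)


def matched_area_radius(
    reference: ProteinShape, target_s: int, target_eps: float
) -> float:
    """Radius R for a (target_s, target_eps) contour with the reference's area.

    Solved by root finding on the quadrature area so the match holds for
    any star-convex contour family, to relative tolerance 1e-10.
    """
    area_ref = enclosed_area(reference, numerical=True)
    if target_s == 0:
        target_eps = 0.0

    def area_diff(R):
        trial = ProteinShape(
            symmetry_order=target_s, radius=R, undulation=target_eps
        )
        return enclosed_area(trial, numerical=True) - area_ref

    r0 = np.sqrt(area_ref / np.pi)
    lo, hi = 0.5 * r0, 2.0 * r0
    R = brentq(area_diff, lo, hi, xtol=1e-13, rtol=1e-12)
    return float(R)


def contour_points(shape: ProteinShape, center=(0.0, 0.0), n: Optional[int] = None,
                   spacing: Optional[float] = None) -> np.ndarray:
    """Sample the contour as a closed polyline with ~uniform arclength spacing.

    ``n`` overrides the point count; otherwise it follows from ``spacing``
    (target edge length) or the package default of >= 40*max(1, s) points.
    """
    s = max(1, shape.symmetry_order)
    if n is None:
        # dense parametric sampling, then arclength resampling
        if spacing is not None:
            per = perimeter(shape)
            n = max(int(np.ceil(per / spacing)), 40 * s)
        else:
            n = 40 * s
    m = max(8 * n, 720)
    t = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    r = contour_radius(shape, t)
    xy = np.column_stack([r * np.cos(t), r * np.sin(t)])
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    xs = np.interp(targets, arc, np.append(xy[:, 0], xy[0, 0]))
    ys = np.interp(targets, arc, np.append(xy[:, 1], xy[0, 1]))
    pts = np.column_stack([xs, ys])
    pts[:, 0] += center[0]
    pts[:, 1] += center[1]
    return pts


def perimeter(shape: ProteinShape) -> float:
    """Contour arclength, by quadrature."""
    def integrand(t):
        s = shape.symmetry_order
        r = contour_radius(shape, t)
        if s == 0:
            dr = 0.0
        else:
            dr = -shape.radius * shape.undulation * s * np.sin(
                s * (t - shape.orientation)
            )
        return np.hypot(r, dr)

    val, _ = quad(integrand, 0.0, 2.0 * np.pi, limit=200)
    return val


@dataclass(frozen=True)
class BoundaryCondition:
    """Dirichlet mismatch value with clamped (zero-slope) contour gradient."""

    dirichlet_u: float       # nm, value of u on the protein contour
    zero_normal_slope: bool = True


def boundary_conditions(shape: ProteinShape, bilayer) -> BoundaryCondition:
    """Boundary conditions for the thickness field at this protein.

    The Dirichlet value is the stored half-mismatch U; the normal slope of
    u vanishes along the bilayer-protein interface.  ``bilayer`` is
    accepted for interface symmetry (a tension-shifted effective mismatch
    is applied inside the solver, not here).
    """
    return BoundaryCondition(dirichlet_u=float(shape.mismatch))


def mismatch_from_thickness(protein_hydrophobic_thickness: float, half_thickness: float) -> float:
    """U = (protein hydrophobic thickness)/2 - a, sign preserved."""
    return 0.5 * protein_hydrophobic_thickness - half_thickness


# -- default MscL shape catalogue ----------------------------------------


def _load_defaults() -> dict:
    with resources.files("mscl_lattice").joinpath("defaults.json").open() as fh:
        return json.load(fh)


_DEFAULTS_CACHE: dict | None = None


def package_defaults() -> dict:
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        _DEFAULTS_CACHE = _load_defaults()
    return _DEFAULTS_CACHE


def mscl_shape(oligomer: str, state: str | GatingState = GatingState.CLOSED,
               orientation: float = 0.0) -> ProteinShape:
    """Default MscL footprint for ``oligomer`` in {'pentamer','tetramer','cylinder'}.

    Radii, undulation amplitudes and hydrophobic mismatches come from the
    versioned defaults file.  The tetramer radius is fixed at run time by
    matching the pentamer cross-sectional area (the two oligomers are
    modeled with equal transmembrane areas); the cylinder uses eps = 0 at
    the same matched area.
    """
    d = package_defaults()
    state = GatingState(state)
    a = d["bilayer"]["half_thickness"]["value"]
    thick = d["mscl"][f"hydrophobic_thickness_{state.value}"]["value"]
    U = mismatch_from_thickness(thick, a)

    pent = d["mscl"]["pentamer"][state.value]
    pent_shape = ProteinShape(
        symmetry_order=5, radius=pent["radius"], undulation=pent["undulation"],
        orientation=orientation, state=state, mismatch=U, label="pentamer",
    )
    if oligomer == "pentamer":
        return pent_shape
    if oligomer == "tetramer":
        eps = d["mscl"]["tetramer"][state.value]["undulation"]
        R = matched_area_radius(pent_shape, 4, eps)
        return ProteinShape(
            symmetry_order=4, radius=R, undulation=eps, orientation=orientation,
            state=state, mismatch=U, label="tetramer",
        )
    if oligomer == "cylinder":
        R = matched_area_radius(pent_shape, 0, 0.0)
        return ProteinShape(
            symmetry_order=0, radius=R, undulation=0.0, state=state,
            mismatch=U, label="cylinder",
        )
    raise ValueError(f"unknown oligomer {oligomer!r}")
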