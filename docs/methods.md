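# Methods

## Physical model

The package models the lipid bilayer around integral membrane proteins
as a continuum elastic sheet whose thickness can deviate locally from
its relaxed value.  The state variable is the thickness deformation
field u(x, y), one-half the local deviation of the bilayer hydrophobic
thickness from its unperturbed value 2a.  Its elastic cost is

    E[u] = ∫ dA [ κb/2 (∇²u)² + Kt/(2a²) u² + τ (u/a + |∇u|²/2) ]

with bending rigidity κb, thickness deformation modulus Kt, unperturbed
half-thickness a and membrane tension τ.  The tension couples both to
the excess leaflet area (|∇u|²/2) and to the thickness itself (u/a):
completing the square shows a tensed bilayer prefers the uniformly
thinned state u_eq = −τa/Kt.  The solver works with the shifted field
v = u − u_eq, whose energy functional is positive-definite,

    E_def[v] = ∫ dA [ κb/2 (∇²v)² + Kt/(2a²) v² + τ/2 |∇v|² ],

and reports E_def, the deformation energy relative to the uniform
tensed bilayer; the extensive background −τ²A/(2Kt) drops out of every
interaction energy.  The u-coupling can be switched off
(`BilayerParams.tension_couples_thickness = False`), which reduces the
model to a pure area-coupled tension term.

A protein of rotational symmetry s imprints itself through its
footprint contour r(θ) = R[1 + ε cos(s(θ − ω))] (s = 5 pentamer, 4
tetramer, 0 cylinder) and through boundary conditions on the contour:
u = U (half the protein/bilayer hydrophobic mismatch) and zero normal
slope.  In the shifted field the Dirichlet value becomes
U_eff = U + τa/Kt — tension deepens the mismatch of a protein that is
thicker than the bilayer, which is the mechanism behind the
tension-dependence of lattice activation barriers.

Because E_def is a quadratic functional, every energy scales as the
square of a uniform scaling of all boundary mismatches, and the
minimizer is unique.

### Parameters and defaults

All defaults live in `src/mscl_lattice/defaults.json`, with per-entry
source notes; nothing is hard-coded.  The package targets MscL, the
bacterial mechanosensitive channel of large conductance:

| quantity | default | units | note |
|---|---|---|---|
| κb | 14 | kBT | typical phospholipid bending rigidity |
| Kt | 56.5 | kBT/nm² | effective thickness deformation modulus |
| a | 1.6 | nm | half hydrophobic thickness, E. coli-like lipids |
| τ | 0 | kBT/nm² | tension-free unless scanning gating |
| closed MscL hydrophobic thickness | 3.8 | nm | U = +0.3 nm |
| open MscL hydrophobic thickness | 2.5 | nm | U = −0.35 nm |
| pentamer closed (R, ε) | (2.27, 0.22) | nm, — | clover-leaf contour fit |
| pentamer open (R, ε) | (3.49, 0.11) | nm, — | open-state models |
| tetramer ε | same as pentamer | — | from the companion contour-modeling study; R fixed by matching the pentamer cross-sectional area |
| steric edge clearance | 0.5 | nm | minimum lipid gap between contours |

The elastic decay length λ = (κb a²/Kt)^¼ ≈ 0.89 nm sets every
geometric scale: domain truncation, mesh grading, interaction range.
The closed state is thicker and the open state thinner than the
bilayer, so closed–closed contacts are strongly favorable near contact
while closed–open contacts are unfavorable at short range — the origin
of both clustering and state segregation.

## Finite-element discretization

The curvature term requires (near-)C¹ continuity; the package uses the
discrete Kirchhoff triangle (DKT) plate element for the (∇²v)² block
combined with linear (CST) interpolation of the nodal deflection for
the stretch and tension blocks.  Each node carries (v, ∂v/∂x, ∂v/∂y).
Element integrals use the 3-point mid-edge rule, which is exact for the
quadratic integrands appearing here; the DKT element reproduces
constant-curvature states exactly (verified by patch test).  The
assembled system is sparse, symmetric positive definite; Dirichlet data
are imposed by DOF elimination (exact constraint satisfaction) and the
free system solved by sparse LU.  Mesh nodes are re-numbered by reverse
Cuthill–McKee at construction, which this SciPy build's SuperLU needs
to factor efficiently.

Protein boundary nodes are fully clamped (v = U_eff, ∇v = 0: the
zero-slope condition plus a constant Dirichlet value imply a vanishing
full gradient).  Mirror-symmetry edges of lattice unit cells constrain
only the normal gradient component.  Outer disc boundaries are left
natural; with the default clearance of ~10λ beyond the outermost
contour, doubling the domain changes single-protein energies by < 0.1%.

### Meshing

Domains are meshed without an external mesh generator: contour nodes
(at least 40 points per symmetry repeat — the lobe tips have curvature
radii of ~0.3–0.5 nm and dominate the discretization error if
under-sampled), graded hexagonal point bands around each contour,
extra points inside narrow inter-protein gaps, and a coarse far-field
hex grid are triangulated by Delaunay; triangles covered ≥ 50% by a
protein footprint are removed (an exact-overlap rule — point-membership
heuristics wrongly carve away thin lipid slivers near the lobes).  The
default resolution is h_near = perimeter/100 grading to 4 h_near over
3 nm.  Meshes are validated structurally (positive areas, conformity,
tag completeness) and physically against the analytic oracle below.

### Analytic oracle

For a single cylindrical inclusion the Euler–Lagrange equation
κb∇⁴v − τ∇²v + (Kt/a²)v = 0 with v(R0) = U_eff, v′(R0) = 0 is solved
exactly by modified Bessel functions K0(k±r), k±² the (generally
complex-conjugate) roots of κb k⁴ − τk² + Kt/a² = 0, and the energy by
the boundary-flux closed form E = πR0 κb U_eff d(∇²v)/dr|R0.  The flux
formula is itself cross-checked against direct radial quadrature of the
energy density (agreement ~10⁻⁵ relative).  At default resolution the
FE solver matches the oracle to ~0.1% with and without tension, and the
error decreases under refinement; this single number exercises the
element, the assembly, the constraints and the mesher at once.

## Pair potentials

The interaction of two proteins is E_int(d, ω1, ω2) = E[pair] −
E[A alone] − E[B alone], tabulated on a uniform grid of center
separations d and one angular symmetry sector per protein.  Exact
2π/s periodicity reduces the angular domain; for identical shapes the
exchange symmetry E(d, ω1, ω2) = E(d, ω2 + π, ω1 + π) halves the number
of FE solves and is imposed on the grid, which the Monte Carlo kernel
relies on when evaluating a pair from either end.

The steric minimum distance d_min(ω1, ω2) is the center distance at
which the full contour-to-contour gap equals the lipid clearance
(bisection on polygon distance).  The clearance gap is evaluated
between whole contours rather than along the center line only: two
lobed contours can touch off-axis first, and the full-polygon rule is
what a lipid annulus actually constrains.

Lookups round angles to the nearest grid point and interpolate linearly
in d, beyond the last tabulated row ramping linearly to exactly zero at
the cutoff d_cut.  A bilinear-in-angle mode exists for smooth
optimizers but is off by default.  The default cutoff is d_cut = 12 nm,
fixed by the operational rule that the tabulated |E_int| stay below
0.05 kBT at the cutoff for every orientation; with the default
parameters the tail at 10 nm can still reach ~0.3 kBT.  The cutoff-tail
magnitude itself is verified at finer-than-default mesh resolution
because it lies below the coarse-mesh discretization floor.
Closed-open tables must extend through ~10.5 nm: their weakly
favorable well sits near 9-10 nm (far outside the same-state contact
range), and truncating it suppresses closed/open cluster association
entirely.

Default tabulation resolutions (Δd = 0.25 nm, 12 angular points per
sector) are config knobs guarded by a grid-halving interpolation test;
the workloads in the test-suite and in `scripts/acceptance.py` use
coarser grids (Δd = 0.4–0.5 nm, 4–8 angular points) chosen so a full
study fits in minutes on one CPU; the qualitative orderings reported
there are stable between these resolutions.

Pairwise additivity is an approximation; `nonpairwise_deviation`
quantifies it by comparing the multi-body FE energy of a configuration
with the two-body sum.

## Monte Carlo

Metropolis dynamics with one displacement and one rotation trial per
protein per step (2N trials in random permutation), uniform proposals,
immediate rejection of steric violations, linear cooling.  Temperatures
are in units of room temperature and pair energies in kBT, so the
acceptance factor is exp(−ΔE/T).  The compiled kernel uses a
linked-cell grid (cell ≈ (d_cut + 2·move)/2, 5×5 neighbor scan) and a
single-scan ΔE evaluation; it is exactly equivalent to the direct
O(N²) sum, which a test asserts to 10⁻¹² and a fixed-temperature
two-particle run validates against the Boltzmann distribution.

Annealing schedule: the default unit moves (0.5 nm, 0.2 rad) give
roughly half of all moves accepted near room temperature in a dense
cluster — a diagnostic, not a constraint.  The default cooling runs
from T_start = 4 to T_end = 0.01 in units of room temperature.
T_start is set by the energy scale of the tabulated contacts: the
strongest closed–closed contact is ~10 kBT, so cooling must start where
such contacts still break (T of a few room temperatures) or the gas
aggregates irreversibly into a glass; starting at room temperature
produces kinetically arrested disordered clusters rather than the
lattice ground states.  Results are otherwise robust to the precise
schedule.

Structure is quantified by bond-orientational order parameters ψ4 and
ψ6 (nearest neighbors = pairs closer than 1.35× the median
nearest-neighbor distance), connected-cluster analysis on the neighbor
graph, and a row-alternation statistic mean cos(s(ωi − ωj)) over
neighbor pairs, which is +1 for aligned and −1 for anti-aligned
(alternating-row) orientational order.

## Lattices

Finite clusters of the regular families (honeycomb 3, square 4,
hexagonal 6 neighbors; shifted square) are built at given spacing and
orientation scheme; "face-on" points a contour trough along the bond
(ω = π/s for a bond along x), "tip-on" a lobe peak (ω = 0).  Energies
per protein are pairwise table sums, or full multi-body FE solves for
small clusters.

Infinite lattices are scored on rectangular unit cells whose edges are
mirror lines of the pattern, so the thickness field has zero normal
slope there and one small FE solve gives the energy per protein (cell
energy divided by the protein area fraction in the cell, minus the
isolated-protein energy).  Mirror cells exist for cylinders and
four-fold shapes in the face-on/tip-on/horizontal schemes; five-fold
contours break the rectangular mirror lines (a site on a vertical
mirror would need ω and π − ω to coincide modulo 2π/5) and are
rejected with a symmetry-violation error — pentamer lattice energetics
therefore use large finite clusters.

The distorted pentamer families are package parameterizations:
distorted-A is a sheared hexagonal lattice with independent row pitch,
row shift and alternating row orientations (ω0, ω0 + π/5),
parameterized by packing fraction φ = N·A_protein / tiled area and
minimized over its free parameters by multi-start Nelder–Mead;
distorted-B tiles a face-on three-protein motif on a hexagonal
superlattice.  Maximal packing fractions are found by bisection on
steric feasibility.

A finding worth flagging: with the default shape parameters the
face-on square and the sheared/offset row packings of tetramers (the
shifted-square relatives) are nearly degenerate, and the tabulated
potential puts the sheared packing a few tenths of kBT per protein
below the face-on square for ~100-protein clusters.  Annealed tetramer
clusters therefore show aligned face-bonded rows with mixed stacking
registry (high row-alignment statistic, low psi4) rather than a clean
square lattice.  The balance between these two architectures is
sensitive to the tetragonal undulation amplitude, which is the least
constrained default in the shape catalogue.

## Gating

Opening MscL expands its footprint (closed → open area increase
≈ 22 nm² with the default shapes) and changes its mismatch sign.  The
lattice activation barrier of a perimeter site is

    ΔG = min over local rearrangements of
         E_int[site open, shell relaxed] − E_int[all closed ground state],

interaction energies only — the isolated-protein gating energy is
identical on both sides and cancels.  The rearrangement search resolves
steric overlaps by cascading radial push-out (terminating at the free
perimeter), then relaxes the site's neighbor shell by low-temperature
annealing tethered to within 1.5 nm of the pushed state, from several
restarts.  The tether embodies the "local rearrangement" in the
definition: without it the minimization would explore global cluster
reorganizations (or, in dilute configurations, let the shell diffuse
away and re-bind).  Corner sites break fewer favorable contacts than
edge sites, so ΔG(corner) ≤ ΔG(edge).

Tension enters through re-tabulated pair potentials at each τ (the
potential itself changes, not just the Boltzmann factor).  Barriers
increase approximately linearly in τ because U_eff(closed) = 0.3 +
τa/Kt deepens the closed–closed contacts that must be broken.  Rate
ratios use the Arrhenius form exp(−ΔG/kBT) at room temperature.

Closed/open mixtures are annealed with all three pair tables
(closed–closed, closed–open, open–open); segregation is reported as the
fraction of neighbor pairs sharing a gating state, against the
random-mixing expectation p_cc + p_oo.

## Problem sizes

The default study sizes in the tests and the acceptance script are
chosen for a single-CPU desk-scale run: pair tables at Δd = 0.4–0.5 nm
with 4–8 angular points per sector and mesh resolution
h_near ≈ perimeter/56; annealing at N = 100 proteins in a 70 nm
periodic box and 10⁵ Monte Carlo steps; finite clusters of 16–81
proteins; barrier scans over three tensions ∈ {0, 1.25, 2.5} kBT/nm².  The library itself
supports the larger settings (10⁶ steps, 216–225-protein pentamer
clusters, Δd = 0.25 nm tables) through the same interfaces.

## What the synthetic conditions do and do not show

All inputs are parametric; there is no external data.  The model
inherits the limitations of leading-order continuum elasticity: no
lipid tilt, no midplane curvature or fluctuation-mediated forces, no
molecular detail at the protein–lipid interface, effective parameters
that in reality vary with lipid composition.  `gradient_validity_check`
confirms post hoc that |∇u| stays small enough for the leading-order
functional.  Finite-temperature disorder, cluster-size effects beyond
the sizes simulated, and the kinetic pathway of gating (beyond an
Arrhenius estimate on a single barrier) are outside scope.

## Numerical choices

- Dirichlet elimination, not penalties; constraints hold exactly.
- 3-point mid-edge quadrature everywhere (exact for the integrands).
- Sparse LU on RCM-ordered meshes; the quadratic functional makes
  iterative minimization unnecessary, but `energy_by_quadrature`
  re-derives every reported energy from the solved field as a check.
- Lookup tables carry +∞ (python) / 10³⁰ (compiled, fastmath-safe)
  sentinels for sterically forbidden entries.
- Ties and degeneracies: zero-protein or one-protein Monte Carlo
  returns immediately with zero energy; degenerate tension grids and
  empty candidate lists raise errors rather than guessing.
- Seeds: every stochastic entry point takes an explicit seed and is
  bit-reproducible given it; seeds are recorded in all outputs.
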