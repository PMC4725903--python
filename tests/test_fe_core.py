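"""Element matrices, solver contracts and the analytic cylinder oracle."""

import numpy as np
import pytest

from mscl_lattice.fe_core import (
    BilayerParams,
    analytic_cylinder,
    analytic_cylinder_energy_quadrature,
    element_matrices,
    energy_by_quadrature,
    gradient_validity_check,
    solve_field,
    write_vtk,
)
from mscl_lattice.meshing import MeshOptions, mesh_patch

TRI = np.array([[0.1, 0.0], [1.3, 0.2], [0.4, 1.1]])
OPTS = MeshOptions(contour_points=70)


def test_element_stiffness_symmetric(params):
    K, f = element_matrices(TRI, params)
    assert np.allclose(K, K.T, atol=1e-12 * np.abs(K).max())


def test_rigid_translation_costs_only_stretch(params):
    c = 0.37
    a, b = TRI[1] - TRI[0], TRI[2] - TRI[0]
    area = 0.5 * abs(a[0] * b[1] - a[1] * b[0])
    K, _ = element_matrices(TRI, params)
    U = np.zeros(9)
    U[[0, 3, 6]] = c
    e = 0.5 * U @ K @ U
    kt_a2 = params.thickness_modulus / params.half_thickness**2
    assert e == pytest.approx(0.5 * kt_a2 * c**2 * area, rel=1e-10)


def test_degenerate_triangle_rejected(params):
    bad = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        element_matrices(bad, params)


def test_internal_tension_load_under_tension():
    p = BilayerParams(tension=1.0)
    a, b = TRI[1] - TRI[0], TRI[2] - TRI[0]
    area = 0.5 * abs(a[0] * b[1] - a[1] * b[0])
    _, f = element_matrices(TRI, p)
    assert f[[0, 3, 6]] == pytest.approx(p.tension / p.half_thickness * area / 3)
    assert np.all(f[[1, 2, 4, 5, 7, 8]] == 0)


def test_zero_mismatch_zero_energy(cyl, params):
    mesh = mesh_patch([(cyl, (0, 0))], opts=OPTS)
    field = solve_field(mesh, params, {0: 0.0})
    assert field.energy == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(field.u, 0.0)


def test_quadratic_scaling_of_energy(cyl, params):
    mesh = mesh_patch([(cyl, (0, 0))], opts=OPTS)
    e1 = solve_field(mesh, params, {0: cyl.mismatch}).energy
    e2 = solve_field(mesh, params, {0: 3.0 * cyl.mismatch}).energy
    assert e2 / e1 == pytest.approx(9.0, rel=1e-8)


def test_dirichlet_constraints_exact(cyl, params):
    mesh = mesh_patch([(cyl, (0, 0))], opts=OPTS)
    field = solve_field(mesh, params, {0: cyl.mismatch})
    on = mesh.node_tags == 1
    assert np.allclose(field.u[on], params.effective_mismatch(cyl.mismatch))
    assert np.allclose(field.grad[on], 0.0)


def test_fe_matches_analytic_cylinder(cyl, params):
    _, e_exact = analytic_cylinder(params, cyl.radius, cyl.mismatch)
    mesh = mesh_patch([(cyl, (0, 0))], opts=OPTS)
    e_fe = solve_field(mesh, params, {0: cyl.mismatch}).energy
    assert e_fe == pytest.approx(e_exact, rel=0.01)


def test_fe_matches_analytic_cylinder_under_tension(cyl):
    p = BilayerParams(tension=1.5)
    _, e_exact = analytic_cylinder(p, cyl.radius, cyl.mismatch)
    mesh = mesh_patch([(cyl, (0, 0))], opts=OPTS)
    e_fe = solve_field(mesh, p, {0: cyl.mismatch}).energy
    assert e_fe == pytest.approx(e_exact, rel=0.01)


def test_analytic_profile_satisfies_boundary_and_decay(cyl, params):
    prof, e = analytic_cylinder(params, cyl.radius, cyl.mismatch)
    assert prof(cyl.radius) == pytest.approx(
        params.effective_mismatch(cyl.mismatch), rel=1e-9)
    h = 1e-6
    d1 = (prof(cyl.radius + h) - prof(cyl.radius)) / h
    assert abs(d1) < 1e-4
    r = cyl.radius + 12 * params.decay_length
    assert abs(prof(r)) < 1e-4 * abs(prof(cyl.radius))
    assert e > 0


def test_analytic_energy_flux_vs_quadrature(cyl):
    for tau in (0.0, 1.0):
        p = BilayerParams(tension=tau)
        _, e_flux = analytic_cylinder(p, cyl.radius, cyl.mismatch)
        e_quad = analytic_cylinder_energy_quadrature(p, cyl.radius, cyl.mismatch)
        assert e_flux == pytest.approx(e_quad, rel=1e-3)


def test_analytic_quadratic_scaling(cyl, params):
    _, e1 = analytic_cylinder(params, cyl.radius, cyl.mismatch)
    _, e2 = analytic_cylinder(params, cyl.radius, 2 * cyl.mismatch)
    assert e2 / e1 == pytest.approx(4.0, rel=1e-10)
    with pytest.raises(ValueError):
        analytic_cylinder(params, -1.0, 0.3)


def test_assembled_energy_equals_quadrature(pent, params):
    mesh = mesh_patch([(pent, (0, 0))], opts=OPTS)
    field = solve_field(mesh, params, {0: pent.mismatch})
    assert energy_by_quadrature(field) == pytest.approx(field.energy, rel=1e-6)


def test_mesh_refinement_convergence(cyl, params):
    _, e_exact = analytic_cylinder(params, cyl.radius, cyl.mismatch)
    errs = []
    for npts in (40, 80, 160):
        mesh = mesh_patch([(cyl, (0, 0))], opts=MeshOptions(contour_points=npts))
        e = solve_field(mesh, params, {0: cyl.mismatch}).energy
        errs.append(abs(e - e_exact))
    assert errs[1] < errs[0] / 2
    assert errs[2] < errs[1] / 2


def test_gradient_validity_report(cyl, pent, params):
    mesh = mesh_patch([(cyl, (0, 0))], opts=OPTS)
    zero = solve_field(mesh, params, {0: 0.0})
    assert gradient_validity_check(zero)["max_gradient"] == 0.0
    mesh = mesh_patch([(pent, (0, 0))], opts=OPTS)
    field = solve_field(mesh, params, {0: pent.mismatch})
    rep = gradient_validity_check(field)
    assert rep["max_gradient"] < 0.5  # leading-order model stays valid
    allflag = gradient_validity_check(field, threshold=0.0)
    assert allflag["fraction_above_threshold"] > 0.9


def test_tension_shifts_preferred_thickness():
    p = BilayerParams(tension=2.0)
    assert p.equilibrium_shift < 0  # tension thins the bilayer
    assert p.effective_mismatch(0.3) > 0.3
    p0 = BilayerParams(tension=2.0, tension_couples_thickness=False)
    assert p0.effective_mismatch(0.3) == 0.3


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        BilayerParams(bending_rigidity=-1)
    with pytest.raises(ValueError):
        BilayerParams(tension=-0.5)


def test_vtk_output_well_formed(tmp_path, cyl, params):
    mesh = mesh_patch([(cyl, (0, 0))], opts=MeshOptions(contour_points=40))
    field = solve_field(mesh, params, {0: cyl.mismatch})
    path = tmp_path / "field.vtk"
    write_vtk(field, path)
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk")
    assert any(ln.startswith("POINTS") for ln in text)
    assert any(ln.startswith("SCALARS u") for ln in text)


def test_discretization_isotropy_under_rotation(pent, params):
    """Rotating the whole problem leaves the energy unchanged up to
    discretization noise at the test resolution."""
    opts = MeshOptions(contour_points=120)
    energies = []
    for w in (0.0, 0.35):
        mesh = mesh_patch([(pent.with_orientation(w), (0, 0))], opts=opts)
        energies.append(solve_field(mesh, params, {0: pent.mismatch}).energy)
    assert abs(energies[1] - energies[0]) / energies[0] < 2e-3
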