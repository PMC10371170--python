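import numpy as np
import pytest

from chargebem import (
    SphereSpec,
    UniformFieldCoil,
    analytic_uniform_field_case,
    assemble_dense,
    assemble_rhs,
    field_off_surface,
    fibonacci_sphere,
    make_figure8,
    make_sphere_model,
    profile_independence_check,
    solve_iterative,
    solve_model,
    transform_coil,
)
from chargebem.sphere_oracle import (
    default_three_layer_case,
    prolong,
    refine_model,
    refined_ground_truth,
)


class TestSphereSpec:
    def test_contrasts_three_layer(self):
        spec = SphereSpec([0.09, 0.085, 0.08], [0.33, 0.01, 0.33], 1)
        model, _ = make_sphere_model(spec, n_probes=10)
        K = [itf.contrast for itf in model.interfaces]
        # outermost faces air; middle interface has the skull-like shell
        # inside and scalp-like outside; innermost the reverse
        assert K[0] == pytest.approx(1.0)
        assert K[1] == pytest.approx((0.01 - 0.33) / 0.34)
        assert K[2] == pytest.approx((0.33 - 0.01) / 0.34)

    def test_equal_conductivities_zero_contrast(self):
        spec = SphereSpec([0.09, 0.08], [0.33, 0.33], 1)
        model, _ = make_sphere_model(spec, n_probes=10)
        assert model.interfaces[1].contrast == 0.0

    def test_non_nested_radii_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            SphereSpec([0.08, 0.09], [0.33, 0.33], 1)

    def test_probe_shell_inside_innermost(self):
        spec = SphereSpec([0.09, 0.08], [0.33, 0.33], 1)
        _, probes = make_sphere_model(spec, n_probes=64)
        r = np.linalg.norm(probes, axis=1)
        np.testing.assert_allclose(r, 0.8 * 0.08, rtol=1e-12)

    def test_fibonacci_sphere_is_deterministic_and_spread(self):
        a = fibonacci_sphere(100, 1.0)
        b = fibonacci_sphere(100, 1.0)
        np.testing.assert_array_equal(a, b)
        # no two points closer than a tenth of the mean spacing
        d = np.linalg.norm(a[:, None] - a[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.1 * np.sqrt(4 * np.pi / 100)


class TestUniformFieldOracle:
    def test_zero_field_zero_charge(self):
        spec = SphereSpec([0.09], [0.33], subdivisions=2)
        model, _ = make_sphere_model(spec)
        sol, rep = solve_model(model, UniformFieldCoil([0, 0, 0.0]))
        np.testing.assert_array_equal(sol.rho_star, 0.0)

    def test_charge_recovery_and_interior_cancellation(self):
        # rho* = 3 E0 cos(theta), interior field zero; both improve with mesh
        rho_errs, int_errs = [], []
        for sub in (2, 3):
            spec = SphereSpec([0.09], [0.33], subdivisions=sub)
            model, probes = make_sphere_model(spec, n_probes=200)
            e0 = np.array([0.0, 0.0, 1.0])
            coil = UniformFieldCoil(e0)
            sol, _ = solve_model(model, coil, tol=1e-10)
            oracle = analytic_uniform_field_case(0.09, e0)
            exact = oracle.rho_star(model.centroids)
            rho_errs.append(
                np.linalg.norm(sol.rho_star - exact) / np.linalg.norm(exact)
            )
            Et = field_off_surface(model, sol, coil, probes).e_total
            int_errs.append(np.linalg.norm(Et, axis=1).max())
        assert rho_errs[1] <= 0.02
        assert int_errs[1] <= 0.02
        assert rho_errs[1] < rho_errs[0]
        assert int_errs[1] < int_errs[0]

    def test_magnitude_argument_maps_to_z(self):
        oracle = analytic_uniform_field_case(0.05, 2.0)
        np.testing.assert_allclose(
            oracle.rho_star([[0.0, 0.0, 0.05]]), [6.0], rtol=1e-12
        )
        np.testing.assert_array_equal(oracle.interior_field(np.zeros((3, 3))), 0.0)


class TestInductiveOracles:
    def test_profile_independence(self, fig8_above_sphere):
        # interior field of a spherically symmetric conductor does not
        # depend on the radial conductivity profile
        single = SphereSpec([0.09], [0.33], subdivisions=3)
        multi = SphereSpec([0.09, 0.085, 0.08], [0.33, 0.01, 0.33], subdivisions=3)
        report = profile_independence_check(
            single, multi, fig8_above_sphere, tol=1e-8, n_probes=300
        )
        assert report.error_total <= 0.02

    def test_identical_profiles_agree_to_solver_tolerance(self, fig8_above_sphere):
        spec = SphereSpec([0.09], [0.33], subdivisions=2)
        report = profile_independence_check(
            spec, spec, fig8_above_sphere, tol=1e-8, n_probes=100
        )
        assert report.error_total <= 1e-6

    def test_interior_radial_component_vanishes(self, fig8_above_sphere):
        spec = SphereSpec([0.09], [0.33], subdivisions=3)
        model, probes = make_sphere_model(spec, n_probes=300)
        sol, _ = solve_model(model, fig8_above_sphere, tol=1e-8)
        Et = field_off_surface(model, sol, fig8_above_sphere, probes).e_total
        rhat = probes / np.linalg.norm(probes, axis=1, keepdims=True)
        radial = np.einsum("ij,ij->i", Et, rhat)
        assert np.abs(radial).max() / np.linalg.norm(Et, axis=1).max() <= 0.02

    def test_conservative_vs_inductive_interior_behavior(self):
        # same solver, opposite physics: a conservative uniform field is
        # fully cancelled inside; an inductive coil field is not
        spec = SphereSpec([0.09], [0.33], subdivisions=2)
        model, probes = make_sphere_model(spec, n_probes=100)
        uni = UniformFieldCoil([0, 0, 1.0])
        sol_u, _ = solve_model(model, uni, tol=1e-10)
        ratio_u = np.linalg.norm(
            field_off_surface(model, sol_u, uni, probes).e_total
        ) / np.linalg.norm(uni.primary_field(probes))
        coil = transform_coil(make_figure8(), np.eye(3), [0, 0, 0.095])
        sol_c, _ = solve_model(model, coil, tol=1e-10)
        ratio_c = np.linalg.norm(
            field_off_surface(model, sol_c, coil, probes).e_total
        ) / np.linalg.norm(coil.primary_field(probes))
        assert ratio_u < 0.15
        assert ratio_c > 0.5


class TestRefinement:
    def test_prolong_repeats_parent_values(self):
        spec = SphereSpec([0.09, 0.08], [0.33, 0.2], subdivisions=1)
        model, _ = make_sphere_model(spec, n_probes=10)
        rho = np.arange(model.total_facets, dtype=float)
        fine = prolong(model, rho)
        assert len(fine) == 4 * len(rho)
        np.testing.assert_array_equal(fine[:4], 0.0)
        np.testing.assert_array_equal(fine[4:8], 1.0)
        # second interface offset preserved
        n0 = model.interfaces[0].surface.n_facets
        np.testing.assert_array_equal(fine[4 * n0 : 4 * n0 + 4], float(n0))

    def test_refine_model_projects_to_sphere(self):
        spec = SphereSpec([0.09], [0.33], subdivisions=1)
        model, _ = make_sphere_model(spec, n_probes=10)
        fine = refine_model(model, 1)
        surf = fine.interfaces[0].surface
        assert surf.n_facets == 320
        r = np.linalg.norm(surf.vertices, axis=1)
        np.testing.assert_allclose(r, 0.09, rtol=1e-12)

    def test_ground_truth_zero_contrast_reproduces_primary(self, fig8_above_sphere):
        spec = SphereSpec([0.09], [0.33], subdivisions=1)
        model, probes = make_sphere_model(spec, n_probes=50)
        neutral = SphereSpec([0.09], [0.33], subdivisions=1)
        m, _ = make_sphere_model(neutral, n_probes=1)
        from chargebem import HeadModel, Interface

        k0 = HeadModel(
            [
                Interface(
                    m.interfaces[0].surface, 0.33, 0.33,
                    projection=m.interfaces[0].projection,
                )
            ]
        )
        gt = refined_ground_truth(k0, fig8_above_sphere, 1, probes)
        np.testing.assert_allclose(
            gt.e_total, fig8_above_sphere.primary_field(probes), rtol=1e-12
        )
        assert gt.provenance["ground_truth"] is True
        assert gt.provenance["levels"] == 1

    def test_invalid_levels(self, fig8_above_sphere):
        spec = SphereSpec([0.09], [0.33], subdivisions=1)
        model, probes = make_sphere_model(spec, n_probes=10)
        with pytest.raises(ValueError, match="levels"):
            refined_ground_truth(model, fig8_above_sphere, 3, probes)

    def test_default_case_shapes(self):
        model, probes, coil = default_three_layer_case(subdivisions=1, n_probes=40)
        assert model.total_facets == 3 * 80
        assert len(probes) == 40
        assert coil.didt == 9.4e7
        # coil sits 5 mm above the outer sphere
        assert coil.elements[:, 2].mean() == pytest.approx(0.095)
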