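import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from chargebem import (
    HeadModel,
    Interface,
    UniformFieldCoil,
    apply_operator,
    assemble_dense,
    assemble_matrix_free,
    assemble_rhs,
    charge_imbalance,
    conductivity_contrast,
    make_figure8,
    make_icosahedron,
    make_icosphere,
    transform_coil,
    triangle_field_integral,
    triangle_fields,
)
from chargebem.bem_operator import (
    CapacityError,
    ChargeSolution,
    INV_4PI,
    TRI_QUAD_BARY,
    TRI_QUAD_W,
)

# ---------------------------------------------------------------------------
# independent quadrature oracles
# ---------------------------------------------------------------------------

def gauss_triangle_field(tri, pt, n=48):
    """Brute-force field of a unit-density triangle by tensor Gauss quadrature
    on the collapsed (square -> triangle) parameterization; independent of
    the closed-form path it checks."""
    a, b, c = tri
    x, w = np.polynomial.legendre.leggauss(n)
    s = (x + 1) / 2
    ws = w / 2
    S, T = np.meshgrid(s, s, indexing="ij")
    WS, WT = np.meshgrid(ws, ws, indexing="ij")
    u, v = S, (1 - S) * T
    wq = WS * WT * (1 - S)
    rp = a + u[..., None] * (b - a) + v[..., None] * (c - a)
    d = pt - rp
    r3 = np.linalg.norm(d, axis=-1) ** 3
    J = np.linalg.norm(np.cross(b - a, c - a))
    return INV_4PI * J * np.einsum("ij,ijk->k", wq / r3, d)


def adaptive_triangle_field(tri, pt):
    """scipy adaptive 2-D quadrature of the Coulomb kernel (slow, tight)."""
    a, b, c = tri
    J = np.linalg.norm(np.cross(b - a, c - a))

    def comp(k):
        def f(u, w):
            rp = a + u * (b - a) + w * (c - a)
            return (pt - rp)[k] / np.linalg.norm(pt - rp) ** 3

        val, _ = integrate.dblquad(
            f, 0, 1, 0, lambda u: 1 - u, epsabs=1e-13, epsrel=1e-13
        )
        return val

    return INV_4PI * J * np.array([comp(k) for k in range(3)])


# ---------------------------------------------------------------------------

class TestConductivityContrast:
    @pytest.mark.parametrize(
        "sin,sout,expected",
        [(0.33, 0.33, 0.0), (0.33, 0.0, 1.0), (1.0, 3.0, -0.5)],
    )
    def test_values(self, sin, sout, expected):
        assert conductivity_contrast(sin, sout) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            conductivity_contrast(0.0, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0.0, 10.0, allow_nan=False),
        st.floats(0.0, 10.0, allow_nan=False),
    )
    def test_bounded(self, sin, sout):
        if sin + sout == 0:
            return
        assert abs(conductivity_contrast(sin, sout)) <= 1.0


class TestTriangleFieldIntegral:
    UNIT_RIGHT = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])

    def test_matches_adaptive_quadrature(self):
        pt = np.array([0.25, 0.25, 0.5])
        ana = triangle_field_integral(self.UNIT_RIGHT, pt)
        ref = adaptive_triangle_field(self.UNIT_RIGHT, pt)
        np.testing.assert_allclose(ana, ref, rtol=1e-8)

    def test_matches_quadrature_skewed(self, rng):
        tri = rng.normal(size=(3, 3))
        pt = rng.normal(size=3) * 2
        np.testing.assert_allclose(
            triangle_field_integral(tri, pt),
            adaptive_triangle_field(tri, pt),
            rtol=1e-8,
        )

    def test_point_charge_far_limit(self):
        tri = self.UNIT_RIGHT
        centroid = tri.mean(axis=0)
        area = 0.5
        diam = np.sqrt(2.0)
        pt = centroid + np.array([0.3, -0.2, 1.0]) * 100 * diam
        mono = area * INV_4PI * (pt - centroid) / np.linalg.norm(pt - centroid) ** 3
        np.testing.assert_allclose(triangle_field_integral(tri, pt), mono, rtol=1e-4)

    def test_in_plane_principal_value_is_tangential(self):
        inside = np.array([0.3, 0.3, 0.0])
        outside = np.array([2.0, 1.5, 0.0])
        for pt in (inside, outside):
            f = triangle_field_integral(self.UNIT_RIGHT, pt)
            assert abs(f[2]) < 1e-14  # normal component vanishes in-plane

    def test_jump_across_sheet(self):
        # field just above minus just below the facet center: n * 1 (unit rho*)
        pt = np.array([0.25, 0.25, 0.0])
        up = triangle_field_integral(self.UNIT_RIGHT, pt + [0, 0, 1e-9])
        dn = triangle_field_integral(self.UNIT_RIGHT, pt - [0, 0, 1e-9])
        np.testing.assert_allclose(up - dn, [0, 0, 1.0], atol=1e-6)

    def test_vertex_singularity_rejected(self):
        with pytest.raises(ValueError, match="vertex"):
            triangle_field_integral(self.UNIT_RIGHT, np.array([0.0, 0.0, 0.0]))


class TestAssembly:
    def test_diagonal_exactly_half(self, three_layer_small):
        model, _ = three_layer_small
        op = assemble_dense(model)
        assert np.all(np.diag(op.dense_matrix) == 0.5)

    def test_zero_contrast_gives_identity_over_two(self):
        surf = make_icosphere(0.05, 1)
        model = HeadModel([Interface(surf, 0.2, 0.2)])
        op = assemble_dense(model)
        np.testing.assert_array_equal(op.dense_matrix, 0.5 * np.eye(80))

    def test_dense_matches_quadrature_oracle(self):
        # every off-diagonal entry of the 20-facet sphere operator, rebuilt
        # with brute-force inner quadrature at the same outer rule
        surf = make_icosahedron(1.0)
        model = HeadModel([Interface(surf, 0.33, 0.0)])
        op = assemble_dense(model, near_threshold=np.inf)
        tris = surf.vertices[surf.triangles]
        worst = 0.0
        for m in range(20):
            for n in range(20):
                if m == n:
                    continue
                entry = 0.0
                for q, wq in zip(TRI_QUAD_BARY, TRI_QUAD_W):
                    p = q @ tris[m]
                    entry += wq * np.dot(surf.normals[m], gauss_triangle_field(tris[n], p))
                entry *= -model.contrasts[m]
                worst = max(worst, abs(op.dense_matrix[m, n] - entry))
        assert worst <= 1e-7

    def test_oracle_validated_against_adaptive_quadrature(self):
        # anchor the Gauss oracle itself to scipy's adaptive integrator
        surf = make_icosahedron(1.0)
        tris = surf.vertices[surf.triangles]
        pt = TRI_QUAD_BARY[1] @ tris[0]
        np.testing.assert_allclose(
            gauss_triangle_field(tris[1], pt),
            adaptive_triangle_field(tris[1], pt),
            rtol=1e-10,
        )

    def test_capacity_guard(self, three_layer_small):
        model, _ = three_layer_small
        with pytest.raises(CapacityError, match="matrix_free"):
            assemble_dense(model, cap=100)


class TestApplyOperator:
    def test_matrix_free_matches_dense(self, three_layer_small, rng):
        model, _ = three_layer_small
        dense = assemble_dense(model)
        mfree = assemble_matrix_free(model)
        x = rng.normal(size=model.total_facets)
        y_d = apply_operator(dense, x)
        y_m = apply_operator(mfree, x)
        assert np.linalg.norm(y_m - y_d) <= 1e-10 * np.linalg.norm(y_d)

    def test_basis_vector_extracts_column(self, single_sphere_small):
        model, _ = single_sphere_small
        op = assemble_dense(model)
        e7 = np.zeros(model.total_facets)
        e7[7] = 1.0
        np.testing.assert_allclose(apply_operator(op, e7), op.dense_matrix[:, 7])

    def test_linearity(self, single_sphere_small, rng):
        model, _ = single_sphere_small
        op = assemble_matrix_free(model)
        x, y = rng.normal(size=(2, model.total_facets))
        lhs = apply_operator(op, 2.5 * x - 0.3 * y)
        rhs = 2.5 * apply_operator(op, x) - 0.3 * apply_operator(op, y)
        assert np.linalg.norm(lhs - rhs) <= 1e-12 * np.linalg.norm(rhs)

    def test_zero_maps_to_zero_and_length_checked(self, single_sphere_small):
        model, _ = single_sphere_small
        op = assemble_dense(model)
        np.testing.assert_array_equal(apply_operator(op, np.zeros(op.n)), 0.0)
        with pytest.raises(ValueError, match="length"):
            apply_operator(op, np.zeros(op.n + 1))

    def test_constant_density_on_closed_surface_near_nullvector(self):
        # Gauss: at an on-surface point the rest of a uniformly charged
        # closed surface contributes normal field ~1/2, cancelling the
        # diagonal for K=1; A @ 1 shrinks under refinement
        means = []
        for sub in (2, 3):
            surf = make_icosphere(0.09, sub)
            model = HeadModel([Interface(surf, 0.33, 0.0)])
            op = assemble_dense(model)
            y = apply_operator(op, np.ones(op.n))
            means.append(np.sum(np.abs(y) * model.areas) / model.areas.sum())
        assert means[0] < 0.02
        assert means[1] < means[0]


class TestRightHandSide:
    def test_zero_didt(self, three_layer_small):
        model, _ = three_layer_small
        coil = make_figure8(didt=0.0)
        coil = transform_coil(coil, np.eye(3), [0, 0, 0.095])
        np.testing.assert_array_equal(assemble_rhs(model, coil).values, 0.0)

    def test_zero_contrast_rows(self):
        outer = Interface(make_icosphere(0.09, 1), 0.33, 0.0)
        inner = Interface(make_icosphere(0.08, 1), 0.33, 0.33)  # K = 0
        model = HeadModel([outer, inner])
        coil = transform_coil(make_figure8(), np.eye(3), [0, 0, 0.095])
        b = assemble_rhs(model, coil).values
        np.testing.assert_array_equal(b[80:], 0.0)
        assert np.any(b[:80] != 0.0)

    def test_uniform_field_projects_cosine(self):
        surf = make_icosphere(1.0, 2)
        model = HeadModel([Interface(surf, 1.0, 0.0)])  # K = 1
        b = assemble_rhs(model, UniformFieldCoil([0, 0, 2.0])).values
        np.testing.assert_allclose(b, 2.0 * surf.normals[:, 2], rtol=1e-14)

    def test_coil_inside_model_warns(self, three_layer_small):
        model, _ = three_layer_small
        coil = make_figure8()  # at origin, inside the spheres
        with pytest.warns(UserWarning, match="inside"):
            assemble_rhs(model, coil)


class TestChargeNeutrality:
    def test_closed_loop_excitation_neutral_per_interface(
        self, three_layer_small, fig8_above_sphere
    ):
        model, _ = three_layer_small
        op = assemble_dense(model)
        b = assemble_rhs(model, fig8_above_sphere)
        x = np.linalg.solve(2 * op.dense_matrix, 2 * b.values)
        sol = ChargeSolution(x, 0.0, "test")
        # solenoidal E_p: net induced charge vanishes on every closed surface
        assert np.all(charge_imbalance(model, sol) <= 1e-6)
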