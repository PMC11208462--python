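"""WSS metric definitions, discrete surface operators and reductions."""

import numpy as np
import pytest

from aneukit.mesh import TimeVaryingVectorField, project_tangential
from aneukit.metrics import (
    area_index,
    gon,
    osi,
    summarize,
    surface_divergence,
    surface_gradient,
    tawss,
    wssd,
    wssg,
)
from aneukit.synthetic import make_analytic_sphere_field

from conftest import icosphere_mesh, interior_vertex_mask, planar_patch


def steady_series(vec_per_vertex, n_t=16, period=1.0):
    return TimeVaryingVectorField(
        np.repeat(vec_per_vertex[None], n_t, axis=0), period=period
    )


class TestTawssOsi:
    def test_constant_field(self):
        mesh = planar_patch(6, 6)
        fld = steady_series(np.tile([3.0, 4.0, 0.0], (mesh.n_vertices, 1)))
        assert tawss(mesh, fld).values == pytest.approx(5.0)
        assert osi(mesh, fld).values == pytest.approx(0.0)

    def test_separable_modulation_mean(self):
        """τ(t) = A(1 + sin 2πt/T)·e has TAWSS = A (mean of 1+sin is 1)."""
        mesh = planar_patch(4, 4)
        n_t, A = 64, 2.0
        s = 1.0 + np.sin(2 * np.pi * np.arange(n_t) / n_t)
        base = np.tile([1.0, 0.0, 0.0], (mesh.n_vertices, 1))
        fld = TimeVaryingVectorField(A * s[:, None, None] * base[None], period=1.0)
        assert np.allclose(tawss(mesh, fld).values, A, atol=1e-3)

    def test_zero_field(self):
        mesh = planar_patch(3, 3)
        fld = steady_series(np.zeros((mesh.n_vertices, 3)))
        assert np.all(tawss(mesh, fld).values == 0.0)
        assert np.all(osi(mesh, fld).values == 0.0)  # ε convention

    def test_full_reversal_gives_half(self):
        mesh = planar_patch(4, 4)
        n_t = 32
        sign = np.where(np.arange(n_t) < n_t // 2, 1.0, -1.0)
        base = np.tile([2.0, 0.0, 0.0], (mesh.n_vertices, 1))
        fld = TimeVaryingVectorField(sign[:, None, None] * base[None], period=1.0)
        assert osi(mesh, fld).values == pytest.approx(0.5)


class TestSurfaceOperators:
    def test_linear_planar_divergence_exact(self):
        mesh = planar_patch(8, 8)
        a, b = 2.0, -3.0
        vec = np.column_stack(
            [a * mesh.vertices[:, 0], b * mesh.vertices[:, 1], np.zeros(mesh.n_vertices)]
        )
        div = surface_divergence(mesh, vec)
        assert np.allclose(div, a + b, atol=1e-8)

    def test_uniform_field_zero_divergence(self):
        mesh = planar_patch(6, 6)
        vec = np.tile([1.0, 2.0, 0.0], (mesh.n_vertices, 1))
        assert np.abs(surface_divergence(mesh, vec)).max() < 1e-8

    def test_sphere_divergence_oracle(self, fine_icosphere):
        """∇_s·(∇_s Y_1^0) = −2 Y_1^0 within 2% interior max error."""
        f = make_analytic_sphere_field(fine_icosphere, 1, 0, "gradient")
        div = surface_divergence(fine_icosphere, f.values)
        err = np.abs(div - f.exact).max() / np.abs(f.exact).max()
        assert err < 0.02

    def test_divergence_error_decreases_under_refinement(self):
        errs = []
        for sub in (3, 4, 5):
            mesh = icosphere_mesh(sub)
            f = make_analytic_sphere_field(mesh, 1, 0, "gradient")
            div = surface_divergence(mesh, f.values)
            errs.append(np.abs(div - f.exact).max() / np.abs(f.exact).max())
        assert errs[0] > errs[1] > errs[2]

    def test_planar_gradient_exact(self):
        mesh = planar_patch(8, 8)
        g = surface_gradient(mesh, 3.0 * mesh.vertices[:, 0])
        np.testing.assert_allclose(g, np.tile([3.0, 0, 0], (mesh.n_vertices, 1)), atol=1e-8)

    def test_constant_map_zero_gradient(self):
        mesh = planar_patch(5, 5)
        assert np.abs(surface_gradient(mesh, np.full(mesh.n_vertices, 7.0))).max() < 1e-8

    def test_sphere_gradient_oracle(self, fine_icosphere):
        """|∇_s z| = sinθ on the unit sphere within 2% interior error."""
        g = surface_gradient(fine_icosphere, fine_icosphere.vertices[:, 2])
        theta = np.arccos(np.clip(fine_icosphere.vertices[:, 2], -1, 1))
        err = np.abs(np.linalg.norm(g, axis=1) - np.sin(theta)).max()
        assert err < 0.02


class TestWssdWssgGon:
    def test_steady_planar_wssd(self):
        mesh = planar_patch(8, 8)
        a, b = 1.5, 2.5
        vec = np.column_stack(
            [a * mesh.vertices[:, 0], b * mesh.vertices[:, 1], np.zeros(mesh.n_vertices)]
        )
        fld = steady_series(vec)
        assert np.allclose(wssd(mesh, fld).values, a + b, atol=1e-8)

    def test_modulated_equals_steady(self):
        """s(t)-modulated field (mean 1) has the same WSSD as the steady one."""
        mesh = planar_patch(6, 6)
        vec = np.column_stack(
            [mesh.vertices[:, 0], -2 * mesh.vertices[:, 1], np.zeros(mesh.n_vertices)]
        )
        n_t = 32
        s = 1.0 + 0.7 * np.sin(2 * np.pi * np.arange(n_t) / n_t)
        fld = TimeVaryingVectorField(s[:, None, None] * vec[None], period=1.0)
        np.testing.assert_allclose(
            wssd(mesh, fld).values, wssd(mesh, steady_series(vec)).values, atol=1e-3
        )

    def test_raw_integral_scales_with_period(self):
        mesh = planar_patch(5, 5)
        vec = np.column_stack(
            [mesh.vertices[:, 0], np.zeros(mesh.n_vertices), np.zeros(mesh.n_vertices)]
        )
        fld = steady_series(vec, period=0.8)
        raw = wssd(mesh, fld, cycle_average=False).values
        avg = wssd(mesh, fld, cycle_average=True).values
        np.testing.assert_allclose(raw, 0.8 * avg, rtol=1e-12)

    def test_uniform_steady_wssg_zero(self):
        mesh = planar_patch(6, 6)
        fld = steady_series(np.tile([2.0, 1.0, 0.0], (mesh.n_vertices, 1)))
        assert np.abs(wssg(mesh, fld).values).max() < 1e-8
        assert np.abs(gon(mesh, fld).values).max() < 1e-12

    def test_linear_shear_wssg(self):
        """τ = (a·x, 0, 0) with x > 0: p = x̂ and WSSG = |a|."""
        mesh = planar_patch(8, 8, x0=1.0)  # keep x positive: stable p frame
        a = -4.0
        vec = np.column_stack(
            [a * mesh.vertices[:, 0], np.zeros(mesh.n_vertices), np.zeros(mesh.n_vertices)]
        )
        assert np.allclose(wssg(mesh, steady_series(vec)).values, abs(a), atol=1e-8)

    def test_reversing_gradient_gon_one(self):
        """G flipping sign each half-period drives GON to 1."""
        mesh = planar_patch(6, 6, x0=1.0)
        n_t = 32
        sign = np.where(np.arange(n_t) < n_t // 2, 1.0, -1.0)
        vec = np.column_stack(
            [mesh.vertices[:, 0], np.zeros(mesh.n_vertices), np.zeros(mesh.n_vertices)]
        )
        fld = TimeVaryingVectorField(sign[:, None, None] * vec[None], period=1.0)
        assert gon(mesh, fld).values == pytest.approx(1.0)

    def test_frobenius_variant_agrees_on_single_component(self):
        mesh = planar_patch(8, 8, x0=1.0)
        vec = np.column_stack(
            [3.0 * mesh.vertices[:, 0], np.zeros(mesh.n_vertices), np.zeros(mesh.n_vertices)]
        )
        fld = steady_series(vec)
        assert np.allclose(
            wssg(mesh, fld, gradient_def="frobenius").values, 3.0, atol=1e-8
        )


class TestInvariants:
    def test_bounds_on_random_fields(self, unit_icosphere):
        mesh = unit_icosphere
        rng = np.random.default_rng(42)
        for _ in range(3):
            raw = rng.normal(size=(16, mesh.n_vertices, 3)) * rng.lognormal(size=16)[:, None, None]
            fld = project_tangential(mesh, raw, period=1.0)
            o = osi(mesh, fld).values
            g = gon(mesh, fld).values
            t = tawss(mesh, fld).values
            assert np.all((o >= 0) & (o <= 0.5))
            assert np.all((g >= 0) & (g <= 1.0))
            assert np.all(t >= 0)

    def test_linearity_in_amplitude(self, unit_icosphere):
        mesh = unit_icosphere
        rng = np.random.default_rng(7)
        fld = project_tangential(
            mesh, rng.normal(size=(16, mesh.n_vertices, 3)), period=1.0
        )
        scaled = TimeVaryingVectorField(-2.5 * fld.samples, period=1.0)
        np.testing.assert_allclose(
            wssd(mesh, scaled).values, -2.5 * wssd(mesh, fld).values, rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(
            tawss(mesh, scaled).values, 2.5 * tawss(mesh, fld).values, rtol=1e-10
        )

    def test_rigid_rotation_invariance(self, unit_icosphere):
        from scipy.spatial.transform import Rotation

        mesh = unit_icosphere
        rng = np.random.default_rng(11)
        fld = project_tangential(
            mesh, rng.normal(size=(16, mesh.n_vertices, 3)), period=1.0
        )
        R = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        from aneukit.mesh import TriSurfaceMesh

        mesh_r = TriSurfaceMesh(mesh.vertices @ R.T, mesh.faces.copy())
        fld_r = TimeVaryingVectorField(fld.samples @ R.T, period=1.0)
        for func in (tawss, osi, wssd, wssg, gon):
            np.testing.assert_allclose(
                func(mesh_r, fld_r).values,
                func(mesh, fld).values,
                rtol=1e-9,
                atol=1e-10,
            )


class TestReductions:
    def test_constant_summary(self, hemisphere):
        mesh, _ = hemisphere
        from aneukit.metrics import MetricMap

        m = MetricMap("TAWSS", np.full(mesh.n_vertices, 4.2), "Pa")
        s = summarize(mesh, m)
        assert s.max == s.min == pytest.approx(4.2)
        assert s.space_average == pytest.approx(4.2)

    def test_area_weighted_mean(self):
        """{1 Pa on weight 1, 3 Pa on weight 3} averages to 2.5 Pa."""
        mesh = planar_patch(2, 2)  # 4 vertices, equal areas
        from aneukit.metrics import MetricMap

        vals = np.array([1.0, 1.0, 3.0, 3.0])
        w = mesh.vertex_areas
        expect = np.average(vals, weights=w)
        s = summarize(mesh, MetricMap("TAWSS", vals, "Pa"))
        assert s.space_average == pytest.approx(expect)
        assert s.min <= s.space_average <= s.max

    def test_empty_region_errors(self):
        mesh = planar_patch(2, 2)
        from aneukit.metrics import MetricMap

        with pytest.raises(ValueError):
            summarize(mesh, MetricMap("OSI", np.zeros(4), "1"), region="parent")

    def test_area_index_uniform(self, hemisphere):
        mesh, _ = hemisphere
        from aneukit.metrics import MetricMap

        m = MetricMap("TAWSS", np.full(mesh.n_vertices, 10.0), "Pa")
        assert area_index(mesh, m, 8.3, "above").ratio == pytest.approx(1.0)
        # strict inequality: threshold equal to the value passes nothing
        assert area_index(mesh, m, 10.0, "above").ratio == 0.0
        assert area_index(mesh, m, 10.0, "below").ratio == 0.0

    def test_area_index_two_level(self, hemisphere):
        """Half the dome at 2 Pa, half at 20 Pa → ratio 0.5 ± one face band."""
        mesh, _ = hemisphere
        from aneukit.metrics import MetricMap

        phi = np.arctan2(mesh.vertices[:, 1], mesh.vertices[:, 0])
        vals = np.where(phi >= 0, 20.0, 2.0)
        res = area_index(mesh, MetricMap("TAWSS", vals, "Pa"), 8.3, "above")
        assert res.ratio == pytest.approx(0.5, abs=0.03)
        below = area_index(mesh, MetricMap("TAWSS", vals, "Pa"), 8.3, "below")
        assert res.ratio + below.ratio == pytest.approx(1.0, abs=1e-12)
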