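"""Cubic fitting, deviation profiles, Frenet-Serret curvature/torsion."""

import numpy as np
import pytest

from dbsdeform import (
    CubicCurveModel,
    DegenerateCurveError,
    FitFailureError,
    InvalidArgumentError,
    IrregularCurveError,
    SkeletonPolyline,
    deformation_profile,
    fit_cubic,
    frenet_curvature_torsion,
    frenet_profile,
)

from conftest import cumulative_chord


def _skeleton_from_coeffs(coeffs, n=60, noise_sd=0.0, rng=None, arc="chord"):
    t = np.linspace(0, 1, n)
    pts = np.vander(t, 4, increasing=True) @ coeffs
    if noise_sd:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    arc_col = t * 70.0 if arc == "parameter" else cumulative_chord(pts)
    return SkeletonPolyline(points=pts, cumulative_arc=arc_col)


class TestFitCubic:
    def test_exact_cubic_recovered_under_matching_parametrization(self):
        # arc column proportional to the generating parameter (uniform slabs)
        coeffs = np.array([[1.0, -2.0, 0.5], [3.0, 1.0, 60.0],
                           [-2.0, 0.5, 4.0], [1.5, -0.3, -2.0]])
        model = fit_cubic(_skeleton_from_coeffs(coeffs, arc="parameter"))
        np.testing.assert_allclose(model.coeffs, coeffs, atol=1e-6)
        assert model.r_squared > 1 - 1e-12
        assert model.rms_residual <= 1e-9

    def test_electrode_like_cubic_fits_essentially_perfectly(self):
        # chord-length parametrization of a realistic near-straight lead
        coeffs = np.array([[0.0, 0.0, 0.0], [1.0, -0.5, 70.0],
                           [2.0, 1.0, 0.0], [-1.5, 0.2, 0.0]])
        model = fit_cubic(_skeleton_from_coeffs(coeffs))
        assert model.r_squared > 1 - 1e-6
        assert model.rms_residual < 0.02

    def test_straight_line_has_zero_high_order_terms(self):
        coeffs = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 70.0],
                           [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        model = fit_cubic(_skeleton_from_coeffs(coeffs))
        assert np.abs(model.coeffs[2:]).max() <= 1e-9

    def test_noisy_rms_matches_noise_level(self):
        # quick Monte-Carlo sanity (the full 100-seed panel runs elsewhere)
        coeffs = np.array([[0.0, 0.0, 0.0], [1.0, -0.5, 70.0],
                           [2.0, 1.0, 0.0], [-1.5, 0.2, 0.0]])
        for seed in range(3):
            rng = np.random.default_rng(seed)
            model = fit_cubic(_skeleton_from_coeffs(coeffs, n=140, noise_sd=0.1, rng=rng))
            assert 0.05 < model.rms_residual < 0.15

    def test_too_few_points_rejected(self):
        pts = np.outer(np.linspace(0, 1, 5), [0, 0, 70.0])
        skel = SkeletonPolyline(points=pts, cumulative_arc=cumulative_chord(pts))
        with pytest.raises(InvalidArgumentError):
            fit_cubic(skel)

    def test_degenerate_identical_points_raise(self):
        class IdenticalPoints:
            points = np.full((8, 3), 5.0)
            cumulative_arc = np.arange(8.0)  # bogus arc from a broken upstream

        with pytest.raises(FitFailureError):
            fit_cubic(IdenticalPoints())


class TestDeformationProfile:
    def test_straight_curve_all_deviations_zero(self):
        model = CubicCurveModel(
            np.array([[0, 0, 0], [0, 0, 70.0], [0, 0, 0], [0, 0, 0]]), 1.0, 0.0, 70.0
        )
        prof = deformation_profile(model)
        assert prof.n_samples == 100
        assert np.abs(prof.deviations).max() <= 1e-9

    def test_planar_bow_max_deviation(self):
        # x(t) = 4 t (1 - t): unit bow on a 70 mm chord
        model = CubicCurveModel(
            np.array([[0, 0, 0], [4.0, 0, 70.0], [-4.0, 0, 0], [0, 0, 0]]), 1.0, 0.0, 70.0
        )
        prof = deformation_profile(model)
        i_max = int(np.argmax(prof.deviations[:, 0]))
        assert abs(prof.deviations[:, 0].max() - 1.0) < 1e-3
        assert 40 <= i_max <= 60  # near mid-electrode
        assert np.abs(prof.deviations[:, 1]).max() <= 1e-9
        # z deviation is second order in the bow amplitude, not exactly zero
        assert np.abs(prof.deviations[:, 2]).max() <= 0.05

    def test_endpoint_deviations_always_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            coeffs = rng.normal(0, 1, (4, 3))
            coeffs[1, 2] += 60.0
            model = CubicCurveModel(coeffs, 1.0, 0.0, 60.0)
            prof = deformation_profile(model)
            assert np.abs(prof.deviations[0]).max() <= 1e-9
            assert np.abs(prof.deviations[-1]).max() <= 1e-9

    def test_zero_chord_raises(self):
        model = CubicCurveModel(
            np.array([[0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0], [0, 0, 0]]), 1.0, 0.0, 1.0
        )
        with pytest.raises(DegenerateCurveError):
            deformation_profile(model)


class TestFrenet:
    def test_twisted_cubic_closed_form(self):
        model = CubicCurveModel(
            np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]), 1.0, 0.0, 1.0
        )
        k, tau, defined = frenet_curvature_torsion(
            model.deriv1(0.0), model.deriv2(0.0), model.deriv3(0.0)
        )
        assert abs(k - 2.0) <= 1e-9
        assert abs(tau - 3.0) <= 1e-9
        assert defined

    def test_helix_closed_form(self):
        a, b = 3.0, 4.0
        t = np.linspace(0, 4 * np.pi, 31)
        d1 = np.stack([-a * np.sin(t), a * np.cos(t), np.full_like(t, b)], axis=-1)
        d2 = np.stack([-a * np.cos(t), -a * np.sin(t), np.zeros_like(t)], axis=-1)
        d3 = np.stack([a * np.sin(t), -a * np.cos(t), np.zeros_like(t)], axis=-1)
        k, tau, _ = frenet_curvature_torsion(d1, d2, d3)
        np.testing.assert_allclose(k, a / (a**2 + b**2), atol=1e-12)
        np.testing.assert_allclose(tau, b / (a**2 + b**2), atol=1e-12)

    def test_planar_curve_torsion_zero_where_defined(self):
        model = CubicCurveModel(
            np.array([[0, 0, 0], [2.0, 1.0, 0], [1.0, -3.0, 0], [0.5, 0.2, 0]]),
            1.0, 0.0, 3.0,
        )
        prof = frenet_profile(model, deformation_profile(model))
        assert np.all(prof.torsion[prof.torsion_defined] == 0.0)
        assert np.any(prof.torsion_defined)

    def test_numeric_differentiation_oracle(self):
        # central differences (h = 1e-4) on 50 random cubics; extended
        # precision keeps stencil roundoff below the comparison tolerance
        rng = np.random.default_rng(123)
        h = np.longdouble(1e-4)
        t0 = np.longdouble(0.5)
        for _ in range(50):
            coeffs = rng.normal(0, 1, (4, 3))
            coeffs[1] += np.array([0, 0, 50.0])  # keep the curve regular
            model = CubicCurveModel(coeffs, 1.0, 0.0, 50.0)

            def pos(t, c=coeffs.astype(np.longdouble)):
                powers = np.array([1.0, t, t**2, t**3], dtype=np.longdouble)
                return powers @ c

            d1 = (pos(t0 + h) - pos(t0 - h)) / (2 * h)
            d2 = (pos(t0 + h) - 2 * pos(t0) + pos(t0 - h)) / h**2
            d3 = (pos(t0 + 2 * h) - 2 * pos(t0 + h) + 2 * pos(t0 - h)
                  - pos(t0 - 2 * h)) / (2 * h**3)
            k_num, tau_num, _ = frenet_curvature_torsion(
                d1.astype(float), d2.astype(float), d3.astype(float)
            )
            k, tau, _ = frenet_curvature_torsion(
                model.deriv1(t0), model.deriv2(t0), model.deriv3(t0)
            )
            assert abs(k_num - k) <= 1e-5 * max(abs(k), 1e-12)
            assert abs(tau_num - tau) <= 1e-5 * max(abs(tau), 1e-9)

    def test_vanishing_speed_raises(self):
        model = CubicCurveModel(
            np.array([[0, 0, 0], [0, 0, 0], [0, 0, 0], [1.0, 0, 0]]), 1.0, 0.0, 1.0
        )
        prof = deformation_profile(model)
        with pytest.raises(IrregularCurveError, match="t ="):
            frenet_profile(model, prof)


class TestInvariances:
    def _random_model(self, rng):
        coeffs = rng.normal(0, 0.5, (4, 3))
        coeffs[1, 2] += 60.0
        return CubicCurveModel(coeffs, 1.0, 0.0, 60.0)

    def test_rigid_motion_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(21)
        from scipy.spatial.transform import Rotation

        for _ in range(5):
            model = self._random_model(rng)
            rot = Rotation.random(rng=rng).as_matrix()
            moved_coeffs = model.coeffs @ rot.T
            moved_coeffs[0] += rng.normal(0, 10, 3)
            moved = CubicCurveModel(moved_coeffs, 1.0, 0.0, 60.0)
            p0 = frenet_profile(model, deformation_profile(model))
            p1 = frenet_profile(moved, deformation_profile(moved))
            np.testing.assert_allclose(p1.curvature, p0.curvature, rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(p1.torsion, p0.torsion, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(
                np.linalg.norm(p1.deviations, axis=1),
                np.linalg.norm(p0.deviations, axis=1),
                atol=1e-9,
            )

    def test_reflection_flips_torsion_sign(self):
        rng = np.random.default_rng(5)
        model = self._random_model(rng)
        mirrored = CubicCurveModel(model.coeffs * [-1, 1, 1], 1.0, 0.0, 60.0)
        p0 = frenet_profile(model, deformation_profile(model))
        p1 = frenet_profile(mirrored, deformation_profile(mirrored))
        np.testing.assert_allclose(p1.curvature, p0.curvature, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(p1.torsion, -p0.torsion, atol=1e-9)

    def test_uniform_scaling(self):
        rng = np.random.default_rng(9)
        model = self._random_model(rng)
        s = 2.5
        scaled = CubicCurveModel(model.coeffs * s, 1.0, 0.0, 60.0 * s)
        p0 = frenet_profile(model, deformation_profile(model))
        p1 = frenet_profile(scaled, deformation_profile(scaled))
        np.testing.assert_allclose(p1.deviations, s * p0.deviations, atol=1e-9)
        np.testing.assert_allclose(p1.curvature, p0.curvature / s, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(p1.torsion, p0.torsion / s, rtol=1e-9, atol=1e-9)
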