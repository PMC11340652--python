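import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oliveshape import geometry
from oliveshape.geometry import (
    Contour,
    caliper_dimensions,
    contour_from_silhouette,
    curvature_profile,
    fit_ellipse,
    locate_landmarks,
    normalize_points,
    polygon_area,
    polygon_perimeter,
    symmetry_measures,
)
from oliveshape.imaging import Silhouette

from conftest import ellipse_contour, ellipse_points


def ramanujan_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def square_silhouette(side_px=60, mm_per_px=0.1):
    mask = np.zeros((side_px + 20, side_px + 20), dtype=bool)
    mask[10 : 10 + side_px, 10 : 10 + side_px] = True
    return Silhouette(mask=mask, mm_per_px=mm_per_px)


def raster_ellipse_mask(a_px, b_px, angle_deg, mm_per_px=0.1):
    pad = int(max(a_px, b_px)) + 5
    yy, xx = np.mgrid[-pad:pad + 1, -pad:pad + 1].astype(float)
    t = np.deg2rad(angle_deg)
    u = xx * np.cos(t) + yy * np.sin(t)
    v = -xx * np.sin(t) + yy * np.cos(t)
    mask = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return Silhouette(mask=mask, mm_per_px=mm_per_px)


class TestContourExtraction:
    def test_square_mask_area(self):
        c = contour_from_silhouette(square_silhouette())
        assert polygon_area(c) == pytest.approx(36.0, rel=0.03)

    def test_tilted_ellipse_is_normalized_upright(self):
        sil = raster_ellipse_mask(a_px=100, b_px=50, angle_deg=30)
        c = contour_from_silhouette(sil)
        height, width, _, _ = caliper_dimensions(c)
        assert height / width == pytest.approx(2.0, rel=0.02)

    def test_resampling_resolution_consistency(self):
        sil = raster_ellipse_mask(a_px=80, b_px=50, angle_deg=10)
        a256 = polygon_area(contour_from_silhouette(sil, n_points=256))
        a1024 = polygon_area(contour_from_silhouette(sil, n_points=1024))
        assert a256 == pytest.approx(a1024, rel=0.005)

    def test_degenerate_mask_rejected(self):
        tiny = np.zeros((30, 30), dtype=bool)
        tiny[10:15, 10:15] = True
        with pytest.raises(Exception):
            contour_from_silhouette(Silhouette(mask=tiny, mm_per_px=0.1))


class TestAreaPerimeter:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        c = normalize_points(sq, mm_per_px=0.05, n_points=256)
        assert polygon_area(c) == pytest.approx(1.0, rel=0.01)
        assert polygon_perimeter(c) == pytest.approx(4.0, rel=0.01)

    def test_disc_area(self):
        c = ellipse_contour(5.0, 5.0)
        assert polygon_area(c) == pytest.approx(np.pi * 25, rel=0.01)

    def test_ellipse_perimeter_vs_ramanujan(self):
        c = ellipse_contour(2.0, 1.0)
        assert polygon_perimeter(c) == pytest.approx(ramanujan_perimeter(2, 1), rel=0.01)


class TestCaliper:
    def test_ellipse_dimensions(self):
        height, width, hs, widths = caliper_dimensions(ellipse_contour(2.0, 1.0))
        assert height == pytest.approx(4.0, rel=0.01)
        assert width == pytest.approx(2.0, rel=0.01)
        # profile at the argmax height equals the reported width
        assert widths.max() == pytest.approx(width)

    def test_square_profile_constant(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        c = normalize_points(sq, mm_per_px=0.05, n_points=512)
        _, _, hs, widths = caliper_dimensions(c)
        inner = widths[(hs > 0.05) & (hs < 0.95)]
        assert np.ptp(inner) / inner.mean() < 0.02


class TestEllipseFit:
    def test_exact_recovery(self):
        fit = fit_ellipse(ellipse_contour(2.0, 1.0))
        assert fit.semi_major == pytest.approx(2.0, abs=1e-6)
        assert fit.semi_minor == pytest.approx(1.0, abs=1e-6)
        assert fit.rms_residual < 1e-6

    def test_circle(self):
        fit = fit_ellipse(ellipse_contour(1.0, 1.0))
        assert fit.semi_major == pytest.approx(1.0, abs=1e-6)
        assert fit.semi_minor == pytest.approx(1.0, abs=1e-6)

    def test_noisy_recovery_monte_carlo(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = ellipse_points(2.0, 1.0, n=512)
            radial = pts / np.hypot(*pts.T)[:, None]
            noisy = pts + radial * rng.normal(0, 0.01, size=(len(pts), 1))
            c = normalize_points(noisy, mm_per_px=0.05, n_points=512)
            fit = fit_ellipse(c)
            errs.append(max(abs(fit.semi_major - 2.0) / 2.0, abs(fit.semi_minor - 1.0)))
        assert np.median(errs) < 0.01


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        kappa = curvature_profile(ellipse_contour(2.0, 2.0)).kappa
        assert kappa.mean() == pytest.approx(0.5, rel=0.05)

    def test_ellipse_apex_to_side_curvature_ratio(self):
        c = ellipse_contour(2.0, 1.0)
        kappa = curvature_profile(c).kappa
        apex, _ = locate_landmarks(c)
        side = int(np.argmax(c.points[:, 0]))
        # closed form: κ(major end)/κ(minor end) = (a/b²)/(b/a²) = 8
        assert kappa[apex] / kappa[side] == pytest.approx(8.0, rel=0.10)

    def test_scaling_halves_curvature(self):
        c = ellipse_contour(2.0, 1.0)
        doubled = normalize_points(c.points * 2.0, mm_per_px=0.05, n_points=512)
        k1 = curvature_profile(c).kappa.mean()
        k2 = curvature_profile(doubled).kappa.mean()
        assert k2 == pytest.approx(k1 / 2, rel=0.01)

    def test_window_too_large_rejected(self):
        c = ellipse_contour(2.0, 1.0, n_points=64)
        with pytest.raises(ValueError):
            curvature_profile(c, window=33)


class TestLandmarks:
    def test_ellipse_apex_at_top(self):
        c = ellipse_contour(2.0, 1.0)
        apex, base = locate_landmarks(c)
        assert c.points[apex, 1] == pytest.approx(c.points[:, 1].max())
        assert c.points[base, 1] == pytest.approx(c.points[:, 1].min())

    def test_apex_base_separation_on_random_ovoids(self):
        from oliveshape.synth import ShapeParams, curve_points

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = ShapeParams(
                organ="fruit",
                height_mm=float(rng.uniform(12, 25)),
                width_A_mm=float(rng.uniform(8, 18)),
                width_B_mm=10.0,
                taper=float(rng.uniform(0, 0.2)),
                apex_sharpness=float(rng.uniform(1.0, 1.8)),
            )
            p.width_A_mm = min(p.width_A_mm, p.height_mm * 0.95)
            _, _, pts = curve_points(p, p.width_A_mm, rng, n_theta=1024)
            c = normalize_points(pts, 0.05, n_points=512)
            apex, base = locate_landmarks(c)
            sep = abs(apex - base) % 512
            sep = min(sep, 512 - sep)
            assert 256 * 0.9 <= sep <= 256 * 1.1


class TestSymmetry:
    def test_ellipse_symmetric(self):
        asym, vsym = symmetry_measures(ellipse_contour(2.0, 1.0))
        assert asym < 0.01
        assert vsym == pytest.approx(0.5, abs=0.02)

    def test_egg_widest_section_height_recovered(self):
        from oliveshape.synth import ShapeParams, curve_points, _curve_truth

        p = ShapeParams(organ="fruit", height_mm=20, width_A_mm=14, width_B_mm=14,
                        taper=0.25, apex_sharpness=1.2)
        rng = np.random.default_rng(0)
        theta, rho, pts = curve_points(p, 14, rng)
        truth = _curve_truth(pts, theta, rho)
        _, vsym = symmetry_measures(normalize_points(pts, 0.05))
        assert vsym == pytest.approx(truth["widest_height_norm"], abs=0.02)


class TestInvariances:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=6.2))
    def test_rotation_invariance(self, angle):
        base = ellipse_contour(2.0, 1.0)
        rotated = normalize_points(
            ellipse_points(2.0, 1.0, angle=angle), mm_per_px=0.05, n_points=512
        )
        assert polygon_area(rotated) == pytest.approx(polygon_area(base), rel=0.01)
        h0, w0, _, _ = caliper_dimensions(base)
        h1, w1, _, _ = caliper_dimensions(rotated)
        assert h1 == pytest.approx(h0, rel=0.01)
        assert w1 == pytest.approx(w0, rel=0.01)

    def test_scale_equivariance(self):
        sil = raster_ellipse_mask(a_px=80, b_px=50, angle_deg=20, mm_per_px=0.1)
        sil2 = raster_ellipse_mask(a_px=80, b_px=50, angle_deg=20, mm_per_px=0.3)
        c1, c2 = contour_from_silhouette(sil), contour_from_silhouette(sil2)
        assert polygon_area(c2) == pytest.approx(9 * polygon_area(c1), rel=0.01)
        assert polygon_perimeter(c2) == pytest.approx(3 * polygon_perimeter(c1), rel=0.01)
        k1 = np.abs(curvature_profile(c1).kappa).mean()
        k2 = np.abs(curvature_profile(c2).kappa).mean()
        assert k2 == pytest.approx(k1 / 3, rel=0.01)

    def test_circularity_primitives(self):
        disc = ellipse_contour(3.0, 3.0)
        circ = 4 * np.pi * polygon_area(disc) / polygon_perimeter(disc) ** 2
        assert circ == pytest.approx(1.0, abs=0.02)
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        c = normalize_points(sq, mm_per_px=0.05, n_points=512)
        circ_sq = 4 * np.pi * polygon_area(c) / polygon_perimeter(c) ** 2
        assert circ_sq == pytest.approx(np.pi / 4, rel=0.02)

    def test_area_matches_pixel_count(self):
        for angle in (0, 17, 45):
            sil = raster_ellipse_mask(a_px=70, b_px=40, angle_deg=angle)
            c = contour_from_silhouette(sil)
            assert polygon_area(c) == pytest.approx(sil.area_mm2, rel=0.03)
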