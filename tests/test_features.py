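import numpy as np
import pandas as pd
import pytest

from oliveshape import features
from oliveshape.features import (
    ENDOCARP_EXTENDED_NAMES,
    ENDOCARP_FEATURE_NAMES,
    FRUIT_FEATURE_NAMES,
    FeatureTable,
    OrganSample,
    build_feature_table,
    detect_nipple,
    endocarp_features,
    fruit_features,
    leaf_features_from_silhouette,
    split_petiole,
)
from oliveshape.geometry import normalize_points
from oliveshape.synth import ShapeParams, curve_points, generate_leaf, generate_shape

from conftest import ellipse_contour


def fruit_contour(height=20.0, width=14.0, seed=0, **kw):
    p = ShapeParams(organ="fruit", height_mm=height, width_A_mm=width, width_B_mm=width,
                    seed=seed, **kw)
    rng = np.random.default_rng(seed)
    _, _, pts = curve_points(p, width, rng, n_theta=1024)
    return p, normalize_points(pts, 0.05, apex_hint=np.array([0.0, 1.0]))


class TestFruit:
    def test_two_ellipses(self):
        c = ellipse_contour(2.0, 1.0)
        fv = fruit_features(c, c)
        d = fv.as_dict()
        assert len(fv.values) == 24
        assert fv.names == FRUIT_FEATURE_NAMES
        assert d["shape_index_A"] == pytest.approx(2.0, rel=0.01)
        assert d["circularity_A"] == pytest.approx(0.841, abs=0.01)
        assert d["nipple_index_A"] == 0.0 and d["nipple_index_B"] == 0.0
        assert d["transversal_asymmetry_A"] < 0.01

    def test_nipple_detected_in_both_positions(self):
        p = ShapeParams(organ="fruit", height_mm=20, width_A_mm=14, width_B_mm=13.5,
                        nipple_amplitude=0.05)
        rng = np.random.default_rng(1)
        contours = {}
        for pos, w in (("A", 14.0), ("B", 13.5)):
            _, _, pts = curve_points(p, w, rng, n_theta=1024)
            contours[pos] = normalize_points(pts, 0.05, apex_hint=np.array([0.0, 1.0]))
        d = fruit_features(contours["A"], contours["B"]).as_dict()
        assert d["nipple_index_A"] == 1.0 and d["nipple_index_B"] == 1.0


class TestNippleDetection:
    def test_pure_ellipse_has_none(self):
        assert detect_nipple(ellipse_contour(2.0, 1.0)) == (0, 0.0)

    def test_amplitude_below_floor_ignored(self):
        _, c = fruit_contour(nipple_amplitude=0.005)
        idx, size = detect_nipple(c)
        assert idx == 0 and size == 0.0

    def test_size_tracks_generator_bump_area(self):
        p = ShapeParams(organ="fruit", height_mm=20, width_A_mm=14, width_B_mm=14,
                        nipple_amplitude=0.05)
        sil, truth = generate_shape(p)
        from oliveshape.geometry import contour_from_silhouette

        idx, size = detect_nipple(contour_from_silhouette(sil))
        assert idx == 1
        assert size == pytest.approx(truth["bump_area_mm2"], rel=0.25)

    def test_detection_monotone_in_amplitude(self):
        amplitudes = [0.0, 0.01, 0.02, 0.05, 0.10]
        recall = []
        for amp in amplitudes:
            hits = 0
            n_seeds = 40
            for seed in range(n_seeds):
                rng = np.random.default_rng(seed)
                p = ShapeParams(organ="fruit",
                                height_mm=float(rng.uniform(16, 24)),
                                width_A_mm=float(rng.uniform(12, 16)),
                                width_B_mm=14.0,
                                taper=float(rng.uniform(0, 0.1)),
                                nipple_amplitude=amp, noise_amp=0.005)
                _, _, pts = curve_points(p, p.width_A_mm, rng, n_theta=1024)
                c = normalize_points(pts, 0.05, apex_hint=np.array([0.0, 1.0]))
                hits += detect_nipple(c)[0]
            recall.append(hits / n_seeds)
        assert all(b >= a - 0.05 for a, b in zip(recall, recall[1:]))
        assert recall[0] <= 0.1 and recall[-1] >= 0.9


class TestLeaf:
    def test_circle_blade(self):
        p = ShapeParams(organ="leaf", height_mm=30, width_A_mm=30)
        sil, _ = generate_leaf(p, mm_per_px=0.1)
        d = leaf_features_from_silhouette(sil.validate()).as_dict()
        assert d["circularity"] == pytest.approx(1.0, abs=0.02)
        assert d["convexity"] == pytest.approx(1.0, abs=0.01)
        assert d["petiole_length"] == 0.0

    def test_lanceolate_shape_index(self):
        p = ShapeParams(organ="leaf", height_mm=60, width_A_mm=12, taper=0.1,
                        apex_sharpness=1.5)
        sil, truth = generate_leaf(p, mm_per_px=0.1)
        d = leaf_features_from_silhouette(sil.validate()).as_dict()
        assert d["shape_index"] == pytest.approx(truth["shape_index"], rel=0.03)

    def test_petiole_recovery(self):
        p = ShapeParams(organ="leaf", height_mm=55, width_A_mm=12, taper=0.12,
                        apex_sharpness=1.6, petiole_length_mm=10, petiole_width_mm=1.0)
        sil, _ = generate_leaf(p)
        d = leaf_features_from_silhouette(sil.validate()).as_dict()
        assert d["petiole_length"] == pytest.approx(10.0, rel=0.10)
        assert d["petiole_thickness_upper"] == pytest.approx(1.0, rel=0.15)
        assert d["petiole_thickness_lower"] == pytest.approx(1.0, rel=0.15)
        assert len(d) == 16

    def test_split_partitions_foreground(self):
        p = ShapeParams(organ="leaf", height_mm=55, width_A_mm=12, taper=0.12,
                        petiole_length_mm=8, petiole_width_mm=1.2)
        sil, _ = generate_leaf(p)
        split = split_petiole(sil)
        assert split.petiole is not None
        union = split.blade.mask | split.petiole.mask
        assert np.array_equal(union, sil.mask)
        assert not (split.blade.mask & split.petiole.mask).any()

    def test_ellipse_only_has_no_petiole(self):
        p = ShapeParams(organ="leaf", height_mm=40, width_A_mm=15)
        sil, _ = generate_leaf(p)
        split = split_petiole(sil)
        assert split.petiole is None
        assert np.array_equal(split.blade.mask, sil.mask)


class TestEndocarp:
    def test_identical_ellipses(self):
        c = ellipse_contour(1.5, 0.8)
        fv = endocarp_features(c, c, extended=True)
        d = fv.as_dict()
        assert fv.names == ENDOCARP_EXTENDED_NAMES and len(fv.values) == 25
        assert d["apex_curve_area_A"] == pytest.approx(0.0, abs=0.01)
        assert d["mucro_index"] == 0.0
        assert d["width_ratio_AB"] == pytest.approx(1.0, rel=0.01)

    def test_default_length_is_22(self):
        c = ellipse_contour(1.5, 0.8)
        fv = endocarp_features(c, c)
        assert fv.names == ENDOCARP_FEATURE_NAMES and len(fv.values) == 22

    def test_mucro_bump_detected(self):
        p = ShapeParams(organ="endocarp", height_mm=14, width_A_mm=7, width_B_mm=6.8,
                        taper=0.1, apex_sharpness=1.3, mucro_amplitude=0.06)
        rng = np.random.default_rng(0)
        cs = []
        for w in (7.0, 6.8):
            _, _, pts = curve_points(p, w, rng, n_theta=1024)
            cs.append(normalize_points(pts, 0.05, apex_hint=np.array([0.0, 1.0])))
        d = endocarp_features(cs[0], cs[1], extended=True).as_dict()
        assert d["mucro_index"] == 1.0


class TestScaleInvariance:
    def test_unitless_descriptors_scale_free(self):
        p, c1 = fruit_contour()
        c2 = normalize_points(c1.points * 2.0, 0.05)
        d1 = fruit_features(c1, c1).as_dict()
        d2 = fruit_features(c2, c2).as_dict()
        for name in ("shape_index_A", "circularity_A", "transversal_asymmetry_A",
                     "apex_pointedness_A", "nipple_index_A"):
            assert d2[name] == pytest.approx(d1[name], rel=0.01, abs=1e-9)


class TestFeatureTable:
    def _fruit_samples(self, n=10):
        out = []
        for i in range(n):
            _, c = fruit_contour(height=18 + i * 0.5, seed=i)
            out.append(
                OrganSample(f"s{i:02d}", "alpha" if i % 2 else "beta", 2016, "fruit",
                            contours={"A": c, "B": c})
            )
        return out

    def test_table_shape_and_order(self):
        table = build_feature_table(self._fruit_samples())
        assert table.df.shape == (10, 4 + 24)
        assert list(table.df.columns[:4]) == ["sample_id", "cultivar", "year", "organ"]
        # deterministic (cultivar, sample_id) ordering
        assert table.df["cultivar"].is_monotonic_increasing

    def test_duplicate_sample_id_rejected(self):
        samples = self._fruit_samples(3)
        samples[2].sample_id = samples[0].sample_id
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(samples)

    def test_csv_round_trip(self, tmp_path):
        table = build_feature_table(self._fruit_samples(4))
        path = tmp_path / "fruit.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        pd.testing.assert_frame_equal(back.df, table.df)
        assert back.organ == "fruit"

    def test_failed_sample_skipped_not_imputed(self, caplog):
        samples = self._fruit_samples(3)
        del samples[1].contours["B"]  # missing position -> extraction fails
        with caplog.at_level("WARNING"):
            table = build_feature_table(samples)
        assert len(table.df) == 2
        assert "skipping" in caplog.text
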