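import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from fstriage.features import (
    FEATURE_NAMES,
    FeatureConfig,
    Heatmap,
    binarize,
    extract_lesions,
    feature_vector,
    marginal_features,
    texture_features,
)


def disk_mask(shape=(300, 300), center=(150, 150), radius=100):
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius)
    m[rr, cc] = True
    return m


class TestBinarize:
    def test_constant_map_thresholds(self):
        hm = Heatmap(np.full((16, 16), 0.7), mpp=2.0)
        assert binarize(hm, 0.5).all()
        assert not binarize(hm, 0.71).any()

    def test_threshold_domain(self):
        hm = Heatmap(np.zeros((4, 4)), mpp=2.0)
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                binarize(hm, bad)

    def test_matches_naive_comparison_loop(self):
        rng = np.random.default_rng(0)
        probs = rng.random((20, 20))
        got = binarize(Heatmap(probs, mpp=2.0), 0.4)
        for i in range(20):
            for j in range(20):
                assert got[i, j] == (probs[i, j] >= 0.4)


class TestExtractLesions:
    def test_disk_closed_forms(self):
        # r = 100 px at 2 µm/px: area πr² = 0.12566 mm², perimeter 2πr =
        # 1.2566 mm, diameter 2r = 0.4 mm
        lesions = extract_lesions(disk_mask(), mpp=2.0)
        assert len(lesions) == 1
        (l,) = lesions.lesions
        assert l.area_mm2 == pytest.approx(np.pi * 0.2**2, rel=0.01)
        assert l.perimeter_mm == pytest.approx(2 * np.pi * 0.2, rel=0.03)
        assert l.diameter_mm == pytest.approx(0.4, rel=0.02)
        assert l.eccentricity < 0.1
        assert l.solidity > 0.98

    def test_rectangle_exact(self):
        m = np.zeros((600, 700), dtype=bool)
        m[50:350, 100:600] = True  # 300 x 500 px
        (l,) = extract_lesions(m, mpp=2.0).lesions
        assert l.area_mm2 == pytest.approx(0.6, abs=1e-12)
        assert l.extent == pytest.approx(1.0)
        assert l.solidity == pytest.approx(1.0)

    def test_empty_mask(self):
        assert len(extract_lesions(np.zeros((50, 50), bool), mpp=2.0)) == 0

    def test_min_area_floor_drops_specks(self):
        m = np.zeros((100, 100), dtype=bool)
        m[10, 10] = True  # single pixel, 4 µm² << 0.01 mm²
        m[20:80, 20:80] = True  # 3600 px = 0.0144 mm², above the floor
        lesions = extract_lesions(m, mpp=2.0, min_area_mm2=0.01)
        assert len(lesions) == 1

    def test_scale_consistency(self):
        m = disk_mask(radius=60)
        a = extract_lesions(m, mpp=2.0).lesions[0]
        b = extract_lesions(m, mpp=4.0).lesions[0]
        assert b.area_mm2 == pytest.approx(4 * a.area_mm2)
        assert b.perimeter_mm == pytest.approx(2 * a.perimeter_mm)
        assert b.diameter_mm == pytest.approx(2 * a.diameter_mm)

    def test_rotation_invariance(self):
        m = np.zeros((400, 400), dtype=bool)
        m[100:200, 150:350] = True
        base = extract_lesions(m, mpp=2.0).lesions[0]
        for k in (1, 2, 3):
            rot = extract_lesions(np.rot90(m, k), mpp=2.0).lesions[0]
            assert rot.area_mm2 == pytest.approx(base.area_mm2)
            assert rot.perimeter_mm == pytest.approx(base.perimeter_mm)

    def test_contour_perimeter_option(self):
        lesions = extract_lesions(disk_mask(), mpp=2.0, perimeter_method="contour")
        assert lesions.lesions[0].perimeter_mm == pytest.approx(2 * np.pi * 0.2, rel=0.06)
        with pytest.raises(ValueError):
            extract_lesions(disk_mask(), mpp=2.0, perimeter_method="nope")


class TestTextureFeatures:
    def test_constant_heatmap_degenerate_cooccurrence(self):
        hm = Heatmap(np.full((64, 64), 0.6), mpp=2.0)
        out = texture_features(hm, np.ones((64, 64), bool))
        assert out["glcm_contrast"] == 0.0
        assert out["glcm_dissimilarity"] == 0.0
        assert out["glcm_homogeneity"] == 1.0
        assert out["intensity_entropy"] == 0.0
        assert out["glcm_correlation"] == 0.0  # degenerate by convention

    def test_checkerboard_contrast_matches_brute_force(self):
        # levels {0, 31}: horizontally adjacent pixels always differ by 31
        probs = (np.indices((32, 32)).sum(axis=0) % 2) * (31 / 32)
        hm = Heatmap(probs, mpp=2.0)
        out = texture_features(hm, np.ones((32, 32), bool), angles=(0.0,))
        q = (probs * 32).astype(int)
        pairs = [
            (q[i, j], q[i, j + 1]) for i in range(32) for j in range(31)
        ]  # brute-force symmetric co-occurrence at distance 1, horizontal
        count = {}
        for a, b in pairs:
            count[(a, b)] = count.get((a, b), 0) + 1
            count[(b, a)] = count.get((b, a), 0) + 1
        total = sum(count.values())
        contrast = sum(n * (a - b) ** 2 for (a, b), n in count.items()) / total
        assert out["glcm_contrast"] == pytest.approx(contrast)
        assert out["glcm_contrast"] == pytest.approx(31**2)

    def test_variance_is_squared_sd(self):
        rng = np.random.default_rng(2)
        hm = Heatmap(rng.random((40, 40)), mpp=2.0)
        out = texture_features(hm, np.ones((40, 40), bool))
        assert out["intensity_var"] == pytest.approx(out["intensity_std"] ** 2)
        assert out["gradient_var"] == pytest.approx(out["gradient_std"] ** 2)

    def test_single_pixel_tissue_is_defined(self):
        tissue = np.zeros((16, 16), bool)
        tissue[8, 8] = True
        hm = Heatmap(np.random.default_rng(0).random((16, 16)), mpp=2.0)
        out = texture_features(hm, tissue)
        assert out["intensity_std"] == 0.0
        assert all(np.isfinite(v) for v in out.values())

    def test_empty_tissue_rejected(self):
        hm = Heatmap(np.zeros((8, 8)), mpp=2.0)
        with pytest.raises(ValueError):
            texture_features(hm, np.zeros((8, 8), bool))


class TestMarginalFeatures:
    def test_flat_map_convention(self):
        assert marginal_features(Heatmap(np.full((32, 32), 0.3), mpp=2.0)) == (0, 0.0)

    def test_disk_boundary_edge_count_near_circumference(self):
        hm = Heatmap(disk_mask().astype(float), mpp=2.0)
        n, mean_grad = marginal_features(hm)
        assert n == pytest.approx(2 * np.pi * 100, rel=0.20)
        assert mean_grad > 0
        assert n <= hm.probs.size


class TestFeatureVector:
    def test_header_is_frozen(self):
        assert len(FEATURE_NAMES) == 69
        assert FEATURE_NAMES[0] == "lesion_area_mm2_max"
        assert FEATURE_NAMES[-1] == "lesion_pixel_count"
        assert len(set(FEATURE_NAMES)) == len(FEATURE_NAMES)

    def test_empty_heatmap_defaults(self):
        hm = Heatmap(np.zeros((600, 600)), mpp=32.0)
        vec = feature_vector(hm)
        assert list(vec.index) == list(FEATURE_NAMES)
        assert vec["region_count"] == 0
        assert vec["lesion_area_mm2_max"] == 0.0
        assert not vec.isna().any()

    def test_identical_heatmaps_identical_vectors(self):
        rng = np.random.default_rng(3)
        probs = rng.random((256, 256))
        a = feature_vector(Heatmap(probs, mpp=32.0))
        b = feature_vector(Heatmap(probs.copy(), mpp=32.0))
        assert (a == b).all()

    def test_max_aggregate_matches_recomputed_lesions(self, ptc_slide):
        from fstriage.pipeline import heatmap_from_oracle
        from fstriage.segmentation import OracleSegmenter

        hm = heatmap_from_oracle(ptc_slide, OracleSegmenter(ptc_slide, 0.05, 0.0, seed=2))
        cfg = FeatureConfig()
        vec = feature_vector(hm, config=cfg)
        lesions = extract_lesions(
            binarize(hm, cfg.threshold), hm.mpp, cfg.min_lesion_area_mm2
        )
        assert vec["lesion_area_mm2_max"] == pytest.approx(
            lesions.values("area_mm2").max()
        )
        assert vec["region_count"] == len(lesions)
        assert vec["lesion_perimeter_mm_max"] == pytest.approx(
            lesions.values("perimeter_mm").max()
        )

    def test_few_lesions_zero_higher_moments(self):
        hm = Heatmap(disk_mask((300, 300)).astype(float), mpp=32.0)
        vec = feature_vector(hm)
        assert vec["lesion_area_mm2_skew"] == 0.0
        assert vec["lesion_area_mm2_kurt"] == 0.0
        assert vec["lesion_area_mm2_std"] == 0.0
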