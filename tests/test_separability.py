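"""Vegetation indices, panel calibration, M-statistic and ANOVA/LSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavweed.alignment import MultibandStack
from uavweed.separability import (
    ClassSample,
    PanelCalibration,
    anova_lsd,
    calibrate_reflectance,
    compute_index,
    m_statistic,
    sample_class_pixels,
    separability_table,
)
from uavweed.synthetic import DEFAULT_CLASS_BAND_STATS, generate_class_samples


def _stack_from_bands(B, G, R, NIR, **kw):
    """Small six-band stack with the given B/G/R/NIR planes."""
    B, G, R, NIR = (np.asarray(a, dtype=float) for a in (B, G, R, NIR))
    px = np.stack([B, G, R, R, (R + NIR) / 2, NIR], axis=-1)
    return MultibandStack(px, **kw)


def _sample(values, label="crop", index_name="NDVI"):
    return ClassSample(label=label, index_name=index_name,
                       values=np.asarray(values, dtype=float))


class TestCalibration:
    def test_panel_maps_to_panel_reflectance(self, small_scene):
        cal = PanelCalibration(panel_mask=small_scene.masks["panel"])
        refl = calibrate_reflectance(small_scene.stack, cal)
        for b in range(refl.n_bands):
            mean = np.nanmean(refl.band(b)[cal.panel_mask])
            assert mean == pytest.approx(0.99, abs=1e-9)

    def test_scale_invariance(self, small_scene):
        cal = PanelCalibration(panel_mask=small_scene.masks["panel"])
        once = calibrate_reflectance(small_scene.stack, cal)
        doubled = MultibandStack(small_scene.stack.pixels * 2.0,
                                 band_centers=small_scene.stack.band_centers,
                                 bit_depth=small_scene.stack.bit_depth,
                                 master_index=small_scene.stack.master_index)
        twice = calibrate_reflectance(doubled, cal)
        np.testing.assert_allclose(twice.pixels, once.pixels, rtol=1e-12)

    def test_recovers_simulated_gains(self, small_scene):
        # panel DN were drawn at mean 950 for reflectance 0.99: the implied
        # per-band gain is 0.99/950, and calibration must recover it to 1%
        cal = PanelCalibration(panel_mask=small_scene.masks["panel"])
        refl = calibrate_reflectance(small_scene.stack, cal)
        soil = small_scene.masks["bare_soil"]
        for b in range(refl.n_bands):
            implied = np.nanmean(refl.band(b)[soil]) / np.nanmean(
                small_scene.stack.band(b)[soil].astype(float))
            assert implied == pytest.approx(0.99 / 950.0, rel=0.01)

    def test_small_panel_rejected(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[0, :10] = True
        with pytest.raises(ValueError):
            PanelCalibration(panel_mask=mask)


class TestComputeIndex:
    def test_pixel_arithmetic(self):
        one = np.ones((2, 2))
        # NIR = R -> NDVI 0; NIR = 3R -> NDVI 0.5; grey -> ExG = NGRDI = 0
        st_eq = _stack_from_bands(one, one, one, one)
        assert np.allclose(compute_index(st_eq, "NDVI"), 0)
        assert np.allclose(compute_index(st_eq, "NGRDI"), 0)
        assert np.allclose(compute_index(st_eq, "ExG"), 0)
        st3 = _stack_from_bands(one, one, one * 2, one * 6)
        assert np.allclose(compute_index(st3, "NDVI"), 0.5)

    def test_zero_denominator_flagged_invalid(self):
        z = np.zeros((2, 2))
        st0 = _stack_from_bands(z, z, z, z)
        assert np.isnan(compute_index(st0, "NDVI")).all()

    def test_missing_band_rejected(self):
        rgb = MultibandStack(np.ones((4, 4, 3)), band_centers=(450., 530., 670.),
                             master_index=2)
        with pytest.raises(KeyError):
            compute_index(rgb, "NDVI")
        assert np.allclose(compute_index(rgb, "ExG"), 0)  # grey pixels

    def test_unknown_index_rejected(self, small_scene):
        with pytest.raises(KeyError):
            compute_index(small_scene.stack, "SAVI")

    @given(gain=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_global_rescaling(self, gain):
        rng = np.random.default_rng(3)
        px = rng.uniform(10, 200, size=(8, 8, 6))
        stack = MultibandStack(px)
        scaled = MultibandStack(px * gain)
        for name in ("NDVI", "NGRDI", "ExG"):
            np.testing.assert_allclose(compute_index(scaled, name),
                                       compute_index(stack, name), rtol=1e-9)

    def test_ranges(self, small_scene):
        ndvi = compute_index(small_scene.stack, "NDVI")
        ngrdi = compute_index(small_scene.stack, "NGRDI")
        exg = compute_index(small_scene.stack, "ExG")
        for img, lo, hi in ((ndvi, -1, 1), (ngrdi, -1, 1), (exg, -2, 2)):
            v = img[np.isfinite(img)]
            assert v.min() >= lo and v.max() <= hi


class TestSampleClassPixels:
    def test_constant_image(self):
        img = np.full((40, 40), 0.7)
        rois = [np.array([(5, 5), (15, 5), (15, 15), (5, 15)], dtype=float)]
        s = sample_class_pixels(img, rois, "crop")
        assert np.all(s.values == 0.7)
        assert s.n_rois == 1

    def test_disjoint_rois_pool_pixel_counts(self):
        img = np.arange(1600, dtype=float).reshape(40, 40)
        sq = lambda x0, y0, n: np.array(
            [(x0, y0), (x0 + n, y0), (x0 + n, y0 + n), (x0, y0 + n)], float)
        s1 = sample_class_pixels(img, [sq(2, 2, 10)], "crop")
        s2 = sample_class_pixels(img, [sq(25, 25, 6)], "crop")
        both = sample_class_pixels(img, [sq(2, 2, 10), sq(25, 25, 6)], "crop")
        assert both.values.size == s1.values.size + s2.values.size
        assert both.n_rois == 2

    def test_mask_input_and_invalid_pixels_excluded(self):
        img = np.full((10, 10), 0.5)
        img[0, :] = np.nan
        mask = np.ones((10, 10), dtype=bool)
        s = sample_class_pixels(img, mask, "weed")
        assert s.values.size == 90

    def test_empty_roi_rejected(self):
        img = np.full((10, 10), np.nan)
        with pytest.raises(ValueError):
            sample_class_pixels(img, np.ones((10, 10), dtype=bool), "crop")
        with pytest.raises(ValueError):
            sample_class_pixels(np.ones((10, 10)), [], "crop")


class TestMStatistic:
    def test_identical_samples_zero(self):
        s = _sample([0.1, 0.2, 0.3])
        assert m_statistic(s, s) == 0.0

    def test_printed_rounded_row_evaluates_to_9_25(self):
        """Means 0.58 / -0.16 with SDs 0.07 / 0.01 give (0.58+0.16)/0.08 = 9.25.

        Three-point samples m-s, m, m+s have mean m and sample SD exactly s,
        so the statistic is evaluated through the full sample path.
        """
        veg = _sample([0.51, 0.58, 0.65], "vegetation")
        soil = _sample([-0.17, -0.16, -0.15], "bare_soil")
        assert m_statistic(veg, soil) == pytest.approx(9.25, abs=1e-9)

    @given(mu=st.floats(-1, 1), shift=st.floats(-2, 2))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, mu, shift):
        rng = np.random.default_rng(5)
        a = _sample(rng.normal(mu, 0.3, 50))
        b = _sample(rng.normal(mu + shift, 0.5, 50), "weed")
        assert m_statistic(a, b) == pytest.approx(-m_statistic(b, a), rel=1e-12)

    def test_degenerate_distributions_rejected(self):
        a = _sample([1.0, 1.0, 1.0])
        b = _sample([2.0, 2.0], "weed")
        with pytest.raises(ZeroDivisionError):
            m_statistic(a, b)

    def test_converges_to_analytic_value(self):
        """On large Gaussian samples M approaches (mu1-mu2)/(sigma1+sigma2)."""
        rng = np.random.default_rng(12)
        n = 100_000
        mu1, mu2, s1, s2 = 0.58, -0.16, 0.07, 0.01
        a = _sample(rng.normal(mu1, s1, n), "vegetation")
        b = _sample(rng.normal(mu2, s2, n), "bare_soil")
        target = (mu1 - mu2) / (s1 + s2)
        # delta-method SE of the estimator (mean and SD sampling error)
        se = np.sqrt((s1 ** 2 + s2 ** 2) / n
                     + target ** 2 * (s1 ** 2 + s2 ** 2) / (2 * n)) / (s1 + s2)
        assert m_statistic(a, b) == pytest.approx(target, abs=3 * se)


class TestAnovaLsd:
    def test_extreme_separation_distinct(self):
        rng = np.random.default_rng(1)
        a = _sample(rng.normal(0, 1, 30))
        b = _sample(rng.normal(10, 1, 30), "weed")
        res = anova_lsd([a, b], alpha=0.01)
        assert res.p_value < 0.01
        assert res.distinct("crop", "weed")

    def test_identical_pair_shares_letter_despite_outlier_group(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 40)
        a = _sample(base, "crop")
        b = _sample(base + rng.normal(0, 1e-3, 40), "weed")
        c = _sample(rng.normal(25, 1, 40), "bare_soil")
        res = anova_lsd([a, b, c], alpha=0.01)
        assert not res.distinct("crop", "weed")
        assert res.distinct("crop", "bare_soil")
        assert res.distinct("weed", "bare_soil")

    def test_null_groups_share_letter_usually(self):
        """Type-I control: same-distribution groups share a letter >=95% of
        seeded trials at alpha = 0.01."""
        shared = 0
        trials = 200
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            a = _sample(rng.normal(0, 1, 50))
            b = _sample(rng.normal(0, 1, 50), "weed")
            if not anova_lsd([a, b], alpha=0.01).distinct("crop", "weed"):
                shared += 1
        assert shared / trials >= 0.95

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd([_sample([1.0]), _sample([1.0, 2.0], "weed")])
        with pytest.raises(ValueError):
            anova_lsd([_sample([1.0, 2.0])])


@pytest.fixture(scope="module")
def table(recovery_scene):
    rois = {lab: recovery_scene.masks[lab]
            for lab in ("bare_soil", "crop", "weed")}
    return separability_table({("multispectral", 30): recovery_scene.stack},
                              {("multispectral", 30): rois})


class TestSeparabilityTable:
    def test_row_structure(self, table):
        assert set(table["index"]) == {"NDVI", "NGRDI", "ExG"}
        assert set(zip(table["class1"], table["class2"])) == {
            ("vegetation", "bare_soil"), ("crop", "weed")}
        assert len(table) == 6
        for _, r in table.iterrows():
            assert r["min1"] <= r["mean1"] <= r["max1"]
            assert r["min2"] <= r["mean2"] <= r["max2"]

    def test_ndvi_separates_vegetation_from_soil_best(self, table):
        vs = table[table["class1"] == "vegetation"].set_index("index")["M"]
        assert vs["NDVI"] > vs["NGRDI"] and vs["NDVI"] > vs["ExG"]

    def test_crop_weed_harder_than_vegetation_soil(self, table):
        for idx in ("NDVI", "NGRDI", "ExG"):
            sub = table[table["index"] == idx].set_index("class1")["M"]
            assert abs(sub["crop"]) < abs(sub["vegetation"])

    def test_ndvi_rows_absent_without_nir(self, recovery_scene):
        scene = recovery_scene
        rgb = MultibandStack(scene.stack.pixels[:, :, :3],
                             band_centers=(450., 530., 670.), master_index=2)
        rois = {lab: scene.masks[lab] for lab in ("bare_soil", "crop", "weed")}
        t = separability_table({("rgb", 30): rgb}, {("rgb", 30): rois})
        assert "NDVI" not in set(t["index"])
        assert set(t["index"]) == {"NGRDI", "ExG"}

    def test_identical_classes_score_zero(self):
        rng = np.random.default_rng(9)
        px = rng.uniform(50, 200, size=(60, 60, 6))
        stack = MultibandStack(px)
        half = np.zeros((60, 60), dtype=bool)
        half[:, :30] = True
        rois = {"bare_soil": ~half, "crop": half, "weed": half.copy()}
        t = separability_table({("c", 30): stack}, {("c", 30): rois})
        cw = t[t["class1"] == "crop"]
        assert (cw["M"].abs() < 0.05).all()
        assert not cw["lsd_distinct"].any()
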