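"""Feature-extraction correctness against brute-force oracles and closed forms."""

import numpy as np
import pytest

from conftest import random_roi
from crclm_fm.phantoms import generate_patient
from crclm_fm.radiomics import (
    DISCRETIZED_FEATURES,
    FEATURE_NAMES,
    QuantizedROI,
    extract_patient_features,
    extract_slice_features,
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    quantize,
)
import oracles

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def roi_from_levels(levels, mask=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    return QuantizedROI(levels=levels, n_levels=int(levels.max()), mask=mask)


# ---------------------------------------------------------------------------
# quantize
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_constant_roi_maps_to_single_level(self):
        roi = quantize(np.full((3, 3), 5.0), np.ones((3, 3), bool), n_bins=8)
        assert roi.n_levels == 1
        assert (roi.levels[roi.mask] == 1).all()

    def test_two_point_range(self):
        img = np.array([[0.0, 10.0]])
        roi = quantize(img, np.ones((1, 2), bool), n_bins=2)
        assert roi.levels.tolist() == [[1, 2]]

    def test_counts_match_numpy_histogram(self, rng):
        img = rng.uniform(0, 100, size=(12, 12))
        mask = rng.uniform(size=(12, 12)) < 0.7
        mask[0, 0] = True
        roi = quantize(img, mask, n_bins=32)
        ours = np.bincount(roi.levels[mask], minlength=33)[1:]
        expected, _ = np.histogram(img[mask], bins=32,
                                   range=(img[mask].min(), img[mask].max()))
        assert (ours == expected).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.ones((3, 3)), np.zeros((3, 3), bool))

    def test_out_of_mask_pixels_ignored(self):
        img = np.array([[1.0, 1e9], [2.0, 3.0]])
        mask = np.array([[True, False], [True, True]])
        roi = quantize(img, mask, n_bins=4)
        assert roi.levels[0, 1] == 0
        assert roi.levels[mask].max() <= 4


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_roi_degenerates(self):
        img = np.full((4, 4), 7.0)
        feats = extract_slice_features(img, np.ones((4, 4), bool))
        assert feats["entropy"] == 0.0
        assert feats["uniformity"] == 1.0
        assert feats["interquartile_range"] == 0.0
        assert feats["mean_absolute_deviation"] == 0.0
        assert feats["robust_mean_absolute_deviation"] == 0.0

    def test_hand_histogram(self):
        # levels histogram p = (3/4, 1/4)
        roi = roi_from_levels([[1, 1], [1, 2]])
        feats = first_order_features(roi, np.array([1.0, 1.0, 1.0, 2.0]))
        assert feats["entropy"] == pytest.approx(0.8112781244591328, abs=1e-12)
        assert feats["uniformity"] == pytest.approx(0.625, abs=1e-12)

    def test_entropy_bounded_by_log_levels(self, rng):
        for _ in range(20):
            levels, mask = random_roi(rng, n_levels=4)
            roi = roi_from_levels(levels, mask)
            feats = first_order_features(roi, rng.uniform(size=int(mask.sum())))
            assert 0.0 <= feats["entropy"] <= np.log2(roi.n_levels) + 1e-12

    def test_dispersion_against_direct_formulas(self, rng):
        raw = rng.normal(size=200)
        roi = quantize(raw.reshape(20, 10), np.ones((20, 10), bool), 16)
        feats = first_order_features(roi, raw)
        q25, q75 = np.percentile(raw, [25, 75])
        assert feats["interquartile_range"] == pytest.approx(q75 - q25)
        assert feats["mean_absolute_deviation"] == pytest.approx(
            np.abs(raw - raw.mean()).mean()
        )
        p10, p90 = np.percentile(raw, [10, 90])
        sub = raw[(raw >= p10) & (raw <= p90)]
        assert feats["robust_mean_absolute_deviation"] == pytest.approx(
            np.abs(sub - sub.mean()).mean()
        )


# ---------------------------------------------------------------------------
# texture families vs oracles
# ---------------------------------------------------------------------------

class TestTextureOracles:
    def test_glcm_hand_example(self):
        roi = roi_from_levels([[1, 1], [1, 2]])
        feats = glcm_features(roi, angles=((0, 1),))
        assert feats["joint_entropy"] == pytest.approx(1.5, abs=1e-12)
        assert feats["autocorrelation"] == pytest.approx(1.5, abs=1e-12)
        assert feats["joint_average"] == pytest.approx(1.25, abs=1e-12)
        assert feats["sum_average"] == pytest.approx(2.5, abs=1e-12)
        assert feats["sum_entropy"] == pytest.approx(1.0, abs=1e-12)

    def test_glcm_constant_roi(self):
        roi = roi_from_levels(np.full((3, 3), 1))
        feats = glcm_features(roi)
        assert feats["joint_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert feats["autocorrelation"] == pytest.approx(1.0, abs=1e-12)

    def test_gldm_single_level_mass(self):
        # all mass at level g: HGLE = g^2, LGLE = 1/g^2
        levels = np.full((3, 3), 3)
        roi = QuantizedROI(levels=levels, n_levels=3, mask=np.ones((3, 3), bool))
        feats = gldm_features(roi)
        assert feats["high_gray_level_emphasis"] == pytest.approx(9.0)
        assert feats["low_gray_level_emphasis"] == pytest.approx(1 / 9.0)

    def test_gldm_single_pixel(self):
        levels = np.zeros((3, 3), dtype=np.int64)
        levels[1, 1] = 2
        roi = QuantizedROI(levels=levels, n_levels=2, mask=levels > 0)
        feats = gldm_features(roi)
        # one isolated pixel: dependence group of size 1, matrix total 1
        assert feats["dependence_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert feats["high_gray_level_emphasis"] == pytest.approx(4.0)

    def test_glrlm_single_run(self):
        roi = roi_from_levels([[3, 3, 3, 3]])
        feats = glrlm_features(roi, angles=((0, 1),))
        assert feats["high_gray_level_run_emphasis"] == pytest.approx(9.0)
        assert feats["long_run_low_gray_level_emphasis"] == pytest.approx(16 / 9)

    def test_glrlm_alternation_is_four_unit_runs(self):
        roi = roi_from_levels([[1, 2, 1, 2]])
        feats = glrlm_features(roi, angles=((0, 1),))
        # four runs of length 1, levels 1,2,1,2
        assert feats["high_gray_level_run_emphasis"] == pytest.approx((1 + 4 + 1 + 4) / 4)
        assert feats["short_run_low_gray_level_emphasis"] == pytest.approx(
            (1 + 0.25 + 1 + 0.25) / 4
        )

    def test_glszm_single_zone(self):
        roi = roi_from_levels(np.full((2, 3), 2))
        feats = glszm_features(roi)
        assert feats["high_gray_level_zone_emphasis"] == pytest.approx(4.0)
        assert feats["small_area_low_gray_level_emphasis"] == pytest.approx(
            1 / (36 * 4)
        )

    def test_glszm_checkerboard_unit_zones(self):
        # 2x2 checkerboard: diagonal pixels are 8-connected, so levels 1 and 2
        # each form ONE zone of size 2
        roi = roi_from_levels([[1, 2], [2, 1]])
        feats = glszm_features(roi)
        assert feats["high_gray_level_zone_emphasis"] == pytest.approx((1 + 4) / 2)

    @pytest.mark.parametrize("trial", range(25))
    def test_all_families_match_bruteforce_on_random_rois(self, trial):
        rng = np.random.default_rng(5000 + trial)
        shape = (int(rng.integers(2, 9)), int(rng.integers(2, 9)))
        levels, mask = random_roi(rng, shape=shape, n_levels=4)
        roi = roi_from_levels(levels, mask)

        got = glcm_features(roi, angles=DIRECTIONS)
        want = oracles.glcm_oracle(levels, DIRECTIONS)
        if want is None:
            assert all(np.isnan(v) for v in got.values())
        else:
            for k, v in want.items():
                assert got[k] == pytest.approx(v, abs=1e-9), k

        got = gldm_features(roi, alpha=0)
        for k, v in oracles.gldm_oracle(levels, alpha=0).items():
            assert got[k] == pytest.approx(v, abs=1e-9), k

        got = glrlm_features(roi, angles=DIRECTIONS)
        for k, v in oracles.glrlm_oracle(levels, DIRECTIONS).items():
            assert got[k] == pytest.approx(v, abs=1e-9), k

        got = glszm_features(roi)
        for k, v in oracles.glszm_oracle(levels).items():
            assert got[k] == pytest.approx(v, abs=1e-9), k


# ---------------------------------------------------------------------------
# per-slice / per-patient extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_affine_rescaling_leaves_discretized_features_unchanged(self, rng):
        img = rng.normal(100, 15, size=(16, 16))
        mask = np.ones((16, 16), bool)
        a = extract_slice_features(img, mask, n_bins=16)
        b = extract_slice_features(3.0 * img + 50.0, mask, n_bins=16)
        for name in DISCRETIZED_FEATURES:
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_single_slice_patient_table(self, small_config):
        patient = generate_patient(small_config, "healthy", patient_seed=5)
        table = extract_patient_features(patient)
        assert list(table.columns) == list(FEATURE_NAMES)
        assert len(table) == patient.n_slices
        assert table.notna().all().all()

    def test_extraction_is_deterministic(self, small_config):
        patient = generate_patient(small_config, "case", patient_seed=9)
        t1 = extract_patient_features(patient)
        t2 = extract_patient_features(patient)
        assert t1.equals(t2)
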