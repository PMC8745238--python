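"""Feature ranking/selection and class-distribution diagnostics."""

import numpy as np
import pandas as pd
import pytest

import oracles
from crclm_fm.phantoms import PhantomConfig, generate_cohort
from crclm_fm.radiomics import FEATURE_NAMES, extract_patient_features
from crclm_fm.selection import (
    class_distributions,
    information_gain,
    rank_features,
    select_features,
)


def make_cohort_table(patient_values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """One-slice-per-patient table with the given feature values; remaining
    canonical features filled with zeros."""
    rows = []
    for pid, feats in patient_values.items():
        row = {"patient_id": pid}
        row.update({name: 0.0 for name in FEATURE_NAMES})
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)


class TestInformationGain:
    def test_perfect_separation_is_one_bit(self):
        gain = information_gain([0, 0, 0, 1, 1, 1], list("AAABBB"))
        assert gain == pytest.approx(1.0)

    def test_constant_feature_has_zero_gain(self):
        assert information_gain([5, 5, 5, 5], list("AABB")) == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_split_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        values = rng.integers(0, 5, size=6).astype(float)
        labels = rng.choice(["healthy", "metastatic"], size=6)
        got = information_gain(values, labels)
        want = oracles.exhaustive_information_gain(values, labels)
        assert got == pytest.approx(want, abs=1e-12)

    def test_label_independent_feature_has_small_gain(self, rng):
        gains = []
        for _ in range(50):
            values = rng.normal(size=30)
            labels = np.array(["healthy"] * 21 + ["metastatic"] * 9)
            gains.append(information_gain(values, labels))
        # optimistic bias of the best split exists, but stays well below 1 bit
        assert np.mean(gains) < 0.5


class TestRanking:
    def test_scores_sorted_and_ties_lexicographic(self):
        table = make_cohort_table(
            {
                "p1": {"entropy": 0.0, "uniformity": 0.0},
                "p2": {"entropy": 0.0, "uniformity": 0.0},
                "p3": {"entropy": 1.0, "uniformity": 1.0},
                "p4": {"entropy": 1.0, "uniformity": 1.0},
            }
        )
        labels = pd.Series(
            ["healthy", "healthy", "metastatic", "metastatic"],
            index=["p1", "p2", "p3", "p4"],
        )
        ranking = rank_features(table, labels)
        gains = [g for _, _, g in ranking.entries]
        assert gains == sorted(gains, reverse=True)
        perfect = [n for n, _, g in ranking.entries if g == pytest.approx(1.0)]
        assert perfect == sorted(perfect)

    def test_row_permutation_invariance(self, rng):
        cfg = PhantomConfig(n_controls=3, n_cases=3, slices_per_patient=(3, 5),
                            image_shape=(32, 32), roi_radius_px=10, seed=2)
        patients, manifest = generate_cohort(cfg)
        frames = []
        for p in patients:
            t = extract_patient_features(p)
            t.insert(0, "patient_id", p.patient_id)
            frames.append(t)
        table = pd.concat(frames, ignore_index=True)
        labels = manifest.set_index("patient_id")["label"]
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert rank_features(table, labels) == rank_features(shuffled, labels)

    def test_single_class_rejected(self):
        table = make_cohort_table({"p1": {}, "p2": {}})
        labels = pd.Series(["healthy", "healthy"], index=["p1", "p2"])
        with pytest.raises(ValueError):
            rank_features(table, labels)


class TestSelect:
    @pytest.fixture
    def ranking(self):
        table = make_cohort_table(
            {
                f"p{i}": {name: (i % 2) * (j + 1) for j, name in enumerate(FEATURE_NAMES)}
                for i in range(6)
            }
        )
        labels = pd.Series(
            ["healthy", "metastatic"] * 3, index=[f"p{i}" for i in range(6)]
        )
        return rank_features(table, labels)

    def test_all_families_keeps_everything_with_positive_gain(self, ranking):
        kept = select_features(
            ranking, families_kept=("FIRST", "GLDM", "GLCM", "GLRLM", "GLSZM")
        )
        assert len(kept) == 22

    def test_family_restriction_excludes_other_families(self, ranking):
        from crclm_fm.radiomics import FAMILY_OF

        kept = select_features(ranking, families_kept=("FIRST", "GLDM", "GLSZM"))
        assert kept
        assert all(FAMILY_OF[name] in ("FIRST", "GLDM", "GLSZM") for name in kept)

    def test_threshold_above_max_gain_empties_selection(self, ranking):
        with pytest.warns(UserWarning):
            kept = select_features(ranking, gain_threshold=2.0)
        assert kept == []


class TestClassDistributions:
    def test_identical_classes_identical_histograms(self):
        vals = {f"p{i}": {"entropy": float(i % 3)} for i in range(6)}
        table = make_cohort_table(vals)
        labels = pd.Series(
            ["healthy", "metastatic"] * 3, index=[f"p{i}" for i in range(6)]
        )
        # classes see the same value multiset {0,1,2}
        dists = class_distributions(table, labels, "entropy")
        assert np.array_equal(dists["healthy"]["counts"], dists["metastatic"]["counts"])

    def test_disjoint_supports_do_not_overlap(self):
        vals = {f"h{i}": {"entropy": 0.0 + i * 0.01} for i in range(3)}
        vals |= {f"m{i}": {"entropy": 10.0 + i * 0.01} for i in range(3)}
        table = make_cohort_table(vals)
        labels = pd.Series(
            ["healthy"] * 3 + ["metastatic"] * 3,
            index=[f"h{i}" for i in range(3)] + [f"m{i}" for i in range(3)],
        )
        d = class_distributions(table, labels, "entropy")
        overlap = (d["healthy"]["counts"] > 0) & (d["metastatic"]["counts"] > 0)
        assert not overlap.any()

    def test_unknown_feature_rejected(self):
        table = make_cohort_table({"p1": {}, "p2": {}})
        labels = pd.Series(["healthy", "metastatic"], index=["p1", "p2"])
        with pytest.raises(ValueError):
            class_distributions(table, labels, "no_such_feature")

    def test_phantom_shift_direction_follows_generator_sd(self):
        """Case class has larger intensity SD, so the dispersion features'
        distributions must shift upward for the metastatic class."""
        cfg = PhantomConfig(n_controls=4, n_cases=4, slices_per_patient=(6, 8),
                            image_shape=(48, 48), roi_radius_px=15,
                            effect_size=2.0, seed=3)
        patients, manifest = generate_cohort(cfg)
        frames = []
        for p in patients:
            t = extract_patient_features(p)
            t.insert(0, "patient_id", p.patient_id)
            frames.append(t)
        table = pd.concat(frames, ignore_index=True)
        labels = manifest.set_index("patient_id")["label"]
        d = class_distributions(table, labels, "mean_absolute_deviation")
        centers = (d["healthy"]["bin_edges"][:-1] + d["healthy"]["bin_edges"][1:]) / 2

        def mean_of(cls):
            c = d[cls]["counts"]
            return (centers * c).sum() / c.sum()

        assert mean_of("metastatic") > mean_of("healthy")
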