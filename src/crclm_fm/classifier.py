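"""Scikit-learn style estimator wrapping the full formal-methods pipeline.

``FormalMethodsClassifier.fit`` takes a *sequence of per-patient feature
tables* (one DataFrame of slice rows x 22 feature columns per patient, as
produced by :func:`crclm_fm.radiomics.extract_patient_features`) plus the
per-patient class labels, and learns

1. a feature subset (information-gain ranking on patient medians,
   restricted to the configured feature families),
2. a quantile discretisation scheme on the pooled training slices,
3. a set of discriminating subsequence pattern rules, disjoined into one
   closed mu-calculus property.

``predict`` discretises each new patient with the fitted scheme, builds the
chain LTS and model-checks the fitted property: True means "metastatic".
Everything is deterministic; there is no random state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .formal_models import (
    DiscretizationScheme,
    build_patient_lts,
    discretize_trace,
    fit_discretization,
)
from .induction import (
    HEALTHY,
    METASTATIC,
    InducedProperty,
    classify_patient,
    induce_property,
    mine_patterns,
)
from .selection import FeatureRanking, rank_features, select_features

__all__ = ["FormalMethodsClassifier"]


class FormalMethodsClassifier(BaseEstimator, ClassifierMixin):
    """Precision-first trace classifier for radiomic slice sequences.

    Parameters
    ----------
    families : tuple of str
        Feature families eligible for selection (default mirrors the three
        families the source study found most discriminating).
    gain_threshold : float
        Keep features with information gain strictly above this (bits).
    n_levels : int
        Number of quantile levels K of the discretisation alphabet.
    min_support_pos, max_support_neg : float
        Pattern acceptance thresholds: minimum fraction of metastatic
        training traces containing the pattern, maximum fraction of healthy
        ones.  ``max_support_neg = 0`` forbids any healthy training match.
    max_pattern_len : int
        Maximum pattern length explored by the miner.
    max_rules : int
        Cap on the number of rules disjoined into the final property.
    """

    def __init__(
        self,
        families: tuple[str, ...] = ("FIRST", "GLDM", "GLSZM"),
        gain_threshold: float = 0.0,
        n_levels: int = 5,
        min_support_pos: float = 0.8,
        max_support_neg: float = 0.0,
        max_pattern_len: int = 2,
        max_rules: int = 20,
    ):
        self.families = families
        self.gain_threshold = gain_threshold
        self.n_levels = n_levels
        self.min_support_pos = min_support_pos
        self.max_support_neg = max_support_neg
        self.max_pattern_len = max_pattern_len
        self.max_rules = max_rules

    # ------------------------------------------------------------------

    @staticmethod
    def _cohort_table(X: list[pd.DataFrame]) -> pd.DataFrame:
        frames = []
        for i, table in enumerate(X):
            t = table.copy()
            t.insert(0, "patient_id", f"train{i:04d}")
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def fit(self, X: list[pd.DataFrame], y) -> "FormalMethodsClassifier":
        y = np.asarray(y, dtype=object)
        if len(X) != y.size:
            raise ValueError("X and y lengths differ")
        if y.size < 2 or np.unique(y).size < 2:
            raise ValueError("need >= 2 patients with both classes present")
        bad = set(y) - {HEALTHY, METASTATIC}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

        cohort = self._cohort_table(list(X))
        labels = pd.Series(
            y, index=[f"train{i:04d}" for i in range(y.size)], name="label"
        )
        self.ranking_: FeatureRanking = rank_features(cohort, labels)
        self.selected_features_ = select_features(
            self.ranking_, families_kept=tuple(self.families),
            gain_threshold=self.gain_threshold,
        )
        if self.selected_features_:
            self.scheme_: DiscretizationScheme | None = fit_discretization(
                cohort, self.selected_features_, n_levels=self.n_levels
            )
            traces = [discretize_trace(table, self.scheme_) for table in X]
            rules = mine_patterns(
                traces,
                list(y),
                max_len=self.max_pattern_len,
                min_support_pos=self.min_support_pos,
                max_support_neg=self.max_support_neg,
            )
        else:  # nothing discriminates: degenerate property, classify nobody
            self.scheme_ = None
            rules = []
        self.property_: InducedProperty = induce_property(rules, max_rules=self.max_rules)
        self.rules_ = self.property_.rules
        self.classes_ = np.unique(y)
        return self

    def predict(self, X: list[pd.DataFrame]) -> np.ndarray:
        if not hasattr(self, "property_"):
            raise RuntimeError("classifier is not fitted")
        out = []
        for table in X:
            if self.scheme_ is None:
                out.append(HEALTHY)
                continue
            symbols = discretize_trace(table, self.scheme_)
            lts = build_patient_lts(symbols)
            out.append(classify_patient(lts, self.property_))
        return np.asarray(out, dtype=object)

    def property_text(self) -> str:
        """Concrete syntax of the fitted disease property."""
        if not hasattr(self, "property_"):
            raise RuntimeError("classifier is not fitted")
        return str(self.property_.formula)
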