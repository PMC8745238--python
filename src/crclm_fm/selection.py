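"""Supervised feature ranking and selection on a labelled cohort table.

Replaces the attribute-selection step of the original workflow with a
deterministic, inspectable scheme: each patient is summarised by the median
of its per-slice feature values (labels are per patient; slices of one
patient are not independent), every feature is scored by the information
gain (in bits) of its entropy-optimal binary split against the class labels,
and selection keeps the features of the requested families whose gain
exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .radiomics import FAMILY_OF, FEATURE_NAMES

__all__ = [
    "FeatureRanking",
    "patient_medians",
    "rank_features",
    "select_features",
    "class_distributions",
    "information_gain",
]


@dataclass(frozen=True)
class FeatureRanking:
    """Ordered (feature, family, gain-in-bits) triples, gain non-increasing.

    Ties are broken lexicographically by canonical feature name.
    """

    entries: tuple[tuple[str, str, float], ...]

    def gains(self) -> dict[str, float]:
        return {name: gain for name, _, gain in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "family", "gain"])


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(values: np.ndarray, labels: np.ndarray) -> float:
    """Best single binary-split information gain of ``values`` vs ``labels``.

    Candidate cut points are midpoints between consecutive distinct sorted
    values; a constant feature has gain 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    h0 = _entropy(y)
    n = v.size
    best = 0.0
    for i in range(n - 1):
        if v[i] == v[i + 1]:
            continue
        left, right = y[: i + 1], y[i + 1 :]
        h = (left.size * _entropy(left) + right.size * _entropy(right)) / n
        best = max(best, h0 - h)
    return best


def patient_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient median of each feature over slices.

    ``table`` is a cohort slice table with a ``patient_id`` column plus the
    feature columns.
    """
    if "patient_id" not in table.columns:
        raise ValueError("cohort table needs a patient_id column")
    feats = [c for c in FEATURE_NAMES if c in table.columns]
    return table.groupby("patient_id", sort=True)[feats].median()


def rank_features(table: pd.DataFrame, labels: pd.Series) -> FeatureRanking:
    """Rank all features by information gain on patient-level medians.

    ``labels`` maps patient_id -> class; both classes must be present.
    """
    med = patient_medians(table)
    y = np.asarray(labels.reindex(med.index))
    if pd.isna(y).any():
        raise ValueError("labels missing for some patients in the table")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to rank features")
    scored = [
        (name, FAMILY_OF[name], information_gain(med[name].to_numpy(), y))
        for name in med.columns
    ]
    scored.sort(key=lambda t: (-t[2], t[0]))
    return FeatureRanking(entries=tuple(scored))


def select_features(
    ranking: FeatureRanking,
    families_kept: tuple[str, ...] = ("FIRST", "GLDM", "GLSZM"),
    gain_threshold: float = 0.0,
) -> list[str]:
    """Retained feature names, in rank order.

    Keeps features whose family is in ``families_kept`` and whose gain is
    strictly above ``gain_threshold``.  An empty result warns but is valid.
    """
    kept = [
        name
        for name, family, gain in ranking.entries
        if family in families_kept and gain > gain_threshold
    ]
    if not kept:
        warnings.warn("feature selection retained no feature")
    return kept


def class_distributions(
    table: pd.DataFrame,
    labels: pd.Series,
    feature: str,
    n_bins: int = 20,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-class histogram plus kernel-smoothed trend of one feature.

    Returns {class: {"bin_edges", "counts", "grid", "density"}} on a shared
    bin grid, serialisable for plotting (the class-wise distribution panels
    of the study's diagnostics).  Degenerate (constant) classes get a zero
    density trend.
    """
    if feature not in table.columns:
        raise ValueError(f"unknown feature {feature!r}")
    med = patient_medians(table)[feature]
    y = labels.reindex(med.index)
    lo, hi = float(med.min()), float(med.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    grid = np.linspace(lo, hi, 200)
    out: dict[str, dict[str, np.ndarray]] = {}
    for cls in sorted(pd.unique(y)):
        v = med[y == cls].to_numpy(dtype=float)
        counts, _ = np.histogram(v, bins=edges)
        if v.size > 1 and np.ptp(v) > 0:
            density = gaussian_kde(v)(grid)
        else:
            density = np.zeros_like(grid)
        out[str(cls)] = {
            "bin_edges": edges,
            "counts": counts,
            "grid": grid,
            "density": density,
        }
    return out
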