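"""Diagnostic accuracy and clinical-utility statistics; pipeline driver.

The positive class is "metastatic" throughout.  Besides the usual confusion
matrix statistics the report carries Mitchell's clinical utility indices,

    CUI+ = sensitivity x PPV,    CUI- = specificity x NPV,

with the qualitative grades Excellent (>= 0.81), Good (>= 0.64),
Satisfactory (>= 0.49), Poor (< 0.49).  Undefined ratios are reported as the
explicit marker "n/a" (never silent NaN), and an infinite positive
likelihood ratio is rendered as the sentinel string "Inf".  Percentages are
rendered to one decimal, half away from zero.

``run_pipeline`` executes the whole study design end to end under
leave-one-out cross-validation: simulate (or load) a cohort, extract
features, and per fold re-fit selection, discretisation and pattern rules
before classifying the held-out patient.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as fmio
from .classifier import FormalMethodsClassifier
from .induction import HEALTHY, METASTATIC
from .phantoms import PhantomConfig, generate_cohort
from .radiomics import extract_patient_features

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PipelineConfig",
    "confusion",
    "metrics",
    "cui_grade",
    "percent",
    "wilson_interval",
    "run_pipeline",
]

logger = logging.getLogger("crclm_fm")

NOT_APPLICABLE = "n/a"
INF = "Inf"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(predictions: pd.Series | dict, labels: pd.Series | dict) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over matching patient ids; metastatic is positive."""
    pred = pd.Series(predictions)
    lab = pd.Series(labels)
    if set(pred.index) != set(lab.index):
        raise ValueError("prediction and label patient sets differ")
    lab = lab.reindex(pred.index)
    p_pos = pred == METASTATIC
    l_pos = lab == METASTATIC
    return ConfusionMatrix(
        tp=int((p_pos & l_pos).sum()),
        fp=int((p_pos & ~l_pos).sum()),
        fn=int((~p_pos & l_pos).sum()),
        tn=int((~p_pos & ~l_pos).sum()),
    )


def percent(value: float, decimals: int = 1) -> str:
    """Render a proportion as a percentage, half away from zero: 0.933 -> '93.3%'."""
    q = Decimal(1).scaleb(-decimals)
    return f"{Decimal(repr(value * 100)).quantize(q, rounding=ROUND_HALF_UP)}%"


def cui_grade(value: float) -> str:
    """Mitchell's qualitative grade of a clinical utility index."""
    if not 0 <= value <= 1:
        raise ValueError("utility index must lie in [0, 1]")
    if value >= 0.81:
        return "Excellent"
    if value >= 0.64:
        return "Good"
    if value >= 0.49:
        return "Satisfactory"
    return "Poor"


@dataclass(frozen=True)
class MetricsReport:
    """All accuracy and utility statistics of one confusion matrix.

    Proportions are floats in [0, 1]; a metric whose denominator is zero is
    ``None`` and rendered "n/a".  ``lr_pos`` is ``math.inf`` when
    specificity is 1 and sensitivity positive.
    """

    matrix: ConfusionMatrix
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    accuracy: float
    prevalence: float
    lr_pos: float | None
    lr_neg: float | None
    cui_pos: float | None
    cui_pos_grade: str | None
    cui_neg: float | None
    cui_neg_grade: str | None

    def rendered(self) -> dict[str, str]:
        """The report as the study would print it (percentages, sentinels)."""
        def pct(v):
            return NOT_APPLICABLE if v is None else percent(v)

        def num3(v):
            if v is None:
                return NOT_APPLICABLE
            if math.isinf(v):
                return INF
            return f"{v:.3f}"

        return {
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "positive_predictive_value": pct(self.precision),
            "negative_predictive_value": pct(self.npv),
            "positive_likelihood_ratio": num3(self.lr_pos),
            "negative_likelihood_ratio": num3(self.lr_neg),
            "test_score": pct(self.accuracy),
            "prevalence": pct(self.prevalence),
            "clinical_utility_positive": num3(self.cui_pos),
            "clinical_utility_positive_grade": self.cui_pos_grade or NOT_APPLICABLE,
            "clinical_utility_negative": num3(self.cui_neg),
            "clinical_utility_negative_grade": self.cui_neg_grade or NOT_APPLICABLE,
        }

    def to_dict(self) -> dict[str, Any]:
        d = {
            "confusion_matrix": asdict(self.matrix),
            "proportions": {
                "precision": self.precision,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "npv": self.npv,
                "accuracy": self.accuracy,
                "prevalence": self.prevalence,
                "lr_pos": INF if self.lr_pos is not None and math.isinf(self.lr_pos) else self.lr_pos,
                "lr_neg": self.lr_neg,
                "cui_pos": self.cui_pos,
                "cui_neg": self.cui_neg,
            },
            "rendered": self.rendered(),
        }
        return d


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Every statistic of the report, undefined-safe."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    accuracy = (cm.tp + cm.tn) / cm.total
    prevalence = (cm.tp + cm.fn) / cm.total

    lr_pos: float | None
    if sensitivity is None or specificity is None:
        lr_pos = None
    elif specificity < 1:
        lr_pos = sensitivity / (1 - specificity)
    else:
        lr_pos = math.inf if sensitivity > 0 else None  # 0/0: undefined
    if sensitivity is not None and specificity is not None and specificity > 0:
        lr_neg = (1 - sensitivity) / specificity
    else:
        lr_neg = None

    cui_pos = sensitivity * precision if None not in (sensitivity, precision) else None
    cui_neg = specificity * npv if None not in (specificity, npv) else None
    return MetricsReport(
        matrix=cm,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        npv=npv,
        accuracy=accuracy,
        prevalence=prevalence,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        cui_pos=cui_pos,
        cui_pos_grade=None if cui_pos is None else cui_grade(cui_pos),
        cui_neg=cui_neg,
        cui_neg_grade=None if cui_neg is None else cui_grade(cui_neg),
    )


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (optional CI helper)."""
    from scipy.stats import norm

    if n == 0:
        raise ValueError("n must be positive")
    z = norm.ppf(0.5 + confidence / 2)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full leave-one-out run needs; fully seeded."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_bins: int = 32
    families: tuple[str, ...] = ("FIRST", "GLDM", "GLSZM")
    gain_threshold: float = 0.0
    n_levels: int = 5
    min_support_pos: float = 0.8
    max_support_neg: float = 0.0
    max_pattern_len: int = 2
    max_rules: int = 20

    def classifier(self) -> FormalMethodsClassifier:
        return FormalMethodsClassifier(
            families=self.families,
            gain_threshold=self.gain_threshold,
            n_levels=self.n_levels,
            min_support_pos=self.min_support_pos,
            max_support_neg=self.max_support_neg,
            max_pattern_len=self.max_pattern_len,
            max_rules=self.max_rules,
        )


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Simulate, extract, and evaluate under leave-one-out cross-validation.

    Returns the JSON-serialisable report; when ``out_dir`` is given, also
    writes the per-patient feature CSVs, the cohort manifest, the held-out
    predictions and the report itself.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    logger.info("simulating cohort (seed=%d)", config.phantom.seed)
    patients, manifest = generate_cohort(config.phantom)
    if len(patients) < 2:
        raise RuntimeError("pipeline needs at least two patients")

    logger.info("extracting features for %d patients", len(patients))
    tables = [extract_patient_features(p, n_bins=config.n_bins) for p in patients]
    labels = manifest.set_index("patient_id")["label"]

    logger.info("leave-one-out evaluation")
    predictions: dict[str, str] = {}
    fold_info = []
    for i, held_out in enumerate(manifest["patient_id"]):
        train_tables = [t for j, t in enumerate(tables) if j != i]
        train_labels = [labels.iloc[j] for j in range(len(tables)) if j != i]
        clf = config.classifier().fit(train_tables, train_labels)
        predictions[held_out] = str(clf.predict([tables[i]])[0])
        fold_info.append(
            {
                "held_out": held_out,
                "n_selected_features": len(clf.selected_features_),
                "n_rules": len(clf.rules_),
            }
        )

    cm = confusion(pd.Series(predictions), labels)
    report_metrics = metrics(cm)
    report: dict[str, Any] = {
        "config": {
            "phantom": asdict(config.phantom),
            "n_bins": config.n_bins,
            "families": list(config.families),
            "gain_threshold": config.gain_threshold,
            "n_levels": config.n_levels,
            "min_support_pos": config.min_support_pos,
            "max_support_neg": config.max_support_neg,
            "max_pattern_len": config.max_pattern_len,
            "max_rules": config.max_rules,
        },
        "seed": config.phantom.seed,
        "n_patients": len(patients),
        "predictions": {k: predictions[k] for k in sorted(predictions)},
        "folds": fold_info,
        "metrics": report_metrics.to_dict(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        features_dir = out_dir / "features"
        features_dir.mkdir(exist_ok=True)
        for p, t in zip(patients, tables):
            fmio.write_feature_table(t, features_dir / f"{p.patient_id}.csv")
        pd.Series(predictions, name="prediction").rename_axis("patient_id").to_csv(
            out_dir / "predictions.csv"
        )
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True), encoding="utf-8"
        )
    logger.info("pipeline done in %.1f s", time.time() - t0)
    return report
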