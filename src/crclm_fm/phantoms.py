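"""Synthetic CT-like liver phantom cohorts.

The study design this package emulates rests on a 30-patient cohort — 21
healthy controls and 9 patients who later developed colorectal-cancer liver
metastases — with roughly 70 (56–92) segmented portal-phase slices per
patient.  The scans themselves are private, so this module generates seeded
stand-in volumes: each slice is a Gaussian random field (white noise smoothed
with a Gaussian kernel) whose mean, standard deviation and correlation length
are class-specific, restricted to an elliptical liver-parenchyma ROI.  Benign
hyper-/hypodense blobs (angioma/cyst stand-ins) are inserted at the same rate
in both classes, mirroring the study's choice not to exclude benign lesions.

``effect_size`` scales every case-vs-control parameter difference: 0 makes
the classes statistically identical, larger values make them more separable.
No claim of anatomical realism is made; the generator exists to give the
downstream pipeline a controllable, reproducible signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "HEALTHY",
    "METASTATIC",
    "PhantomConfig",
    "PatientVolume",
    "generate_patient",
    "generate_cohort",
    "patient_seed_for",
]

HEALTHY = "healthy"
METASTATIC = "metastatic"
_LABEL_ALIASES = {"healthy": HEALTHY, "case": METASTATIC, "metastatic": METASTATIC}


def _normalize_label(label: str) -> str:
    try:
        return _LABEL_ALIASES[label]
    except KeyError:
        raise ValueError(f"unknown class label {label!r}") from None


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort and texture parameters.

    Two-element tuples are (healthy, case) values; the effective case value
    is ``healthy + effect_size * (case - healthy)``, so ``effect_size = 0``
    collapses the two classes onto identical parameters.
    """

    n_controls: int = 21
    n_cases: int = 9
    slices_per_patient: tuple[int, int] = (56, 92)
    image_shape: tuple[int, int] = (64, 64)
    roi_radius_px: int = 20
    intensity_mean: tuple[float, float] = (100.0, 112.0)  # HU-like
    intensity_sd: tuple[float, float] = (15.0, 22.0)
    correlation_length_px: tuple[float, float] = (2.0, 3.5)
    benign_lesion_rate: float = 0.05  # per slice, both classes
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValueError("patient counts must be non-negative")
        lo, hi = self.slices_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("slices_per_patient must satisfy 1 <= low <= high")
        if min(self.image_shape) < 3 or self.roi_radius_px < 1:
            raise ValueError("non-positive image/ROI dimensions")
        if self.roi_radius_px * 2 + 2 > min(self.image_shape):
            raise ValueError("ROI radius too large for the image shape")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.benign_lesion_rate <= 1:
            raise ValueError("benign_lesion_rate must be a probability")

    def class_params(self, label: str) -> dict[str, float]:
        """Effective (mean, sd, correlation length) for one class."""
        w = self.effect_size if _normalize_label(label) == METASTATIC else 0.0
        def mix(pair: tuple[float, float]) -> float:
            return pair[0] + w * (pair[1] - pair[0])
        return {
            "mean": mix(self.intensity_mean),
            "sd": mix(self.intensity_sd),
            "corr_length": mix(self.correlation_length_px),
        }


@dataclass(frozen=True)
class PatientVolume:
    """One patient's intensity volume (slice, row, col) with per-slice ROI masks."""

    patient_id: str
    label: str
    volume: np.ndarray
    masks: np.ndarray

    def __post_init__(self) -> None:
        if self.volume.shape != self.masks.shape:
            raise ValueError("volume and masks shapes differ")
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D (slice, row, col)")
        if not all(self.masks[s].any() for s in range(self.masks.shape[0])):
            raise ValueError("every slice must have a non-empty ROI mask")

    @property
    def n_slices(self) -> int:
        return self.volume.shape[0]


def _random_field(rng: np.random.Generator, shape: tuple[int, int],
                  mean: float, sd: float, corr_length: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    field_ = gaussian_filter(noise, sigma=corr_length, mode="reflect")
    std = field_.std()
    if std > 0:
        field_ = field_ / std
    return mean + sd * field_


def _elliptical_mask(rng: np.random.Generator, shape: tuple[int, int],
                     radius: int) -> np.ndarray:
    h, w = shape
    ry = radius * rng.uniform(0.85, 1.0)
    rx = radius * rng.uniform(0.85, 1.0)
    margin_y, margin_x = int(np.ceil(ry)) + 1, int(np.ceil(rx)) + 1
    cy = rng.uniform(margin_y, h - 1 - margin_y)
    cx = rng.uniform(margin_x, w - 1 - margin_x)
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _insert_benign_lesion(rng: np.random.Generator, image: np.ndarray,
                          mask: np.ndarray) -> None:
    """Add a smooth hyper- or hypodense circular blob centred inside the ROI."""
    ys, xs = np.nonzero(mask)
    k = rng.integers(0, ys.size)
    cy, cx = ys[k], xs[k]
    radius = rng.uniform(2.0, 4.0)
    amplitude = rng.choice([-1.0, 1.0]) * rng.uniform(20.0, 40.0)
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    image += amplitude * np.exp(-d2 / (2 * (radius / 2.0) ** 2))


def generate_patient(config: PhantomConfig, label: str, patient_seed: int) -> PatientVolume:
    """Generate one patient volume; a pure function of (config, label, seed)."""
    label = _normalize_label(label)
    params = config.class_params(label)
    rng = np.random.default_rng(patient_seed)
    lo, hi = config.slices_per_patient
    n_slices = int(rng.integers(lo, hi + 1))
    volume = np.empty((n_slices, *config.image_shape), dtype=float)
    masks = np.empty((n_slices, *config.image_shape), dtype=bool)
    for s in range(n_slices):
        image = _random_field(
            rng, config.image_shape, params["mean"], params["sd"], params["corr_length"]
        )
        mask = _elliptical_mask(rng, config.image_shape, config.roi_radius_px)
        if rng.uniform() < config.benign_lesion_rate:
            _insert_benign_lesion(rng, image, mask)
        volume[s] = image
        masks[s] = mask
    return PatientVolume(
        patient_id=f"seed{patient_seed}", label=label, volume=volume, masks=masks
    )


def patient_seed_for(master_seed: int, index: int) -> int:
    """Per-patient seed: a counter scheme off the master seed (stays < 2^31)."""
    return int((master_seed * 1_000_003 + 7919 * index + 1) % (2**31))


def generate_cohort(config: PhantomConfig) -> tuple[list[PatientVolume], pd.DataFrame]:
    """Generate the full cohort plus its manifest.

    Controls come first.  The manifest has one row per patient with columns
    (patient_id, label, n_slices, seed) and is the unit of truth for labels.
    """
    labels = [HEALTHY] * config.n_controls + [METASTATIC] * config.n_cases
    patients: list[PatientVolume] = []
    records = []
    for i, label in enumerate(labels):
        seed = patient_seed_for(config.seed, i)
        p = generate_patient(config, label, seed)
        pid = f"P{i + 1:03d}"
        p = replace(p, patient_id=pid)
        patients.append(p)
        records.append(
            {"patient_id": pid, "label": label, "n_slices": p.n_slices, "seed": seed}
        )
    manifest = pd.DataFrame.from_records(
        records, columns=["patient_id", "label", "n_slices", "seed"]
    )
    return patients, manifest
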