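"""Per-slice radiomic texture features of a liver ROI.

Implements the 22 features retained by the study design, spread over five
families:

* FIRST  -- first-order intensity statistics,
* GLDM   -- gray-level dependence matrix,
* GLCM   -- gray-level co-occurrence matrix,
* GLRLM  -- gray-level run-length matrix,
* GLSZM  -- gray-level size-zone matrix,

following the IBSI definitions as popularised by pyradiomics.  All texture
features operate on a gray-level image quantised to a fixed number of
equal-width bins between the in-mask minimum and maximum, which makes every
discretised-level feature invariant under affine rescaling of the raw
intensities.  Entropies are in bits (log base 2).

Computation is strictly 2D and per slice: one feature vector per CT slice,
restricted to that slice's ROI mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FEATURE_FAMILIES",
    "FEATURE_NAMES",
    "FAMILY_OF",
    "DISCRETIZED_FEATURES",
    "QuantizedROI",
    "quantize",
    "first_order_features",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "extract_slice_features",
    "extract_patient_features",
]

# Canonical snake_case feature names, grouped by family, in canonical order.
# The display names used in radiology literature are the title-case versions
# ("Robust Mean Absolute Deviation" <-> robust_mean_absolute_deviation, etc.).
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "FIRST": (
        "entropy",
        "interquartile_range",
        "mean_absolute_deviation",
        "robust_mean_absolute_deviation",
        "uniformity",
    ),
    "GLDM": (
        "dependence_entropy",
        "high_gray_level_emphasis",
        "large_dependence_low_gray_level_emphasis",
        "low_gray_level_emphasis",
        "small_dependence_low_gray_level_emphasis",
    ),
    "GLCM": (
        "autocorrelation",
        "joint_average",
        "joint_entropy",
        "sum_average",
        "sum_entropy",
    ),
    "GLRLM": (
        "high_gray_level_run_emphasis",
        "long_run_low_gray_level_emphasis",
        "low_gray_level_run_emphasis",
        "short_run_low_gray_level_emphasis",
    ),
    "GLSZM": (
        "high_gray_level_zone_emphasis",
        "low_gray_level_zone_emphasis",
        "small_area_low_gray_level_emphasis",
    ),
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    name for family in FEATURE_FAMILIES.values() for name in family
)

FAMILY_OF: dict[str, str] = {
    name: family for family, names in FEATURE_FAMILIES.items() for name in names
}

#: Features computed on quantised gray levels (affine-invariant); the
#: complement (IQR, MAD, robust MAD) is computed on raw intensities.
DISCRETIZED_FEATURES: tuple[str, ...] = tuple(
    n
    for n in FEATURE_NAMES
    if n
    not in (
        "interquartile_range",
        "mean_absolute_deviation",
        "robust_mean_absolute_deviation",
    )
)

# 2D directions: east, north-east, north, north-west (offsets as (drow, dcol)).
_DIRECTIONS_4: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
_NEIGHBOURS_8: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)

@dataclass(frozen=True)
class QuantizedROI:
    """A 2D ROI quantised to integer gray levels.

    ``levels`` holds values in ``1..n_levels`` inside the mask and 0 outside;
    out-of-mask pixels take part in no statistic.
    """

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("empty ROI mask")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("in-mask levels must lie in [1, n_levels]")


def quantize(image: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> QuantizedROI:
    """Equal-width quantisation of in-mask intensities to ``1..n_bins``.

    Bins span the in-mask min..max; a constant ROI maps to the single level 1.
    The effective number of levels ``n_levels`` is the highest occupied bin.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    values = image[mask]
    if values.size == 0:
        raise ValueError("empty ROI mask")
    lo, hi = values.min(), values.max()
    levels = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        width = (hi - lo) / n_bins
        binned = np.floor((image[mask] - lo) / width).astype(np.int64) + 1
        levels[mask] = np.clip(binned, 1, n_bins)
    return QuantizedROI(levels=levels, n_levels=int(levels.max()), mask=mask)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------

def first_order_features(roi: QuantizedROI, raw_pixels: np.ndarray) -> dict[str, float]:
    """First-order statistics.

    Entropy and Uniformity use the discretised gray-level histogram; the
    three dispersion features use the raw in-mask intensities.  Robust MAD
    is the mean absolute deviation of the sub-sample within the closed
    10th..90th percentile interval.
    """
    raw = np.asarray(raw_pixels, dtype=float).ravel()
    if raw.size == 0:
        raise ValueError("empty ROI")
    levels = roi.levels[roi.mask]
    counts = np.bincount(levels, minlength=roi.n_levels + 1)[1:]
    p = counts / counts.sum()

    q25, q75 = np.percentile(raw, [25, 75])
    p10, p90 = np.percentile(raw, [10, 90])
    robust = raw[(raw >= p10) & (raw <= p90)]
    return {
        "entropy": _entropy_bits(p),
        "interquartile_range": float(q75 - q25),
        "mean_absolute_deviation": float(np.abs(raw - raw.mean()).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(roi: QuantizedROI, offset: tuple[int, int], distance: int) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction."""
    dr, dc = offset[0] * distance, offset[1] * distance
    lvl, mask = roi.levels, roi.mask
    h, w = lvl.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a, b = lvl[r0, c0], lvl[r1, c1]
    valid = mask[r0, c0] & mask[r1, c1]
    ng = roi.n_levels
    counts = np.zeros((ng, ng), dtype=float)
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    return counts + counts.T


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 2..2*ng
    k = np.arange(2, 2 * ng + 1)
    pxy = np.zeros(k.size)
    np.add.at(pxy, (ii + jj).ravel() - 2, p.ravel())
    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": float((ii * p).sum()),
        "joint_entropy": _entropy_bits(p.ravel()),
        "sum_average": float((k * pxy).sum()),
        "sum_entropy": _entropy_bits(pxy),
    }


def glcm_features(
    roi: QuantizedROI,
    distance: int = 1,
    angles: tuple[tuple[int, int], ...] = _DIRECTIONS_4,
) -> dict[str, float]:
    """Co-occurrence features, averaged over the direction set.

    Counts are accumulated symmetrically per direction and normalised per
    direction before averaging.  Directions with no valid pixel pair are
    dropped; if none remains, all features are NaN (with a warning).
    """
    per_angle = []
    for offset in angles:
        counts = _glcm_matrix(roi, offset, distance)
        total = counts.sum()
        if total > 0:
            per_angle.append(_glcm_single(counts / total))
    if not per_angle:
        warnings.warn("GLCM: no valid pixel pair in any direction; features are NaN")
        return {name: float("nan") for name in FEATURE_FAMILIES["GLCM"]}
    return {
        name: float(np.mean([f[name] for f in per_angle]))
        for name in FEATURE_FAMILIES["GLCM"]
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_features(roi: QuantizedROI, alpha: int = 0) -> dict[str, float]:
    """Gray-level dependence features.

    A neighbour (8-connectivity, in-mask) is *dependent* on the centre pixel
    when their level difference is at most ``alpha``.  The dependence index
    j counts the dependent group including the centre itself (j = number of
    dependent neighbours + 1), so isolated pixels contribute at j = 1.
    """
    lvl, mask = roi.levels, roi.mask
    h, w = lvl.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in _NEIGHBOURS_8:
        r0 = slice(max(0, -dr), min(h, h - dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        r1 = slice(max(0, dr), min(h, h + dr))
        c1 = slice(max(0, dc), min(w, w + dc))
        ok = (
            mask[r0, c0]
            & mask[r1, c1]
            & (np.abs(lvl[r0, c0] - lvl[r1, c1]) <= alpha)
        )
        dep[r0, c0] += ok
    g = lvl[mask]
    j = dep[mask] + 1
    nd = int(j.max())
    counts = np.zeros((roi.n_levels, nd), dtype=float)
    np.add.at(counts, (g - 1, j - 1), 1.0)
    p = counts / counts.sum()
    gi = np.arange(1, roi.n_levels + 1)[:, None].astype(float)
    ji = np.arange(1, nd + 1)[None, :].astype(float)
    return {
        "dependence_entropy": _entropy_bits(p.ravel()),
        "high_gray_level_emphasis": float((p * gi**2).sum()),
        "large_dependence_low_gray_level_emphasis": float((p * ji**2 / gi**2).sum()),
        "low_gray_level_emphasis": float((p / gi**2).sum()),
        "small_dependence_low_gray_level_emphasis": float((p / (ji**2 * gi**2)).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _direction_lines(arr: np.ndarray, offset: tuple[int, int]) -> list[np.ndarray]:
    """1D scan lines of ``arr`` along a direction offset."""
    h, w = arr.shape
    dr, dc = offset
    if (dr, dc) == (0, 1):
        return [arr[r] for r in range(h)]
    if (dr, dc) == (-1, 0):
        return [arr[:, c] for c in range(w)]
    if (dr, dc) == (-1, 1):  # anti-diagonals, scanned bottom-left -> top-right
        flipped = arr[::-1]
        return [flipped.diagonal(k) for k in range(-h + 1, w)]
    if (dr, dc) == (-1, -1):  # main diagonals, scanned bottom-right -> top-left
        flipped = arr[::-1, ::-1]
        return [flipped.diagonal(k) for k in range(-h + 1, w)]
    raise ValueError(f"unsupported direction {offset!r}")


def _runs_along(levels_masked: np.ndarray, offset: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(level, length) of maximal constant-level in-mask runs along a direction.

    ``levels_masked`` has level 0 on out-of-mask pixels, which terminates runs.
    """
    lines = _direction_lines(levels_masked, offset)
    # Concatenate all scan lines with 0 sentinels so runs never straddle lines.
    flat = np.concatenate([x for line in lines for x in (line, [0])])
    change = np.flatnonzero(np.diff(flat, prepend=-1))
    lengths = np.diff(change, append=flat.size)
    values = flat[change]
    keep = values > 0
    return values[keep], lengths[keep]


def glrlm_features(
    roi: QuantizedROI,
    angles: tuple[tuple[int, int], ...] = _DIRECTIONS_4,
) -> dict[str, float]:
    """Run-length features, averaged over the direction set."""
    lvl = np.where(roi.mask, roi.levels, 0)
    per_angle = []
    for offset in angles:
        g, r = _runs_along(lvl, offset)
        if g.size == 0:
            continue
        total = g.size
        p_g = g.astype(float)
        p_r = r.astype(float)
        per_angle.append(
            {
                "high_gray_level_run_emphasis": float((p_g**2).sum() / total),
                "long_run_low_gray_level_emphasis": float((p_r**2 / p_g**2).sum() / total),
                "low_gray_level_run_emphasis": float((1.0 / p_g**2).sum() / total),
                "short_run_low_gray_level_emphasis": float(
                    (1.0 / (p_r**2 * p_g**2)).sum() / total
                ),
            }
        )
    if not per_angle:
        warnings.warn("GLRLM: no run in any direction; features are NaN")
        return {name: float("nan") for name in FEATURE_FAMILIES["GLRLM"]}
    return {
        name: float(np.mean([f[name] for f in per_angle]))
        for name in FEATURE_FAMILIES["GLRLM"]
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def glszm_features(roi: QuantizedROI) -> dict[str, float]:
    """Size-zone features over 8-connected equal-level zones."""
    lvl = np.where(roi.mask, roi.levels, 0)
    zone_levels: list[np.ndarray] = []
    zone_sizes: list[np.ndarray] = []
    for g in range(1, roi.n_levels + 1):
        labelled, n = ndimage.label(lvl == g, structure=_STRUCT_8)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            zone_levels.append(np.full(n, g, dtype=float))
            zone_sizes.append(sizes.astype(float))
    g = np.concatenate(zone_levels)
    s = np.concatenate(zone_sizes)
    total = g.size
    return {
        "high_gray_level_zone_emphasis": float((g**2).sum() / total),
        "low_gray_level_zone_emphasis": float((1.0 / g**2).sum() / total),
        "small_area_low_gray_level_emphasis": float((1.0 / (s**2 * g**2)).sum() / total),
    }


# ---------------------------------------------------------------------------
# Per-slice / per-patient extraction
# ---------------------------------------------------------------------------

def extract_slice_features(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    glcm_distance: int = 1,
    gldm_alpha: int = 0,
) -> dict[str, float]:
    """All 22 features of one slice's ROI, as a name -> value dict."""
    roi = quantize(image, mask, n_bins=n_bins)
    raw = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    out: dict[str, float] = {}
    out.update(first_order_features(roi, raw))
    out.update(gldm_features(roi, alpha=gldm_alpha))
    out.update(glcm_features(roi, distance=glcm_distance))
    out.update(glrlm_features(roi))
    out.update(glszm_features(roi))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_patient_features(patient, n_bins: int = 32) -> pd.DataFrame:
    """Feature table of a patient volume: one row per slice, cranio-caudal.

    ``patient`` is a :class:`crclm_fm.phantoms.PatientVolume` (or anything with
    ``volume`` (S, H, W), ``masks`` (S, H, W) and ``patient_id``).
    """
    rows = []
    for s in range(patient.volume.shape[0]):
        mask = patient.masks[s]
        if not np.any(mask):
            raise ValueError(f"patient {patient.patient_id}: empty mask at slice {s}")
        rows.append(extract_slice_features(patient.volume[s], mask, n_bins=n_bins))
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table.index.name = "slice_idx"
    return table
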