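"""Segmentation agreement metrics: DSC, surface error, areas, Bland–Altman.

The two headline metrics for single-slice muscle segmentation are the Dice
similarity coefficient,

    DSC = 2 TP / (2 TP + FP + FN)
        = 1 - (FP + FN) / (2 TP + FP + FN),

and the segmentation surface error, the physical area of the disagreement
region,

    SSE = (FP + FN) * pixel_area  [cm^2],

where TP/FP/FN count pixels of the model mask against the reference
standard and pixel_area comes from the scan's pixel spacing.  Cohort-level
agreement between reference and model muscle areas is summarised by a
Bland–Altman analysis with limits of agreement at mean +/- 1.96 SD of the
paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SegmentationPair",
    "PairMetrics",
    "BlandAltman",
    "confusion_counts",
    "dice",
    "dice_from_counts",
    "sse",
    "surface_area",
    "evaluate_pair",
    "bland_altman",
    "summarize_cohort",
]


@dataclass
class SegmentationPair:
    """Reference and model masks with the physical pixel area (cm^2/pixel)."""

    reference: np.ndarray
    prediction: np.ndarray
    pixel_area: float  # cm^2 per pixel = row_mm * col_mm / 100

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=bool)
        self.prediction = np.asarray(self.prediction, dtype=bool)
        if self.reference.shape != self.prediction.shape:
            raise ValueError(
                f"mask shapes differ: {self.reference.shape} vs {self.prediction.shape}"
            )
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")


@dataclass(frozen=True)
class PairMetrics:
    """Per-subject agreement summary."""

    tp: int
    fp: int
    fn: int
    dsc: float
    sse: float  # cm^2
    ref_area: float  # cm^2
    pred_area: float  # cm^2


def confusion_counts(pair: SegmentationPair) -> tuple[int, int, int]:
    """Pixel-level (TP, FP, FN) of the prediction against the reference."""
    ref, pred = pair.reference, pair.prediction
    tp = int(np.count_nonzero(ref & pred))
    fp = int(np.count_nonzero(~ref & pred))
    fn = int(np.count_nonzero(ref & ~pred))
    return tp, fp, fn


def dice_from_counts(tp: int, fp: int, fn: int, *, empty_value: float = 1.0) -> float:
    """DSC from confusion counts; ``empty_value`` covers the both-empty case."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        return empty_value
    return 2.0 * tp / denom


def dice(pair: SegmentationPair, *, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient of a mask pair.

    When both masks are empty there is no overlap to quantify; by default
    this degenerate case scores 1.0 (vacuous perfect agreement) with a
    warning.  A reference-empty/prediction-nonempty pair scores 0.
    """
    tp, fp, fn = confusion_counts(pair)
    if 2 * tp + fp + fn == 0:
        warnings.warn("both masks empty; returning the configured empty-pair DSC", stacklevel=2)
        return empty_value
    return dice_from_counts(tp, fp, fn)


def sse(pair: SegmentationPair) -> float:
    """Segmentation surface error in cm^2: (FP + FN) * pixel_area."""
    _, fp, fn = confusion_counts(pair)
    return (fp + fn) * pair.pixel_area


def surface_area(mask: np.ndarray, pixel_area: float) -> float:
    """Foreground area of a binary mask in cm^2."""
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    return float(np.count_nonzero(mask) * pixel_area)


def evaluate_pair(pair: SegmentationPair) -> PairMetrics:
    """All per-subject metrics for one reference/prediction pair."""
    tp, fp, fn = confusion_counts(pair)
    return PairMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        dsc=dice_from_counts(tp, fp, fn),
        sse=(fp + fn) * pair.pixel_area,
        ref_area=(tp + fn) * pair.pixel_area,
        pred_area=(tp + fp) * pair.pixel_area,
    )


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference and +/- 1.96 SD limits of agreement (cm^2)."""

    mean_difference: float
    loa_upper: float
    loa_lower: float
    n_outside: int


def bland_altman(
    ref_areas: Sequence[float],
    pred_areas: Sequence[float],
    *,
    orientation: str = "pred_minus_ref",
) -> BlandAltman:
    """Bland–Altman agreement between reference and model areas.

    Differences default to prediction - reference; flip with
    ``orientation='ref_minus_pred'``.  Limits of agreement use the sample
    SD (n-1 denominator).  ``n_outside`` counts differences strictly outside
    the limits.
    """
    ref = np.asarray(ref_areas, dtype=float)
    pred = np.asarray(pred_areas, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("ref_areas and pred_areas must be 1-D of equal length")
    if len(ref) < 2:
        raise ValueError("Bland–Altman requires at least 2 paired areas")
    if orientation == "pred_minus_ref":
        d = pred - ref
    elif orientation == "ref_minus_pred":
        d = ref - pred
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    upper, lower = mean + 1.96 * sd, mean - 1.96 * sd
    n_outside = int(np.count_nonzero((d > upper) | (d < lower)))
    return BlandAltman(mean_difference=mean, loa_upper=upper, loa_lower=lower, n_outside=n_outside)


def summarize_cohort(metrics: Sequence[PairMetrics]) -> dict[str, dict[str, float]]:
    """Median and IQR (linear-interpolated 25th/75th percentiles) per metric."""
    if len(metrics) == 0:
        raise ValueError("cannot summarize an empty cohort")
    out: dict[str, dict[str, float]] = {}
    for name in ("dsc", "sse", "ref_area", "pred_area"):
        values = np.array([getattr(m, name) for m in metrics], dtype=float)
        q25, q50, q75 = np.percentile(values, [25, 50, 75])
        out[name] = {"median": float(q50), "iqr_low": float(q25), "iqr_high": float(q75)}
    return out
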