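"""Segmentation evaluation: pixel confusion counts and the seven scores.

For binary masks (background 0, DME 1) the joint tabulation ``p[i][j]`` counts
pixels of true class ``i`` predicted as class ``j``.  From it:

- PA    overall pixel accuracy, ``sum_i p_ii / sum_ij p_ij``
- MPA   mean per-class accuracy (per-class recall averaged over classes)
- Pre   precision of the DME class, ``TP / (TP + FP)``
- Re    recall of the DME class, ``TP / (TP + FN)``
- F1    harmonic mean of Pre and Re
- MIoU  mean over classes of ``p_ii / (row_i + col_i - p_ii)``
- FPS   images per second, ``frameNum / elapsedTime`` (hardware-dependent)

Any class-wise ratio that is 0/0 (the class absent from both masks) scores 1:
vacuously perfect agreement.  Metrics over a dataset are micro-averaged: the
confusion counts are summed over images before the ratios are taken.

Overlay rendering follows the standard error-visualization convention:
true positives red, false positives blue, false negatives white, true
negatives keep the underlying image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "metric_report",
    "render_overlay",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 pixel confusion matrix; p[i][j] = true class i predicted as j."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p)
        if p.shape != (2, 2):
            raise ValueError(f"expected a 2x2 matrix, got shape {p.shape}")
        if (p < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "p", p.astype(np.int64))

    @property
    def TP(self) -> int:
        return int(self.p[1, 1])

    @property
    def FP(self) -> int:
        return int(self.p[0, 1])

    @property
    def FN(self) -> int:
        return int(self.p[1, 0])

    @property
    def TN(self) -> int:
        return int(self.p[0, 0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.p + other.p)


@dataclass(frozen=True)
class MetricReport:
    PA: float
    MPA: float
    Pre: float
    Re: float
    F1: float
    MIoU: float
    FPS: float | None = None

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        d = {k: getattr(self, k) * scale for k in ("PA", "MPA", "Pre", "Re", "F1", "MIoU")}
        d["FPS"] = self.FPS
        return d


def _validate_masks(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    for name, m in (("pred", pred), ("true", true)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask contains values other than 0/1: {vals}")
    return pred.astype(np.int64), true.astype(np.int64)


def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Exact joint tabulation of a binary prediction against ground truth."""
    pred, true = _validate_masks(pred_mask, true_mask)
    joint = np.bincount((true * 2 + pred).ravel(), minlength=4)
    return ConfusionCounts(joint.reshape(2, 2))


def _safe_ratio(num: float, den: float) -> float:
    # 0/0 -> 1 by the vacuous-agreement convention; x/0 with x>0 cannot occur
    # for these ratios since the numerator is part of the denominator.
    if den == 0:
        return 1.0
    return num / den


def metric_report(counts: ConfusionCounts, frame_num: int | None = None,
                  elapsed_time: float | None = None) -> MetricReport:
    """Compute PA/MPA/Pre/Re/F1/MIoU (fractions) and optionally FPS."""
    p = counts.p.astype(np.float64)
    total = p.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(p)
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    pa = diag.sum() / total
    mpa = float(np.mean([_safe_ratio(diag[i], rows[i]) for i in range(2)]))
    pre = _safe_ratio(counts.TP, counts.TP + counts.FP)
    re = _safe_ratio(counts.TP, counts.TP + counts.FN)
    f1 = _safe_ratio(2.0 * pre * re, pre + re)
    miou = float(np.mean([_safe_ratio(diag[i], rows[i] + cols[i] - diag[i])
                          for i in range(2)]))
    fps = None
    if frame_num is not None and elapsed_time is not None:
        if elapsed_time <= 0:
            raise ValueError("elapsed time must be positive to compute FPS")
        fps = frame_num / elapsed_time
    return MetricReport(PA=pa, MPA=mpa, Pre=pre, Re=re, F1=f1, MIoU=miou, FPS=fps)


# Overlay colors (RGB): TP red, FP blue, FN white.
_TP_COLOR = (255, 0, 0)
_FP_COLOR = (0, 0, 255)
_FN_COLOR = (255, 255, 255)


def render_overlay(pred_mask: np.ndarray, true_mask: np.ndarray,
                   image: np.ndarray | None = None) -> np.ndarray:
    """RGB uint8 error overlay: TP red, FP blue, FN white, TN background.

    ``image`` (grayscale uint8/float in [0,1]) supplies the background where
    prediction and truth agree on background; black when omitted.
    """
    pred, true = _validate_masks(pred_mask, true_mask)
    h, w = pred.shape
    if image is None:
        bg = np.zeros((h, w), dtype=np.uint8)
    else:
        img = np.asarray(image)
        if img.shape[:2] != (h, w):
            raise ValueError(f"image shape {img.shape} does not match masks {pred.shape}")
        bg = (np.clip(img, 0, 1) * 255).astype(np.uint8) if img.dtype.kind == "f" \
            else img.astype(np.uint8)
        if bg.ndim == 3:
            bg = bg[:, :, 0]
    out = np.repeat(bg[:, :, None], 3, axis=2)
    out[(true == 1) & (pred == 1)] = _TP_COLOR
    out[(true == 0) & (pred == 1)] = _FP_COLOR
    out[(true == 1) & (pred == 0)] = _FN_COLOR
    return out
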