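"""Evaluation: reconciliation, metrics, Grade Groups, kappa, timing.

Annotation-level evaluation reconciles each ground-truth region with
the predicted raster by majority pixel area, then computes per-class
precision / sensitivity / F1 (macro-averaged arithmetically) and binary
malignant-vs-non-malignant sensitivity, specificity, PPV and NPV.

Slide-level evaluation derives the Gleason score from the predicted
malignant areas — primary pattern = largest area, secondary = next
largest provided it reaches 5% of the malignant area, else the primary
is doubled — and maps it to the 5-tier Grade Group:
GG1 = score 6, GG2 = 3+4, GG3 = 4+3, GG4 = score 8, GG5 = scores 9-10.
Observer agreement on Grade Groups uses quadratic weighted kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from .geo import Annotation, rasterize_polygon
from .types import (CLASS_CODES, CLASS_NAMES, CODE_NAMES, MALIGNANT_CLASSES,
                    severity_rank)

__all__ = [
    "GradeGroup",
    "MetricTable",
    "TimingSummary",
    "reconcile_instance_label",
    "evaluate_annotations",
    "classification_metrics",
    "slide_gleason",
    "grade_group_from_patterns",
    "quadratic_weighted_kappa",
    "timing_summary",
]


@dataclass(frozen=True)
class GradeGroup:
    """Gleason score and its prognostic Grade Group (1-5).

    ``group`` is ``None`` for slides without malignant tissue.
    """

    primary: Optional[int]
    secondary: Optional[int]

    @property
    def gleason_score(self) -> Optional[int]:
        if self.primary is None:
            return None
        return self.primary + self.secondary

    @property
    def group(self) -> Optional[int]:
        if self.primary is None:
            return None
        score = self.gleason_score
        if score == 6:
            return 1
        if score == 7:
            return 2 if (self.primary, self.secondary) == (3, 4) else 3
        if score == 8:
            return 4
        return 5  # scores 9 and 10


def grade_group_from_patterns(primary: int, secondary: int) -> int:
    """Grade Group of a (primary, secondary) Gleason pattern pair."""
    if primary not in (3, 4, 5) or secondary not in (3, 4, 5):
        raise ValueError("patterns must be 3, 4 or 5")
    return GradeGroup(primary, secondary).group


def reconcile_instance_label(pred_raster: np.ndarray,
                             polygon: Polygon | Annotation) -> str:
    """Final predicted label of one annotated instance.

    The class covering the largest scored pixel area inside the polygon
    wins; exact area ties go to the more severe class.  A polygon whose
    pixels are entirely unscored raises.
    """
    poly = polygon.polygon if isinstance(polygon, Annotation) else polygon
    mask = rasterize_polygon(poly, pred_raster.shape)
    inside = pred_raster[mask]
    inside = inside[inside > 0]
    if inside.size == 0:
        raise ValueError("polygon covers no scored pixels")
    counts = np.bincount(inside, minlength=len(CLASS_NAMES) + 1)
    best = max(
        (code for code in range(1, len(CLASS_NAMES) + 1) if counts[code] > 0),
        key=lambda code: (counts[code], -severity_rank(CODE_NAMES[code])),
    )
    return CODE_NAMES[best]


def evaluate_annotations(
    pred_raster: np.ndarray,
    annotations: Sequence[Annotation],
    max_unscored_fraction: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Reconcile every annotation against a prediction raster.

    Returns parallel ground-truth and predicted label vectors.
    Instances with more than ``max_unscored_fraction`` of their pixels
    unscored are excluded (quality guard).
    """
    gt, pred = [], []
    for ann in annotations:
        mask = rasterize_polygon(ann.polygon, pred_raster.shape)
        total = int(mask.sum())
        if total == 0:
            continue
        unscored = int((pred_raster[mask] == 0).sum())
        if unscored / total > max_unscored_fraction:
            continue
        gt.append(ann.label)
        pred.append(reconcile_instance_label(pred_raster, ann))
    return gt, pred


@dataclass
class MetricTable:
    """Per-class and binary classification metrics."""

    per_class: pd.DataFrame  # index class, columns precision/sensitivity/f1
    macro_f1: float
    binary: dict[str, float]  # sensitivity, specificity, ppv, npv

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_class.copy()
        rows.loc["macro"] = [np.nan, np.nan, self.macro_f1]
        return rows


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def classification_metrics(gt: Sequence[str], pred: Sequence[str]) -> MetricTable:
    """One-vs-rest per-class metrics plus binary malignancy metrics.

    Macro F1 is the arithmetic mean of per-class F1 over classes present
    in ground truth or prediction; absent classes are excluded with a
    warning.  Binary metrics group GP3/GP4/GP5 as malignant and
    benign/stroma as non-malignant.
    """
    if len(gt) != len(pred):
        raise ValueError("label vectors must have equal length")
    gt = list(gt)
    pred = list(pred)
    present = [c for c in CLASS_NAMES if c in gt or c in pred]
    absent = [c for c in CLASS_NAMES if c not in present]
    if absent:
        warnings.warn(f"classes absent from gt and pred excluded: {absent}",
                      stacklevel=2)
    rows = {}
    for cls in present:
        tp = sum(g == cls and p == cls for g, p in zip(gt, pred))
        fp = sum(g != cls and p == cls for g, p in zip(gt, pred))
        fn = sum(g == cls and p != cls for g, p in zip(gt, pred))
        precision = _safe_div(tp, tp + fp)
        sensitivity = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity)
        rows[cls] = {"precision": precision, "sensitivity": sensitivity, "f1": f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    macro_f1 = float(per_class["f1"].mean())

    gt_bin = [g in MALIGNANT_CLASSES for g in gt]
    pred_bin = [p in MALIGNANT_CLASSES for p in pred]
    tp = sum(g and p for g, p in zip(gt_bin, pred_bin))
    tn = sum(not g and not p for g, p in zip(gt_bin, pred_bin))
    fp = sum(not g and p for g, p in zip(gt_bin, pred_bin))
    fn = sum(g and not p for g, p in zip(gt_bin, pred_bin))
    binary = {
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "ppv": _safe_div(tp, tp + fp),
        "npv": _safe_div(tn, tn + fn),
    }
    return MetricTable(per_class=per_class, macro_f1=macro_f1, binary=binary)


def slide_gleason(pred_raster: np.ndarray,
                  secondary_min_fraction: float = 0.05) -> GradeGroup:
    """Derive the slide-level Gleason score from predicted areas.

    Primary pattern = malignant pattern with the largest pixel area;
    secondary = next largest pattern whose area reaches
    ``secondary_min_fraction`` of the total malignant area, else the
    primary is doubled.  No malignant pixels -> Grade Group ``None``.
    """
    areas = {
        p: int((pred_raster == CLASS_CODES[f"GP{p}"]).sum()) for p in (3, 4, 5)
    }
    total = sum(areas.values())
    if total == 0:
        return GradeGroup(None, None)
    ranked = sorted(areas.items(), key=lambda kv: (-kv[1], -kv[0]))
    primary = ranked[0][0]
    secondary = primary
    for pattern, area in ranked[1:]:
        if area >= secondary_min_fraction * total and area > 0:
            secondary = pattern
            break
    return GradeGroup(primary, secondary)


def quadratic_weighted_kappa(labels_a: Sequence[int], labels_b: Sequence[int],
                             k: int) -> float:
    """Chance-corrected agreement with squared-distance penalties.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` where ``w_ij =
    (i - j)^2 / (k - 1)^2``, ``O`` is the observed joint proportion
    matrix and ``E`` the outer product of the two marginals.  Labels
    must lie in ``1..k``.  Degenerate marginals (both raters constant)
    with perfect agreement return 1.0.
    """
    if k < 2:
        raise ValueError("need at least 2 categories")
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("label vectors must have equal length >= 2")
    if a.min() < 1 or a.max() > k or b.min() < 1 or b.max() > k:
        raise ValueError("labels must be in 1..k")
    n = a.size
    observed = np.zeros((k, k))
    np.add.at(observed, (a - 1, b - 1), 1.0 / n)
    idx = np.arange(k)
    w = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    denom = float((w * expected).sum())
    numer = float((w * observed).sum())
    if denom == 0.0:
        return 1.0 if numer == 0.0 else 0.0
    return 1.0 - numer / denom


@dataclass
class TimingSummary:
    """Comparison of per-item times under two conditions."""

    mean_before: float
    mean_after: float
    fold_speedup: float  # mean_before / mean_after, 1 decimal
    percent_reduction: int  # 100 * (1 - after / before), nearest integer
    p_value: Optional[float] = None


def timing_summary(times_before: Sequence[float],
                   times_after: Sequence[float]) -> TimingSummary:
    """Summarize a timing comparison between two workflows.

    Fold speedup is reported to one decimal, percent reduction to the
    nearest integer, and a paired two-sided t-test p-value is included
    when the samples are paired (equal length >= 2).
    """
    before = np.asarray(times_before, dtype=float)
    after = np.asarray(times_after, dtype=float)
    if (before <= 0).any() or (after <= 0).any():
        raise ValueError("times must be positive")
    mean_b, mean_a = float(before.mean()), float(after.mean())
    p_value: Optional[float] = None
    if before.size == after.size and before.size >= 2:
        diffs = before - after
        # the paired t statistic is undefined for zero-variance differences
        if np.ptp(diffs) > 1e-12:
            p_value = float(stats.ttest_rel(before, after).pvalue)
    else:
        warnings.warn("unpaired samples: t-test p-value omitted", stacklevel=2)
    return TimingSummary(
        mean_before=mean_b,
        mean_after=mean_a,
        fold_speedup=round(mean_b / mean_a, 1),
        percent_reduction=int(round(100.0 * (1.0 - mean_a / mean_b))),
        p_value=p_value,
    )
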