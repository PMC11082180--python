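"""Slide-level inference: overlapping windows, vote fusion, simplification.

The patch classifier is slid over the tissue region with the training
stride, so most pixels are covered by several windows (9 at the slide
interior for stride = (side-1)/2 in 2-D).  Each window's class
probability vector is accumulated into every pixel it covers and its
argmax class receives one vote; fusion then labels each pixel either by
the most votes or by the highest mean score.

Ties are broken by higher mean score, then by clinical severity
(GP5 > GP4 > GP3 > benign > stroma): when the evidence is balanced we
prefer not to miss tumor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .geo import Annotation, label_raster_to_annotations
from .patches import PatchScale, enumerate_windows, resize_patch
from .types import CLASS_NAMES, SEVERITY_ORDER, LabeledImage

__all__ = ["ScoreAccumulator", "VotePolicy", "predict_slide", "vote",
           "simplify_prediction"]

#: Raster code for pixels not covered by any scored window.
UNSCORED = 0

_SEVERITY_IDX = [CLASS_NAMES.index(name) for name in SEVERITY_ORDER]


@dataclass
class ScoreAccumulator:
    """Running per-pixel evidence from overlapping windows."""

    scores: np.ndarray  # (H, W, 5) float64 probability sums
    votes: np.ndarray  # (H, W, 5) int32 argmax vote counts
    coverage: np.ndarray  # (H, W) int32 number of covering windows

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "ScoreAccumulator":
        h, w = shape
        k = len(CLASS_NAMES)
        return cls(
            scores=np.zeros((h, w, k)),
            votes=np.zeros((h, w, k), dtype=np.int32),
            coverage=np.zeros((h, w), dtype=np.int32),
        )

    def add_window(self, window: tuple[int, int, int, int],
                   proba: np.ndarray) -> None:
        r0, c0, r1, c1 = window
        self.scores[r0:r1, c0:c1] += proba
        self.votes[r0:r1, c0:c1, int(proba.argmax())] += 1
        self.coverage[r0:r1, c0:c1] += 1


@dataclass(frozen=True)
class VotePolicy:
    """How per-pixel evidence is fused into a single class.

    ``max_votes`` picks the class with the most window votes;
    ``max_mean_score`` the class with the highest average probability.
    The tie-break is total: higher mean score first, then the more
    severe class.
    """

    mode: str = "max_votes"

    def __post_init__(self) -> None:
        if self.mode not in ("max_votes", "max_mean_score"):
            raise ValueError(f"unknown vote mode {self.mode!r}")


def predict_slide(
    img: LabeledImage | np.ndarray,
    classifier,
    scale: Optional[PatchScale] = None,
    mask: Optional[np.ndarray] = None,
    min_tissue: float = 0.5,
) -> ScoreAccumulator:
    """Score every sliding window inside the tissue region.

    Windows are enumerated over the tissue bounding box; windows whose
    tissue fraction is below ``min_tissue`` are skipped.  The result is
    order-independent: each valid window is scored exactly once.
    """
    scale = scale or PatchScale()
    rgb = img.rgb if isinstance(img, LabeledImage) else np.asarray(img)
    if mask is None:
        if isinstance(img, LabeledImage) and img.tissue is not None:
            mask = img.tissue
        else:
            from .migration import tissue_mask
            mask = tissue_mask(rgb)
    if not mask.any():
        raise ValueError("empty tissue mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r_off, c_off = int(rows[0]), int(cols[0])
    extent = (int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))

    windows = [
        (r0 + r_off, c0 + c_off, r1 + r_off, c1 + c_off)
        for r0, c0, r1, c1 in enumerate_windows(extent, scale)
    ]
    area = scale.side * scale.side
    valid, crops = [], []
    for win in windows:
        r0, c0, r1, c1 = win
        if mask[r0:r1, c0:c1].sum() / area < min_tissue:
            continue
        valid.append(win)
        crops.append(resize_patch(rgb[r0:r1, c0:c1], scale.target_side))
    if not valid:
        raise ValueError("no window meets the tissue-fraction requirement")

    probas = classifier.predict_proba(crops)
    acc = ScoreAccumulator.empty(rgb.shape[:2])
    for win, proba in zip(valid, probas):
        acc.add_window(win, proba)
    return acc


def vote(acc: ScoreAccumulator, policy: Optional[VotePolicy] = None) -> np.ndarray:
    """Fuse accumulated evidence into a class-code label raster.

    Pixels with zero coverage get code 0 ("unscored").  Returned codes
    follow :data:`gleasonkit.types.CLASS_CODES` (class index + 1).
    """
    policy = policy or VotePolicy()
    covered = acc.coverage > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_scores = np.where(
            acc.coverage[..., None] > 0,
            acc.scores / np.maximum(acc.coverage, 1)[..., None],
            -1.0,
        )
    primary = acc.votes.astype(float) if policy.mode == "max_votes" else mean_scores

    best_idx = np.zeros(acc.coverage.shape, dtype=np.int64)
    best_primary = np.full(acc.coverage.shape, -np.inf)
    best_secondary = np.full(acc.coverage.shape, -np.inf)
    # scan classes in severity order: on full ties the first (most
    # severe) class is kept, implementing the documented tie-break
    for idx in _SEVERITY_IDX:
        p = primary[..., idx]
        s = mean_scores[..., idx]
        better = (p > best_primary) | ((p == best_primary) & (s > best_secondary))
        best_idx = np.where(better, idx, best_idx)
        best_primary = np.where(better, p, best_primary)
        best_secondary = np.where(better, s, best_secondary)

    labels = np.where(covered, best_idx + 1, UNSCORED).astype(np.uint8)
    return labels


def _merge_small_regions(labels: np.ndarray, min_region_area: int) -> np.ndarray:
    """Absorb regions below ``min_region_area`` into their largest
    bordering neighbor (by shared boundary length)."""
    out = labels.copy()
    changed = True
    while changed:
        changed = False
        comp = measure.label(out, connectivity=1, background=-1)
        for region in measure.regionprops(comp):
            if region.area >= min_region_area:
                continue
            mask = comp == region.label
            border = ndimage.binary_dilation(mask) & ~mask
            neighbor_vals = out[border]
            neighbor_vals = neighbor_vals[neighbor_vals != out[mask][0]]
            if neighbor_vals.size == 0:
                continue
            counts = np.bincount(neighbor_vals)
            out[mask] = counts.argmax()
            changed = True
    return out


def _majority_smooth(labels: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return labels
    footprint = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    footprint[yy**2 + xx**2 <= radius**2] = True
    values = np.unique(labels)
    counts = np.stack([
        ndimage.convolve((labels == v).astype(np.int32), footprint.astype(np.int32),
                         mode="nearest")
        for v in values
    ])
    return values[counts.argmax(axis=0)].astype(labels.dtype)


def simplify_prediction(
    labels: np.ndarray,
    min_region_area: int = 100,
    smoothing_radius: int = 2,
    max_iter: int = 10,
) -> tuple[np.ndarray, list[Annotation]]:
    """Simplify a predicted label raster for pathologist review.

    Small regions are merged into their dominant neighbor and region
    boundaries are smoothed by circular majority filtering; the two
    steps are iterated to a fixed point, so a second simplification pass
    changes nothing.  Returns the simplified raster and its traced
    polygon annotations.
    """
    out = np.asarray(labels, dtype=np.uint8).copy()
    for _ in range(max_iter):
        prev = out
        out = _majority_smooth(prev, smoothing_radius)
        out = _merge_small_regions(out, min_region_area)
        if np.array_equal(out, prev):
            break
    polygons = label_raster_to_annotations(out, min_area=0)
    return out, polygons
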