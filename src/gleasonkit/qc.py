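"""Automated tile quality control for scanned histology images.

Tiles an image into non-overlapping windows and scores each tile on the
five common whole-slide-image quality issues — out of focus, low
contrast, saturation, artifacts and texture uniformity.  A tile is
"low quality" when two or more issues are flagged; slide-level
summaries report the low-quality tile percentage over tissue tiles.

Score definitions (all computed over tissue pixels only):

* ``focus`` — variance of the 3x3 Laplacian divided by the grayscale
  variance.  The normalization cancels global contrast scaling, so the
  score responds to blur rather than to stain intensity; it decreases
  monotonically with Gaussian blur sigma.
* ``contrast`` — (P95 - P5) of grayscale intensities, divided by 255.
* ``saturation`` — fraction of pixels with any channel >= 250 or all
  channels <= 5 (clipped highlights / shadows).
* ``artifact`` — fraction of pixels outside a robust H&E color
  envelope (very dark pixels, or saturated hues in the green-cyan band:
  pen ink, dust and fold shadows rather than hematoxylin/eosin).
* ``uniformity`` — coefficient of variation of local (32 px block)
  grayscale variance; a near-zero value means pathologically flat
  texture, as produced by scan faults.

Default thresholds were calibrated once on the seeded synthetic tile
suite (``synthetic.make_qc_tile_suite``) and shipped here; every
threshold is overridable via :class:`QcThresholds` or a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv

__all__ = [
    "QcThresholds",
    "TileRecord",
    "SlideQualitySummary",
    "tile_image",
    "compute_quality_metrics",
    "classify_tile_quality",
    "summarize_slide_quality",
    "run_qc",
]

QC_ISSUES = ("focus", "contrast", "saturation", "artifact", "uniformity")


@dataclass
class QcThresholds:
    """Decision thresholds for the five quality issues.

    ``focus_min`` and ``contrast_min`` flag when the score falls *below*
    the threshold; ``saturation_max`` and ``artifact_max`` flag when the
    affected-pixel fraction *exceeds* it; ``uniformity_min`` flags when
    the block-variance coefficient of variation falls below it (too-flat
    texture).  A tile is low quality when at least
    ``issue_count_for_low_quality`` issues are flagged.
    """

    focus_min: float = 0.05
    contrast_min: float = 0.12
    saturation_max: float = 0.05
    artifact_max: float = 0.04
    uniformity_min: float = 0.10
    tile_side: int = 512
    tissue_fraction_min: float = 0.1
    issue_count_for_low_quality: int = 2

    def __post_init__(self) -> None:
        if self.issue_count_for_low_quality < 1:
            raise ValueError("issue_count_for_low_quality must be >= 1")
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite")


@dataclass
class TileRecord:
    """Per-tile QC outcome: position, five scores, five flags, verdict."""

    row: int
    col: int
    tissue_fraction: float
    scores: dict[str, float]
    flags: dict[str, bool]
    low_quality: bool = False


@dataclass
class SlideQualitySummary:
    tile_count: int
    low_quality_count: int

    @property
    def low_quality_percentage(self) -> float:
        return 100.0 * self.low_quality_count / self.tile_count


def tile_image(img: np.ndarray, tile_side: int,
               drop_partial: bool = True) -> list[tuple[int, int, np.ndarray]]:
    """Split an image into non-overlapping tiles.

    Returns ``(row, col, tile)`` triples with top-left pixel coordinates.
    Partial edge tiles are dropped by default; with ``drop_partial=False``
    they are padded to ``tile_side`` by edge replication.
    """
    if tile_side < 32:
        raise ValueError("tile_side must be >= 32")
    h, w = img.shape[:2]
    if h < tile_side or w < tile_side:
        raise ValueError("image smaller than one tile")
    tiles = []
    stops_r = range(0, h - tile_side + 1, tile_side) if drop_partial else range(0, h, tile_side)
    stops_c = range(0, w - tile_side + 1, tile_side) if drop_partial else range(0, w, tile_side)
    for r in stops_r:
        for c in stops_c:
            tile = img[r : r + tile_side, c : c + tile_side]
            if tile.shape[0] < tile_side or tile.shape[1] < tile_side:
                pad = ((0, tile_side - tile.shape[0]), (0, tile_side - tile.shape[1]))
                if tile.ndim == 3:
                    pad = pad + ((0, 0),)
                tile = np.pad(tile, pad, mode="edge")
            tiles.append((r, c, tile))
    return tiles


def _tissue_mask_simple(rgb: np.ndarray) -> np.ndarray:
    """Bright, unsaturated pixels are background; the rest is tissue."""
    v = rgb.astype(float)
    bright = v.min(axis=-1) >= 235
    spread = v.max(axis=-1) - v.min(axis=-1)
    return ~(bright & (spread <= 20))


def _block_variances(gray: np.ndarray, block: int = 32) -> np.ndarray:
    h, w = gray.shape
    nh, nw = h // block, w // block
    if nh == 0 or nw == 0:
        return np.array([gray.var()])
    trimmed = gray[: nh * block, : nw * block]
    blocks = trimmed.reshape(nh, block, nw, block).transpose(0, 2, 1, 3)
    return blocks.reshape(nh * nw, block * block).var(axis=1)


def compute_quality_metrics(
    tile: np.ndarray,
    thresholds: Optional[QcThresholds] = None,
    row: int = 0,
    col: int = 0,
    tissue: Optional[np.ndarray] = None,
) -> Optional[TileRecord]:
    """Score one RGB tile on the five quality issues.

    Returns ``None`` for background tiles (tissue fraction at or below
    ``thresholds.tissue_fraction_min``), which are excluded from slide
    summaries.  All statistics are invariant to 90-degree rotations and
    flips of the tile.
    """
    thresholds = thresholds or QcThresholds()
    tile = np.asarray(tile)
    if tissue is None:
        tissue = _tissue_mask_simple(tile)
    tissue_fraction = float(tissue.mean())
    if tissue_fraction <= thresholds.tissue_fraction_min:
        return None

    gray = tile.astype(float).mean(axis=-1)
    gray_t = gray[tissue]
    var_gray = float(gray_t.var())

    lap = ndimage.laplace(gray)
    if var_gray < 1e-3:
        focus = 0.0
    else:
        focus = float(lap[tissue].var() / var_gray)

    p5, p95 = np.percentile(gray_t, [5, 95])
    contrast = float((p95 - p5) / 255.0)

    v = tile.astype(float)
    clipped_hi = (v >= 250).any(axis=-1)
    clipped_lo = (v <= 5).all(axis=-1)
    clipped = clipped_hi | clipped_lo
    # clipped-white pixels are color-indistinguishable from glass and
    # fall out of the tissue mask, so count them back into the footprint
    footprint = tissue | clipped
    saturation = float(clipped.sum() / footprint.sum())

    hsv = rgb2hsv(tile)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    outside = (val < 0.25) | ((sat > 0.25) & (hue > 0.15) & (hue < 0.60))
    artifact = float(outside[tissue].mean())

    bvars = _block_variances(gray)
    mean_var = float(bvars.mean())
    uniformity = 0.0 if mean_var < 0.5 else float(bvars.std() / mean_var)

    scores = {
        "focus": focus,
        "contrast": contrast,
        "saturation": saturation,
        "artifact": artifact,
        "uniformity": uniformity,
    }
    flags = {
        "focus": focus < thresholds.focus_min,
        "contrast": contrast < thresholds.contrast_min,
        "saturation": saturation > thresholds.saturation_max,
        "artifact": artifact > thresholds.artifact_max,
        "uniformity": uniformity < thresholds.uniformity_min,
    }
    record = TileRecord(row=row, col=col, tissue_fraction=tissue_fraction,
                        scores=scores, flags=flags)
    record.low_quality = classify_tile_quality(record, thresholds)
    return record


def classify_tile_quality(record: TileRecord, thresholds: QcThresholds) -> bool:
    """A tile is low quality iff it has >= the configured issue count."""
    return sum(record.flags.values()) >= thresholds.issue_count_for_low_quality


def summarize_slide_quality(records: Iterable[TileRecord]) -> SlideQualitySummary:
    records = list(records)
    if not records:
        raise ValueError("no tissue tiles to summarize (all background?)")
    low = sum(r.low_quality for r in records)
    return SlideQualitySummary(tile_count=len(records), low_quality_count=low)


def run_qc(img: np.ndarray, thresholds: Optional[QcThresholds] = None,
           drop_partial: bool = True):
    """Tile an image, score every tissue tile and summarize.

    Returns ``(records, summary)``; background tiles are skipped.
    """
    thresholds = thresholds or QcThresholds()
    records = []
    for r, c, tile in tile_image(img, thresholds.tile_side, drop_partial):
        record = compute_quality_metrics(tile, thresholds, row=r, col=c)
        if record is not None:
            records.append(record)
    return records, summarize_slide_quality(records)


def records_to_frame(records: Iterable[TileRecord]) -> pd.DataFrame:
    """Flatten tile records into a stable-schema table for CSV export."""
    rows = []
    for rec in records:
        row = {"row": rec.row, "col": rec.col,
               "tissue_fraction": rec.tissue_fraction}
        row.update({f"score_{k}": v for k, v in rec.scores.items()})
        row.update({f"flag_{k}": v for k, v in rec.flags.items()})
        row["low_quality"] = rec.low_quality
        rows.append(row)
    return pd.DataFrame(rows)
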