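"""Scanner appearance migration by per-channel PDF matching.

Different slide scanners render the same tissue with systematically
different color: some darker, some lighter, with channel-specific gamma.
To make a model trained on one scanner usable on others, images are
migrated into the reference color space: a reference probability
density function (PDF) is estimated per RGB channel over tissue pixels
of a reference image set, and each incoming image's tissue intensity
distribution is mapped onto it with the monotone transform
``T = invCDF_ref o CDF_source`` (classical histogram specification).

The PDF is estimated from tissue pixels only, but the transform is
applied to all pixels: background stays visually background while
avoiding seams at the tissue boundary.

Diagnostics mirror common practice: per-channel histogram intersection
against the reference (1.0 = identical distributions) and per-image
tissue mean-RGB cluster compactness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage import morphology

from .types import LabeledImage

__all__ = [
    "TissueMaskParams",
    "ReferencePDF",
    "tissue_mask",
    "estimate_reference_pdf",
    "migrate_image",
    "histogram_intersection",
    "channel_mean_summary",
]


@dataclass
class TissueMaskParams:
    """Background separation: bright and unsaturated pixels are glass.

    ``background_value_min`` is the minimum channel intensity for a
    pixel to count as bright; ``background_saturation_max`` bounds the
    channel spread (relative to 255) of background pixels; connected
    tissue specks below ``min_object_area`` pixels are discarded.
    """

    background_value_min: int = 235
    background_saturation_max: float = 0.08
    min_object_area: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.background_value_min <= 255:
            raise ValueError("background_value_min outside [0, 255]")
        if not 0.0 <= self.background_saturation_max <= 1.0:
            raise ValueError("background_saturation_max outside [0, 1]")


@dataclass
class ReferencePDF:
    """Per-channel 256-bin intensity PDF over tissue pixels.

    Bin index equals the 8-bit intensity value.  The PDF is the average
    of per-image normalized histograms (not a pooled-pixel histogram),
    so reference images with unequal tissue areas contribute equally.
    """

    pdf: np.ndarray  # (3, 256), rows sum to 1
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pdf = np.asarray(self.pdf, dtype=float)
        if pdf.shape != (3, 256):
            raise ValueError("pdf must have shape (3, 256)")
        if (pdf < 0).any():
            raise ValueError("pdf must be non-negative")
        sums = pdf.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each channel PDF must sum to 1")
        self.pdf = pdf

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pdf, axis=1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "pdf": self.pdf.tolist(), "provenance": self.provenance,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferencePDF":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["pdf"]), payload.get("provenance", []))


def tissue_mask(img: LabeledImage | np.ndarray,
                params: Optional[TissueMaskParams] = None) -> np.ndarray:
    """Binary tissue mask: excludes bright unsaturated background."""
    params = params or TissueMaskParams()
    rgb = img.rgb if isinstance(img, LabeledImage) else np.asarray(img)
    v = rgb.astype(float)
    bright = v.min(axis=-1) >= params.background_value_min
    spread = (v.max(axis=-1) - v.min(axis=-1)) / 255.0
    mask = ~(bright & (spread <= params.background_saturation_max))
    if params.min_object_area > 1 and mask.any():
        mask = morphology.remove_small_objects(mask, max_size=params.min_object_area - 1)
    return mask


def _channel_histograms(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(3, 256) normalized tissue-pixel histograms of one image."""
    pix = rgb[mask]
    if pix.size == 0:
        raise ValueError("empty tissue mask")
    hists = np.stack([
        np.bincount(pix[:, c], minlength=256).astype(float) for c in range(3)
    ])
    return hists / hists.sum(axis=1, keepdims=True)


def estimate_reference_pdf(
    images: Sequence[LabeledImage | np.ndarray],
    masks: Optional[Sequence[np.ndarray]] = None,
    ids: Optional[Sequence[str]] = None,
) -> ReferencePDF:
    """Average per-image tissue histograms into a reference PDF."""
    if masks is None:
        masks = [tissue_mask(img) for img in images]
    per_image = []
    for img, mask in zip(images, masks):
        rgb = img.rgb if isinstance(img, LabeledImage) else np.asarray(img)
        if not mask.any():
            continue
        per_image.append(_channel_histograms(rgb, mask))
    if not per_image:
        raise ValueError("all tissue masks are empty")
    pdf = np.mean(per_image, axis=0)
    provenance = list(ids) if ids is not None else [str(i) for i in range(len(per_image))]
    return ReferencePDF(pdf, provenance)


def _matching_lut(source_pdf_1ch: np.ndarray, ref_pdf_1ch: np.ndarray) -> np.ndarray:
    """256-entry monotone lookup table mapping source onto reference.

    For each intensity v, T(v) is the reference intensity whose CDF
    first reaches CDF_source(v), with linear interpolation on the
    inverse CDF and ties broken toward the lowest intensity.
    """
    cdf_s = np.cumsum(source_pdf_1ch)
    cdf_r = np.cumsum(ref_pdf_1ch)
    # keep first occurrence of each CDF plateau -> lowest-intensity ties
    values = np.arange(256, dtype=float)
    keep = np.concatenate([[True], np.diff(cdf_r) > 1e-12])
    lut = np.interp(cdf_s, cdf_r[keep], values[keep])
    return np.clip(np.rint(lut), 0, 255).astype(np.uint8)


def migrate_image(
    img: LabeledImage | np.ndarray,
    ref: ReferencePDF,
    mask: Optional[np.ndarray] = None,
) -> LabeledImage:
    """Map an image's tissue intensity distribution onto the reference.

    The per-channel transform is monotone non-decreasing, estimated from
    tissue pixels and applied to every pixel; labels and tissue mask are
    untouched.  A constant (degenerate) source channel is shifted so it
    lands on the reference median, with a warning.
    """
    src = img if isinstance(img, LabeledImage) else LabeledImage(rgb=np.asarray(img))
    if mask is None:
        # prefer the image's own tissue mask: keeps repeated migrations
        # consistent even when the color transform moves the background
        mask = src.tissue if src.tissue is not None else tissue_mask(src)
    if not mask.any():
        raise ValueError("empty tissue mask: nothing to match")
    src_pdf = _channel_histograms(src.rgb, mask)
    out = np.empty_like(src.rgb)
    for c in range(3):
        nonzero = np.flatnonzero(src_pdf[c])
        if nonzero.size == 1:
            const = int(nonzero[0])
            cdf_r = np.cumsum(ref.pdf[c])
            median = int(np.searchsorted(cdf_r, 0.5))
            warnings.warn(
                f"channel {c} is constant ({const}); shifting to reference "
                f"median {median}", stacklevel=2,
            )
            shift = median - const
            lut = np.clip(np.arange(256) + shift, 0, 255).astype(np.uint8)
        else:
            lut = _matching_lut(src_pdf[c], ref.pdf[c])
        out[..., c] = lut[src.rgb[..., c]]
    return LabeledImage(rgb=out, labels=src.labels, tissue=src.tissue,
                        meta={**src.meta, "migrated": True})


def histogram_intersection(
    pdf_a: ReferencePDF | np.ndarray, pdf_b: ReferencePDF | np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-channel sum of bin-wise minima, plus the channel mean.

    1.0 means identical distributions; 0.0 means disjoint supports.
    Symmetric in its arguments.
    """
    a = pdf_a.pdf if isinstance(pdf_a, ReferencePDF) else np.atleast_2d(np.asarray(pdf_a, float))
    b = pdf_b.pdf if isinstance(pdf_b, ReferencePDF) else np.atleast_2d(np.asarray(pdf_b, float))
    per_channel = np.minimum(a, b).sum(axis=1)
    return per_channel, float(per_channel.mean())


def image_pdf(img: LabeledImage | np.ndarray,
              mask: Optional[np.ndarray] = None) -> np.ndarray:
    """(3, 256) tissue-pixel PDF of a single image."""
    rgb = img.rgb if isinstance(img, LabeledImage) else np.asarray(img)
    if mask is None:
        mask = tissue_mask(rgb)
    return _channel_histograms(rgb, mask)


def channel_mean_summary(
    images: Sequence[LabeledImage | np.ndarray],
    masks: Optional[Sequence[np.ndarray]] = None,
) -> tuple[np.ndarray, float]:
    """Per-image tissue mean RGB and cluster compactness.

    Compactness is the mean pairwise Euclidean distance between the
    per-image mean-RGB points; tight clusters (uniform appearance)
    give small values.  Invariant to image order.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if masks is None:
        masks = [tissue_mask(img) for img in images]
    means = []
    for img, mask in zip(images, masks):
        rgb = img.rgb if isinstance(img, LabeledImage) else np.asarray(img)
        means.append(rgb[mask].mean(axis=0))
    means = np.asarray(means)
    diffs = means[:, None, :] - means[None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=-1))
    n = len(means)
    compactness = float(dists[np.triu_indices(n, k=1)].mean())
    return means, compactness
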