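"""Annotation-driven patch extraction, augmentation and class weighting.

Training patches are cut from annotated regions with a sliding window of
side ``x`` and stride ``(x - 1) / 2``, giving adjacent windows an
overlap ratio of ``(x + 1) / (2x)``.  A window becomes a labeled patch
only when a single class covers more than 70% of its area; patches are
then resized to 224 x 224 for the classifier input, which sets the
effective sampling resolution to ``x * scan_resolution / 224`` µm/pixel
(1.12 µm/pixel for x = 501 scanned at 0.5 µm/pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from PIL import Image

from .geo import Annotation, rasterize_annotations
from .types import CLASS_CODES, CLASS_NAMES, CODE_NAMES, LabeledImage

__all__ = [
    "PatchScale",
    "LabeledPatch",
    "AugmentationConfig",
    "AUGMENTATION_PRESETS",
    "enumerate_windows",
    "extract_patches",
    "effective_resolution",
    "augment_patch",
    "compute_class_weights",
    "resize_patch",
]


@dataclass(frozen=True)
class PatchScale:
    """Sliding-window geometry for one patch scale.

    ``side`` must be odd so the stride ``(side - 1) / 2`` is integral;
    the canonical scales are 251, 501, 1001 and 2001 pixels.
    """

    side: int = 501
    coverage_min: float = 0.70
    target_side: int = 224
    scan_resolution: float = 0.5  # µm/pixel of the source scan

    def __post_init__(self) -> None:
        if self.side < 3 or self.side % 2 == 0:
            raise ValueError("side must be odd and >= 3 so stride=(side-1)/2 is integral")
        if not 0.0 < self.coverage_min < 1.0:
            raise ValueError("coverage_min must be in (0, 1)")

    @property
    def stride(self) -> int:
        return (self.side - 1) // 2

    @property
    def overlap_ratio(self) -> float:
        """Overlap between adjacent windows: (side + 1) / (2 * side)."""
        return (self.side + 1) / (2 * self.side)

    @property
    def resolution(self) -> float:
        return effective_resolution(self.side, self.scan_resolution, self.target_side)


@dataclass
class LabeledPatch:
    """A resized training patch with its class label and provenance."""

    pixels: np.ndarray  # (target_side, target_side, 3) uint8
    label: str
    window: tuple[int, int, int, int]  # (row0, col0, row1, col1)
    coverage: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in CLASS_CODES:
            raise ValueError(f"label {self.label!r} outside the class vocabulary")


def effective_resolution(side: int, scan_resolution: float = 0.5,
                         target_side: int = 224) -> float:
    """Sampling resolution (µm/pixel) of a patch after resizing.

    A window of ``side`` source pixels at ``scan_resolution`` µm/pixel
    resized to ``target_side`` pixels samples the tissue at
    ``side * scan_resolution / target_side`` µm/pixel, reported rounded
    to two decimals (e.g. 501 px at 0.5 µm/pixel -> 1.12).
    """
    if side <= 0 or scan_resolution <= 0 or target_side <= 0:
        raise ValueError("all arguments must be positive")
    return round(side * scan_resolution / target_side, 2)


def enumerate_windows(extent: tuple[int, int] | int,
                      scale: PatchScale) -> list[tuple[int, int, int, int]]:
    """All sliding windows fully inside ``extent``.

    Windows are half-open ``(row0, col0, row1, col1)`` in 0-based pixel
    coordinates, starting at 0 with step ``scale.stride``.  An extent
    smaller than one window yields an empty list with a warning.
    """
    if isinstance(extent, int):
        extent = (extent, extent)
    h, w = extent
    if h < scale.side or w < scale.side:
        warnings.warn(f"extent {extent} smaller than window side {scale.side}",
                      stacklevel=2)
        return []
    rows = range(0, h - scale.side + 1, scale.stride)
    cols = range(0, w - scale.side + 1, scale.stride)
    return [(r, c, r + scale.side, c + scale.side) for r in rows for c in cols]


def resize_patch(pixels: np.ndarray, target_side: int) -> np.ndarray:
    """Deterministic area-averaging (box filter) resize to a square."""
    if pixels.shape[0] == target_side and pixels.shape[1] == target_side:
        return np.ascontiguousarray(pixels)
    im = Image.fromarray(pixels)
    out = im.resize((target_side, target_side), resample=Image.Resampling.BOX)
    return np.asarray(out)


def extract_patches(
    img: LabeledImage | np.ndarray,
    annotations: Sequence[Annotation] | np.ndarray,
    scale: Optional[PatchScale] = None,
    image_id: str = "",
) -> list[LabeledPatch]:
    """Cut labeled patches from annotated regions of an image.

    A window yields a patch iff one class's annotated area covers more
    than ``scale.coverage_min`` of the window; the patch takes that
    class's label.  Windows with high total but mixed-class coverage are
    ambiguous and are skipped.  Extraction is deterministic and
    independent of annotation ordering.
    """
    scale = scale or PatchScale()
    rgb = img.rgb if isinstance(img, LabeledImage) else np.asarray(img)
    if isinstance(annotations, np.ndarray):
        label_raster = annotations
    else:
        label_raster = rasterize_annotations(annotations, rgb.shape[:2])
    windows = enumerate_windows(rgb.shape[:2], scale)
    area = scale.side * scale.side
    patches: list[LabeledPatch] = []
    for r0, c0, r1, c1 in windows:
        sub = label_raster[r0:r1, c0:c1]
        counts = np.bincount(sub.ravel(), minlength=6)
        best_code = int(counts[1:].argmax()) + 1
        coverage = counts[best_code] / area
        if coverage <= scale.coverage_min:
            continue
        pixels = resize_patch(rgb[r0:r1, c0:c1], scale.target_side)
        patches.append(LabeledPatch(
            pixels=pixels, label=CODE_NAMES[best_code],
            window=(r0, c0, r1, c1), coverage=float(coverage),
            image_id=image_id,
        ))
    return patches


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentationConfig:
    """Geometric and color augmentation settings.

    Geometric ops are exact 90-degree rotations and flips (no
    interpolation).  Color jitter applies a random per-channel
    gain/offset/gamma transform drawn uniformly from the configured
    ranges; the scanner presets bias the draw dark (B, C) or light (D)
    to emulate the corresponding scanner's appearance.
    """

    rotations: tuple[int, ...] = (0,)
    flip: bool = False
    gain_range: Optional[tuple[float, float]] = None
    offset_range: Optional[tuple[float, float]] = None
    gamma_range: Optional[tuple[float, float]] = None
    preset: str = "none"
    seed: int = 0


AUGMENTATION_PRESETS: dict[str, AugmentationConfig] = {
    "none": AugmentationConfig(preset="none"),
    "geometric": AugmentationConfig(rotations=(0, 90, 180, 270), flip=True,
                                    preset="geometric"),
    # darker scanners: gain < 1, negative offsets, gamma > 1
    "scannerB": AugmentationConfig(
        rotations=(0, 90, 180, 270), flip=True,
        gain_range=(0.92, 1.0), offset_range=(-20.0, -5.0),
        gamma_range=(1.0, 1.08), preset="scannerB",
    ),
    "scannerC": AugmentationConfig(
        rotations=(0, 90, 180, 270), flip=True,
        gain_range=(0.90, 0.98), offset_range=(-25.0, -8.0),
        gamma_range=(1.02, 1.12), preset="scannerC",
    ),
    # lighter scanner: gain > 1, positive offsets, gamma < 1
    "scannerD": AugmentationConfig(
        rotations=(0, 90, 180, 270), flip=True,
        gain_range=(1.0, 1.08), offset_range=(5.0, 20.0),
        gamma_range=(0.92, 1.0), preset="scannerD",
    ),
}


def _jitter(pixels: np.ndarray, cfg: AugmentationConfig,
            rng: np.random.Generator) -> np.ndarray:
    if cfg.gain_range is None and cfg.offset_range is None and cfg.gamma_range is None:
        return pixels
    gain = rng.uniform(*(cfg.gain_range or (1.0, 1.0)), size=3)
    offset = rng.uniform(*(cfg.offset_range or (0.0, 0.0)), size=3)
    gamma = rng.uniform(*(cfg.gamma_range or (1.0, 1.0)), size=3)
    v = pixels.astype(float) / 255.0
    out = gain * (v**gamma) * 255.0 + offset
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_patch(patch: LabeledPatch,
                  cfg: AugmentationConfig) -> list[LabeledPatch]:
    """Expand one patch into its augmented variants.

    Output order is deterministic (rotations then flips), color jitter
    is drawn from ``cfg.seed``, and labels are preserved.  The identity
    preset returns the input patch unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    variants: list[LabeledPatch] = []
    for rot in cfg.rotations:
        if rot % 90 != 0:
            raise ValueError("rotations must be multiples of 90 degrees")
        base = np.rot90(patch.pixels, k=(rot // 90) % 4)
        geoms = [base, base[:, ::-1]] if cfg.flip else [base]
        for g in geoms:
            pixels = _jitter(np.ascontiguousarray(g), cfg, rng)
            variants.append(LabeledPatch(
                pixels=pixels, label=patch.label, window=patch.window,
                coverage=patch.coverage, image_id=patch.image_id,
            ))
    return variants


def compute_class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency class weights, normalized to mean 1.

    ``w_i = (1 / count_i) * K / sum_j (1 / count_j)`` over the K classes
    with positive counts; zero-count classes are excluded with a
    warning.  Doubling every count leaves the weights unchanged.
    """
    positive = {k: v for k, v in counts.items() if v > 0}
    if not positive:
        raise ValueError("all class counts are zero")
    dropped = set(counts) - set(positive)
    if dropped:
        warnings.warn(f"classes with zero patches excluded: {sorted(dropped)}",
                      stacklevel=2)
    inv = {k: 1.0 / v for k, v in positive.items()}
    norm = len(inv) / sum(inv.values())
    return {k: v * norm for k, v in inv.items()}
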