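"""Shared domain types and class-code conventions.

Label rasters are single-channel ``uint8`` arrays using the codes in
:data:`CLASS_CODES`; code 0 means "unlabeled / background".  The five
tissue classes follow the standard prostate-histology vocabulary:
Gleason pattern 3/4/5 (``GP3``/``GP4``/``GP5``), ``benign`` glandular
tissue and ``stroma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Raster code for pixels carrying no class label.
UNLABELED = 0

#: Class name -> raster code.  Code 0 is reserved for unlabeled pixels.
CLASS_CODES: dict[str, int] = {
    "stroma": 1,
    "benign": 2,
    "GP3": 3,
    "GP4": 4,
    "GP5": 5,
}

#: Raster code -> class name.
CODE_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

#: The fixed five-class vocabulary, in raster-code order.
CLASS_NAMES: tuple[str, ...] = ("stroma", "benign", "GP3", "GP4", "GP5")

#: Clinical severity, most severe first.  Used for deterministic
#: tie-breaking: when two classes are otherwise tied we prefer the more
#: severe call so that tumor is not silently dropped.
SEVERITY_ORDER: tuple[str, ...] = ("GP5", "GP4", "GP3", "benign", "stroma")

#: Malignant subset for binary (malignant vs non-malignant) grouping.
MALIGNANT_CLASSES: frozenset[str] = frozenset({"GP3", "GP4", "GP5"})


def severity_rank(name: str) -> int:
    """Rank of ``name`` in the severity order (0 = most severe)."""
    return SEVERITY_ORDER.index(name)


@dataclass
class LabeledImage:
    """An RGB raster with an optional per-pixel class-label raster.

    Parameters
    ----------
    rgb
        ``(H, W, 3) uint8`` image.
    labels
        Optional ``(H, W) uint8`` raster of :data:`CLASS_CODES` values;
        0 marks unlabeled pixels.
    tissue
        Optional ``(H, W) bool`` tissue mask.
    """

    rgb: np.ndarray
    labels: Optional[np.ndarray] = None
    tissue: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError(f"rgb must be (H, W, 3), got {rgb.shape}")
        if rgb.dtype != np.uint8:
            rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
        self.rgb = rgb
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != rgb.shape[:2]:
                raise ValueError("labels shape must match rgb")
            self.labels = labels.astype(np.uint8)
        if self.tissue is not None:
            tissue = np.asarray(self.tissue)
            if tissue.shape != rgb.shape[:2]:
                raise ValueError("tissue mask shape must match rgb")
            self.tissue = tissue.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]
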