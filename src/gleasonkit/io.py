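"""Raster file IO: RGB images and class-code label rasters.

Label rasters are written as single-channel PNG holding the class codes
from :data:`gleasonkit.types.CLASS_CODES` (0 = unlabeled/background).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .types import LabeledImage


def write_image(rgb: np.ndarray | LabeledImage, path: str | Path) -> None:
    if isinstance(rgb, LabeledImage):
        rgb = rgb.rgb
    Image.fromarray(np.asarray(rgb)).save(str(path))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)).convert("RGB"))


def write_label_raster(labels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(labels.astype(np.uint8), mode="L").save(str(path))


def read_label_raster(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)).convert("L"))
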