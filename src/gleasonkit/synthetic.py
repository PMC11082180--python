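"""Seeded tissue-like image fixtures.

Generates H&E-look RGB images with exhaustive per-pixel class labels,
scanner-style color shifts, controlled quality degradations and partial
polygon annotations, so the whole pipeline is testable without any
slide downloads.  Textures are procedural: they only need to be
*separable* by a simple patch classifier and to exercise the quality
metrics, not to look like real prostate histology.

Per-class motifs:

* ``benign`` — ring/gland motifs (dark ring, pale lumen),
* ``GP3``    — small well-separated dark discs,
* ``GP4``    — fused irregular blobs,
* ``GP5``    — diffuse fine speckle,
* ``stroma`` — smooth low-frequency pink field,
* background — near-white with slight noise.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .geo import Annotation, mask_to_polygons
from .types import CLASS_CODES, CLASS_NAMES, CODE_NAMES, LabeledImage

__all__ = [
    "TissueLayoutSpec",
    "ScannerStyle",
    "DegradationSpec",
    "generate_tissue_image",
    "apply_scanner_style",
    "apply_degradation",
    "generate_annotation_set",
    "SCANNER_STYLES",
    "varied_tissue_spec",
    "make_qc_tile_suite",
    "make_quality_slide",
]

#: Base colors per class, chosen in the purple/pink H&E palette.
_BASE_COLORS = {
    "background": (244, 243, 244),
    "stroma": (228, 180, 199),
    "benign": (216, 180, 219),
    "GP3": (229, 197, 221),
    "GP4": (206, 162, 201),
    "GP5": (212, 172, 206),
}
_MOTIF_COLORS = {
    "benign": (128, 68, 148),
    "GP3": (113, 54, 133),
    "GP4": (136, 76, 152),
    "GP5": (99, 46, 124),
}

DEGRADATION_KINDS = ("blur", "low_contrast", "saturation_clip", "artifact", "uniform_patch")


@dataclass
class TissueLayoutSpec:
    """Layout of a synthetic labeled tissue image.

    ``class_fractions`` maps each of the five tissue classes to its
    target area fraction; together with ``background_fraction`` they
    must sum to 1.  Realized fractions land within ±5 percentage points
    of the targets (in practice within one layout cell).
    """

    image_side: int = 512
    cell_side: Optional[int] = None  # layout granularity; None = image_side/16
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "stroma": 0.30,
            "benign": 0.20,
            "GP3": 0.20,
            "GP4": 0.15,
            "GP5": 0.05,
        }
    )
    background_fraction: float = 0.10
    texture_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 64:
            raise ValueError("image_side must be >= 64")
        if self.cell_side is not None and not 8 <= self.cell_side <= self.image_side:
            raise ValueError("cell_side must be in [8, image_side]")
        for name, frac in self.class_fractions.items():
            if name not in CLASS_CODES:
                raise ValueError(f"unknown class {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name} outside [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction outside [0, 1]")
        total = sum(self.class_fractions.values()) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


@dataclass
class ScannerStyle:
    """Global per-channel color transform emulating a scanner's look.

    Applied as ``v' = clip(gain * (v / 255) ** gamma * 255 + offset)``
    per channel; darker scanners use negative offsets / gamma > 1,
    lighter scanners the reverse.
    """

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = "custom"

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("gain must be positive")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("gamma must be positive")


#: Canonical scanner styles used throughout the test fixtures: the
#: identity baseline, two darker scanners and one lighter scanner.
SCANNER_STYLES: dict[str, ScannerStyle] = {
    "baseline": ScannerStyle(name="baseline"),
    # darker scanners: offset-dominant shifts with mild gamma
    "scannerB": ScannerStyle(
        gain=(1.0, 1.0, 1.0), offset=(-18.0, -12.0, -15.0),
        gamma=(1.02, 1.03, 1.02), name="scannerB",
    ),
    "scannerC": ScannerStyle(
        gain=(0.99, 0.98, 0.99), offset=(-28.0, -22.0, -25.0),
        gamma=(1.04, 1.05, 1.03), name="scannerC",
    ),
    # lighter scanner: positive offsets kept small enough that
    # highlights stay below the clipping range
    "scannerD": ScannerStyle(
        gain=(1.0, 1.0, 1.0), offset=(8.0, 10.0, 7.0),
        gamma=(0.97, 0.96, 0.97), name="scannerD",
    ),
}


@dataclass
class DegradationSpec:
    """A controlled quality degradation.

    ``magnitude`` is kind-specific: Gaussian sigma for ``blur``,
    contrast scale factor in (0, 1] for ``low_contrast``, affected area
    fraction for ``saturation_clip`` and ``artifact``, and unused for
    ``uniform_patch`` (the region is flattened to its mean color).
    ``region`` restricts the effect to ``(row0, col0, row1, col1)``.
    """

    kind: str
    magnitude: float = 1.0
    region: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in DEGRADATION_KINDS:
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.kind == "blur" and not 0 < self.magnitude <= 20:
            raise ValueError("blur sigma must be in (0, 20]")
        if self.kind == "low_contrast" and not 0 < self.magnitude <= 1:
            raise ValueError("contrast scale must be in (0, 1]")
        if self.kind in ("saturation_clip", "artifact") and not 0 < self.magnitude <= 1:
            raise ValueError("area fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# texture rendering


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  cell: int, amplitude: float) -> np.ndarray:
    """Low-frequency field: coarse white noise smoothly upsampled."""
    coarse = rng.standard_normal(
        ((shape[0] // cell) + 2, (shape[1] // cell) + 2)
    )
    field_ = ndimage.zoom(coarse, cell, order=1)[: shape[0], : shape[1]]
    return field_ * amplitude


def _paint_base(rng: np.random.Generator, shape, color, noise_sigma=3.0):
    img = np.empty(shape + (3,), dtype=float)
    for c in range(3):
        img[..., c] = color[c] + rng.normal(0.0, noise_sigma, shape)
    return img


def _disc_mask(shape, centers, radii) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for (cy, cx), r in zip(centers, radii):
        r_int = int(math.ceil(r))
        y0, y1 = max(0, cy - r_int), min(h, cy + r_int + 1)
        x0, x1 = max(0, cx - r_int), min(w, cx + r_int + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return mask


def _render_class_texture(name: str, shape: tuple[int, int],
                          rng: np.random.Generator) -> np.ndarray:
    """Full-frame texture for one class; composited through the label mask."""
    h, w = shape
    base = _BASE_COLORS[name]
    if name == "background":
        return _paint_base(rng, shape, base, noise_sigma=2.0)
    if name == "stroma":
        img = _paint_base(rng, shape, base, noise_sigma=4.0)
        field_ = _smooth_noise(rng, shape, cell=24, amplitude=20.0)
        # correlated across channels: fibrous density modulation, biased
        # dark so bright excursions stay below the clipping range
        img += field_[..., None] * np.array([0.9, 1.1, 1.0]) - 14.0
        return np.minimum(img, 246.0)
    if name == "benign":
        img = _paint_base(rng, shape, base, noise_sigma=5.0)
        n = max(4, (h * w) // 2200)
        centers = np.column_stack([rng.integers(0, h, n), rng.integers(0, w, n)])
        outer = rng.uniform(9.0, 13.0, n)
        ring = _disc_mask(shape, centers, outer) & ~_disc_mask(shape, centers, outer * 0.55)
        lumen = _disc_mask(shape, centers, outer * 0.55)
        img[ring] = np.array(_MOTIF_COLORS["benign"], dtype=float)
        img[lumen] = np.array([243.0, 238.0, 243.0])
        img += rng.normal(0.0, 4.0, shape + (3,))
        return img
    if name == "GP3":
        img = _paint_base(rng, shape, base, noise_sigma=5.0)
        n = max(8, (h * w) // 600)
        centers = np.column_stack([rng.integers(0, h, n), rng.integers(0, w, n)])
        radii = rng.uniform(2.5, 4.5, n)
        discs = _disc_mask(shape, centers, radii)
        img[discs] = np.array(_MOTIF_COLORS["GP3"], dtype=float)
        img += rng.normal(0.0, 4.0, shape + (3,))
        return img
    if name == "GP4":
        img = _paint_base(rng, shape, base, noise_sigma=5.0)
        field_ = _smooth_noise(rng, shape, cell=10, amplitude=1.0)
        blobs = field_ > 0.55  # fused irregular cords
        img[blobs] = np.array(_MOTIF_COLORS["GP4"], dtype=float)
        img += rng.normal(0.0, 4.0, shape + (3,))
        return img
    if name == "GP5":
        img = _paint_base(rng, shape, base, noise_sigma=5.0)
        # speckle density modulated by a smooth field: diffuse single
        # cells with regionally varying density
        density = np.clip(_smooth_noise(rng, shape, cell=32, amplitude=1.0), -1, 1)
        speckle = rng.random(shape) < (0.16 + 0.10 * density)
        img[speckle] = np.array(_MOTIF_COLORS["GP5"], dtype=float)
        img += rng.normal(0.0, 4.0, shape + (3,))
        return img
    raise ValueError(name)


# ---------------------------------------------------------------------------
# layout


def _serpentine_order(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    order = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return order


def _allocate_cells(spec: TissueLayoutSpec, rng: np.random.Generator,
                    cell: int) -> np.ndarray:
    """Assign grid cells to classes along a serpentine path.

    Each class's cell quota is split into a few contiguous runs so the
    image contains several connected regions per class (needed for
    partial-annotation sampling) while fractions stay within one cell
    of their targets.
    """
    side = spec.image_side
    n = math.ceil(side / cell)
    quotas = {"background": spec.background_fraction, **spec.class_fractions}
    names = [k for k, v in quotas.items() if v > 0]
    total_cells = n * n
    # largest-remainder apportionment of cells
    raw = np.array([quotas[k] * total_cells for k in names])
    counts = np.floor(raw).astype(int)
    remainder = total_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:remainder]:
        counts[i] += 1
    runs: list[tuple[str, int]] = []
    for name, count in zip(names, counts):
        if count == 0:
            continue
        k = int(min(count, 1 + rng.integers(2, 5)))
        splits = np.sort(rng.choice(np.arange(1, count), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        sizes = np.diff(np.concatenate([[0], splits, [count]]))
        runs.extend((name, int(s)) for s in sizes if s > 0)
    perm = rng.permutation(len(runs))
    runs = [runs[i] for i in perm]

    grid = np.empty((n, n), dtype=np.uint8)
    path = _serpentine_order(n, n)
    pos = 0
    for name, size in runs:
        code = 0 if name == "background" else CLASS_CODES[name]
        for r, c in path[pos : pos + size]:
            grid[r, c] = code
        pos += size
    return grid


def generate_tissue_image(spec: TissueLayoutSpec) -> LabeledImage:
    """Render a seeded tissue-like image with an exhaustive label raster.

    The same spec (including seed) always yields bit-identical output.
    Realized class area fractions are within ±5 percentage points of
    the spec (one layout cell in practice).
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    cell = spec.cell_side or int(np.clip(side // 16, 8, 32))
    grid = _allocate_cells(spec, rng, cell)
    labels = np.kron(grid, np.ones((cell, cell), dtype=np.uint8))[:side, :side]

    img = np.empty((side, side, 3), dtype=float)
    present = ["background"] + [
        n for n in CLASS_NAMES if np.any(labels == CLASS_CODES[n])
    ]
    for name in present:
        code = 0 if name == "background" else CLASS_CODES[name]
        mask = labels == code
        if not mask.any():
            continue
        texture = _render_class_texture(name, (side, side), rng)
        img[mask] = texture[mask]

    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    tissue = labels > 0
    return LabeledImage(rgb=rgb, labels=labels, tissue=tissue,
                        meta={"seed": spec.seed, "cell": cell})


# ---------------------------------------------------------------------------
# scanner styles and degradations


def _color_transform(rgb: np.ndarray, gain, offset, gamma) -> np.ndarray:
    out = np.empty_like(rgb, dtype=float)
    v = rgb.astype(float) / 255.0
    for c in range(3):
        out[..., c] = gain[c] * (v[..., c] ** gamma[c]) * 255.0 + offset[c]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_scanner_style(img: LabeledImage, style: ScannerStyle) -> LabeledImage:
    """Re-color an image with a scanner style; labels/mask are untouched."""
    rgb = _color_transform(img.rgb, style.gain, style.offset, style.gamma)
    return LabeledImage(rgb=rgb, labels=img.labels, tissue=img.tissue,
                        meta={**img.meta, "scanner": style.name})


def apply_degradation(img: LabeledImage, spec: DegradationSpec) -> LabeledImage:
    """Inject a quality defect; deterministic and confined to ``region``."""
    h, w = img.shape
    region = spec.region or (0, 0, h, w)
    r0, c0, r1, c1 = region
    rgb = img.rgb.astype(float).copy()
    sub = rgb[r0:r1, c0:c1]

    if spec.kind == "blur":
        for c in range(3):
            sub[..., c] = ndimage.gaussian_filter(sub[..., c], spec.magnitude)
    elif spec.kind == "low_contrast":
        mean = sub.mean(axis=(0, 1), keepdims=True)
        sub[...] = mean + spec.magnitude * (sub - mean)
    elif spec.kind == "saturation_clip":
        area = (r1 - r0) * (c1 - c0)
        radius = math.sqrt(spec.magnitude * area / math.pi)
        cy, cx = (r1 - r0) / 2.0, (c1 - c0) / 2.0
        yy, xx = np.ogrid[0 : r1 - r0, 0 : c1 - c0]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        sub[disc] = 255.0
    elif spec.kind == "artifact":
        # dark diagonal pen stroke covering ~magnitude of the region
        hh, ww = r1 - r0, c1 - c0
        yy, xx = np.ogrid[0:hh, 0:ww]
        diag = np.abs(yy / hh - xx / ww)
        half = spec.magnitude / 2.0
        stroke = diag <= half
        sub[stroke] = np.array([28.0, 62.0, 44.0])  # ink green-black
    elif spec.kind == "uniform_patch":
        sub[...] = sub.mean(axis=(0, 1), keepdims=True)

    rgb[r0:r1, c0:c1] = sub
    out = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return LabeledImage(rgb=out, labels=img.labels, tissue=img.tissue,
                        meta={**img.meta, "degradation": spec.kind})


# ---------------------------------------------------------------------------
# partial annotations


def generate_annotation_set(labels: np.ndarray, completeness: float,
                            seed: int = 0, min_area: int = 100) -> list[Annotation]:
    """Trace a partial polygon annotation set from a label raster.

    Emulates non-exhaustive pathologist markup: for each class, whole
    connected regions are selected in seeded random order until roughly
    ``completeness`` of the class's labeled area carries a polygon; the
    last region may be cropped row-wise to land within ±10% of the
    target.  ``completeness=1.0`` annotates every region (of at least
    ``min_area`` pixels).
    """
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must be in (0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    annotations: list[Annotation] = []
    from skimage import measure

    for code in sorted(CODE_NAMES):
        name = CODE_NAMES[code]
        class_mask = labels == code
        class_area = int(class_mask.sum())
        if class_area == 0:
            continue
        if completeness == 1.0:
            for poly in mask_to_polygons(class_mask, min_area=min_area):
                annotations.append(Annotation(poly, name))
            continue
        comp = measure.label(class_mask, connectivity=1)
        regions = [r for r in measure.regionprops(comp) if r.area >= min_area]
        if not regions:
            continue
        order = rng.permutation(len(regions))
        target = completeness * class_area
        taken = 0.0
        for idx in order:
            region = regions[idx]
            if taken >= target:
                break
            mask = comp == region.label
            if taken + region.area > target:
                # crop the region row-wise to the remaining quota
                need = int(round(target - taken))
                rows_present = np.flatnonzero(mask.any(axis=1))
                cum = np.cumsum(mask[rows_present].sum(axis=1))
                keep = int(np.searchsorted(cum, need) + 1)
                cropped = np.zeros_like(mask)
                cropped[rows_present[:keep]] = mask[rows_present[:keep]]
                mask = cropped
                if mask.sum() < min_area:
                    break
            for poly in mask_to_polygons(mask, min_area=min_area):
                annotations.append(Annotation(poly, name))
            taken += mask.sum()
    return annotations


def varied_tissue_spec(seed: int, image_side: int = 384, alpha: float = 4.0,
                       tissue_total: float = 0.9,
                       cell_side: Optional[int] = None) -> TissueLayoutSpec:
    """Layout spec with seeded random class composition.

    Class fractions are drawn from a symmetric Dirichlet (concentration
    ``alpha``) scaled to ``tissue_total``, emulating slide-to-slide
    variation in tissue composition; the remainder is background.
    """
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(len(CLASS_NAMES), alpha)) * tissue_total
    fractions = dict(zip(CLASS_NAMES, w.tolist()))
    return TissueLayoutSpec(
        image_side=image_side, cell_side=cell_side, seed=seed,
        class_fractions=fractions,
        background_fraction=1.0 - float(w.sum()),
    )


# ---------------------------------------------------------------------------
# canonical QC fixture suites

#: Degradation magnitudes used by the canonical QC fixture suite.  These
#: define the study conditions for the detection benchmarks: clearly
#: pathological defects, not borderline ones.
QC_SUITE_MAGNITUDES = {
    "blur": 3.0,
    "low_contrast": 0.2,
    "saturation_clip": 0.15,
    "artifact": 0.10,
    "uniform_patch": 1.0,
}


def _single_class_tile(name: str, side: int, seed: int) -> LabeledImage:
    rng = np.random.default_rng(seed)
    texture = _render_class_texture(name, (side, side), rng)
    rgb = np.clip(np.rint(texture), 0, 255).astype(np.uint8)
    labels = np.full((side, side), CLASS_CODES[name], dtype=np.uint8)
    return LabeledImage(rgb=rgb, labels=labels, tissue=np.ones((side, side), bool))


def make_qc_tile_suite(n_tiles: int = 200, tile_side: int = 256, seed: int = 0):
    """Seeded tile suite for QC detection benchmarks.

    Half the tiles are clean, half carry exactly one degradation, with
    the five kinds and five tissue classes cycled evenly.  Returns a
    list of ``(tile: LabeledImage, truth: str | None)`` pairs where
    ``truth`` names the injected degradation kind (``None`` = clean).
    """
    suite = []
    kinds = list(DEGRADATION_KINDS)
    for i in range(n_tiles):
        idx = i // 2
        if i % 2 == 0:
            name = CLASS_NAMES[idx % len(CLASS_NAMES)]
            tile = _single_class_tile(name, tile_side, seed=seed * 100003 + i)
            suite.append((tile, None))
        else:
            # cycle every (kind, class) combination evenly
            kind = kinds[idx % len(kinds)]
            name = CLASS_NAMES[(idx // len(kinds)) % len(CLASS_NAMES)]
            tile = _single_class_tile(name, tile_side, seed=seed * 100003 + i)
            spec = DegradationSpec(kind=kind, magnitude=QC_SUITE_MAGNITUDES[kind])
            suite.append((apply_degradation(tile, spec), kind))
    return suite


def make_quality_slide(side: int = 1024, tile_side: int = 256,
                       low_quality_fraction: float = 0.25, seed: int = 0):
    """Synthetic slide with a known fraction of low-quality tiles.

    Selected tiles receive two defects (clipped highlights + ink
    artifact, both content-independent) so they trip the
    two-or-more-issues rule; returns ``(image, truth_mask)`` where
    ``truth_mask[i, j]`` marks degraded tiles on the tile grid.
    """
    spec = TissueLayoutSpec(image_side=side, background_fraction=0.0,
                            class_fractions={"stroma": 0.3, "benign": 0.2,
                                             "GP3": 0.2, "GP4": 0.2, "GP5": 0.1},
                            seed=seed)
    img = generate_tissue_image(spec)
    rng = np.random.default_rng(seed + 1)
    n = side // tile_side
    n_low = int(round(low_quality_fraction * n * n))
    flat = rng.choice(n * n, size=n_low, replace=False)
    truth = np.zeros((n, n), dtype=bool)
    out = img
    for k in flat:
        i, j = divmod(int(k), n)
        truth[i, j] = True
        region = (i * tile_side, j * tile_side, (i + 1) * tile_side, (j + 1) * tile_side)
        out = apply_degradation(out, DegradationSpec("saturation_clip", 0.12, region))
        out = apply_degradation(out, DegradationSpec("artifact", 0.10, region))
    return out, truth
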