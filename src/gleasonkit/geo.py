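"""Polygon annotations: tracing, rasterization and GeoJSON round-trip.

Annotations are labeled polygons in pixel coordinates, the common
currency between pathologists' region markup, the synthetic fixture
generator and model predictions.  Polygons use (x, y) = (column, row)
axis order; rasters are indexed (row, column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon, mapping, shape
from skimage import measure
from skimage.draw import polygon2mask

from .types import CLASS_CODES, CODE_NAMES


@dataclass
class Annotation:
    """A single labeled polygonal region in pixel coordinates."""

    polygon: Polygon
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_CODES:
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def area(self) -> float:
        return self.polygon.area


#: An annotation set is simply an ordered list of labeled polygons; the
#: order carries no meaning (all consumers are order-invariant).
AnnotationSet = list


def mask_to_polygons(mask: np.ndarray, min_area: int = 0) -> list[Polygon]:
    """Trace connected components of a boolean mask into polygons.

    Contours are traced at the 0.5 iso-level of the padded mask, so each
    polygon passes halfway between foreground and background pixel
    centers.  Interior holes are preserved.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=1)
    polygons: list[Polygon] = []
    for region in measure.regionprops(labeled):
        if min_area and region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        sub = labeled[r0:r1, c0:c1] == region.label
        padded = np.pad(sub.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        rings = []
        for contour in contours:
            # (row, col) in padded coords -> (x, y) in image coords
            xy = np.column_stack([
                contour[:, 1] - 1 + c0,
                contour[:, 0] - 1 + r0,
            ])
            ring = Polygon(xy)
            if ring.is_valid and ring.area > 0:
                rings.append(ring)
        if not rings:
            continue
        rings.sort(key=lambda p: p.area, reverse=True)
        exterior, holes = rings[0], rings[1:]
        poly = Polygon(
            exterior.exterior.coords,
            [h.exterior.coords for h in holes],
        )
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        # drop collinear contour points (exact): pixel-edge contours of
        # blocky regions carry long straight runs
        poly = poly.simplify(0)
        if poly.geom_type == "MultiPolygon":
            polygons.extend(list(poly.geoms))
        else:
            polygons.append(poly)
    return polygons


def _ring_mask(coords: Sequence, shape: tuple[int, int],
               offset: tuple[int, int] = (0, 0)) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    # (x, y) -> (row, col), shifted into the cropped frame
    rc = pts[:, ::-1] - np.asarray(offset, dtype=float)
    return polygon2mask(shape, rc)


def rasterize_polygon(polygon: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``polygon``."""
    minx, miny, maxx, maxy = polygon.bounds
    r0 = max(0, int(np.floor(miny)))
    c0 = max(0, int(np.floor(minx)))
    r1 = min(shape[0], int(np.ceil(maxy)) + 1)
    c1 = min(shape[1], int(np.ceil(maxx)) + 1)
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    crop_shape = (r1 - r0, c1 - c0)
    crop = _ring_mask(polygon.exterior.coords, crop_shape, (r0, c0))
    for interior in polygon.interiors:
        crop &= ~_ring_mask(interior.coords, crop_shape, (r0, c0))
    mask[r0:r1, c0:c1] = crop
    return mask


def rasterize_annotations(
    annotations: Iterable[Annotation], shape: tuple[int, int]
) -> np.ndarray:
    """Render an annotation set to a class-code label raster.

    Later annotations overwrite earlier ones where polygons overlap
    (annotation sets produced by this package never overlap).
    """
    raster = np.zeros(shape, dtype=np.uint8)
    for ann in annotations:
        mask = rasterize_polygon(ann.polygon, shape)
        raster[mask] = CLASS_CODES[ann.label]
    return raster


def label_raster_to_annotations(
    labels: np.ndarray, min_area: int = 100
) -> list[Annotation]:
    """Trace every labeled region of a class raster into annotations."""
    annotations: list[Annotation] = []
    for code in sorted(CODE_NAMES):
        name = CODE_NAMES[code]
        for poly in mask_to_polygons(labels == code, min_area=min_area):
            annotations.append(Annotation(poly, name))
    return annotations


def write_geojson(annotations: Iterable[Annotation], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(ann.polygon),
            "properties": {"label": ann.label},
        }
        for ann in annotations
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_geojson(path: str | Path) -> list[Annotation]:
    payload = json.loads(Path(path).read_text())
    annotations = []
    for feature in payload["features"]:
        geom = shape(feature["geometry"])
        label = feature["properties"]["label"]
        if geom.geom_type == "MultiPolygon":
            annotations.extend(Annotation(g, label) for g in geom.geoms)
        else:
            annotations.append(Annotation(geom, label))
    return annotations
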