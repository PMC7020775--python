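"""Segmentation metrics: pixelwise Dice and instance-level polygon F1.

The Dice similarity coefficient, ``2·TP / (2·TP + FP + FN)``, measures pixel
overlap between a predicted and a ground-truth binary mask.  It is blind to
instance structure: a single blob covering two adjacent buildings scores
nearly as well as two correctly separated footprints.  The polygon F1 metric
(as used for building-footprint benchmarks) closes that gap: the predicted
mask is polygonized by pixel connectivity, proposals are matched one-to-one
to ground-truth polygons by Jaccard index (IoU) with a true positive asserted
when IoU exceeds 0.5, and F1 is the harmonic mean of precision and recall
over those matches.

Polygons live in pixel coordinates with the convention that pixel ``(row,
col)`` occupies the unit square ``[col, col+1] x [row, row+1]`` in ``(x, y)``
space; polygon area therefore equals pixel count exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import shapely
import shapely.geometry as sgeom
from scipy import ndimage
from shapely.ops import unary_union

__all__ = [
    "ConfusionCounts",
    "PolygonSet",
    "MatchResult",
    "confusion_counts",
    "dice",
    "dice_from_counts",
    "polygonize",
    "rasterize_polygons",
    "polygon_iou",
    "polygon_f1",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against ground truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact TP/FP/TN/FN pixel counts; masks must share a shape."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred > 0
    g = gt > 0
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def dice_from_counts(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        # Both masks empty: perfect agreement by convention.
        return 1.0
    return 2.0 * c.tp / denom


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks.

    Returns 1.0 when both masks are empty (the community convention for
    scans with no foreground).
    """
    return dice_from_counts(confusion_counts(pred, gt))


# ---------------------------------------------------------------------------
# Polygons


@dataclass
class PolygonSet:
    """A list of simple positive-area polygons in pixel coordinates."""

    polygons: list[sgeom.Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, p in enumerate(self.polygons):
            if not isinstance(p, sgeom.Polygon):
                raise TypeError(f"entry {i} is {type(p).__name__}, not a Polygon")
            if not p.is_valid:
                raise ValueError(f"polygon {i} is not simple/valid")
            if p.area <= 0:
                raise ValueError(f"polygon {i} has non-positive area")

    def __len__(self) -> int:
        return len(self.polygons)

    def __iter__(self) -> Iterator[sgeom.Polygon]:
        return iter(self.polygons)

    def __getitem__(self, i: int) -> sgeom.Polygon:
        return self.polygons[i]

    @property
    def areas(self) -> list[float]:
        return [p.area for p in self.polygons]

    def to_geojson(
        self, transform: Callable[[float, float], tuple[float, float]] | None = None
    ) -> dict:
        """As a GeoJSON FeatureCollection; ``transform`` optionally maps pixel
        (x, y) to another coordinate frame (e.g. an affine geo-referencing)."""
        polys = self.polygons
        if transform is not None:
            polys = [shapely.ops.transform(lambda x, y: transform(x, y), p) for p in polys]
        return {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"index": i}, "geometry": sgeom.mapping(p)}
                for i, p in enumerate(polys)
            ],
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "PolygonSet":
        polys = []
        for feat in obj.get("features", []):
            geom = sgeom.shape(feat["geometry"])
            if isinstance(geom, sgeom.Polygon):
                polys.append(geom)
            elif isinstance(geom, sgeom.MultiPolygon):
                polys.extend(geom.geoms)
            else:
                raise ValueError(f"unsupported geometry type {geom.geom_type}")
        return cls(polys)

    def write_geojson(self, path: str | Path, **kwargs) -> None:
        Path(path).write_text(json.dumps(self.to_geojson(**kwargs)))

    @classmethod
    def read_geojson(cls, path: str | Path) -> "PolygonSet":
        return cls.from_geojson(json.loads(Path(path).read_text()))


def _pixel_box(row: int, col: int) -> sgeom.Polygon:
    return sgeom.box(col, row, col + 1, row + 1)


def polygonize(mask: np.ndarray, connectivity: int = 4) -> PolygonSet:
    """Trace one polygon per foreground connected component of a 2D mask.

    Components are found under 4-connectivity by default (8 available); each
    component's pixels are merged into a polygon whose vertices follow the
    pixel-boundary outline, so the polygon area equals the component's pixel
    count.  Holes are preserved as interior rings and subtract from the area.
    Under 8-connectivity, a component whose parts touch only at pixel corners
    merges its corner-touching squares into the rings GEOS produces for that
    union; such point-contacts may yield one feature per 4-connected part.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"polygonize expects a 2D mask, got {mask.ndim}D")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(mask > 0, structure=structure)
    polys: list[sgeom.Polygon] = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        rows, cols = np.nonzero(labels[sl] == lab)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        merged = unary_union([_pixel_box(r, c) for r, c in zip(rows, cols)])
        if isinstance(merged, sgeom.Polygon):
            polys.append(merged)
        else:  # MultiPolygon: 8-connectivity corner-contact case
            polys.extend(merged.geoms)
    return PolygonSet(polys)


def rasterize_polygons(polygons: PolygonSet | Sequence[sgeom.Polygon], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize polygons onto a pixel grid by pixel-center containment.

    Pixel (r, c) is foreground when its center (c + 0.5, r + 0.5) lies inside
    any polygon — exact for polygons built from whole pixels.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor(minx)))
        r0 = max(0, int(np.floor(miny)))
        c1 = min(shape[1], int(np.ceil(maxx)))
        r1 = min(shape[0], int(np.ceil(maxy)))
        if c1 <= c0 or r1 <= r0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = shapely.points(cc.ravel() + 0.5, rr.ravel() + 0.5)
        inside = shapely.contains(poly, pts).reshape(rr.shape)
        mask[r0:r1, c0:c1] |= inside.astype(np.uint8)
    return mask


def polygon_iou(a: sgeom.Polygon, b: sgeom.Polygon) -> float:
    """Jaccard index (intersection over union) of two polygons."""
    inter = a.intersection(b).area
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching proposal polygons to ground truth by IoU."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...]  # (proposal idx, gt idx, IoU)
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "pairs": [list(p) for p in self.pairs],
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def polygon_f1(
    proposals: PolygonSet,
    ground_truth: PolygonSet,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one IoU matching and the resulting precision/recall/F1.

    Candidate pairs with IoU strictly above ``iou_threshold`` are matched in
    descending-IoU order (ties broken by proposal index, then ground-truth
    index); each polygon participates in at most one match.  F1 is the
    harmonic mean of precision and recall, 0 when both are undefined.
    """
    candidates: list[tuple[float, int, int]] = []
    for i, p in enumerate(proposals):
        for j, g in enumerate(ground_truth):
            iou = polygon_iou(p, g)
            if iou > iou_threshold:
                candidates.append((iou, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for iou, i, j in candidates:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        pairs.append((i, j, iou))

    tp = len(pairs)
    fp = len(proposals) - tp
    fn = len(ground_truth) - tp
    precision = tp / len(proposals) if len(proposals) else 0.0
    recall = tp / len(ground_truth) if len(ground_truth) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MatchResult(tp, fp, fn, tuple(pairs), precision, recall, f1)
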