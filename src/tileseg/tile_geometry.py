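"""Tile layouts over 2D images and 3D volumes.

Tiled ("sliding window" / patch-based) inference runs a segmentation model on
small windows of a large image and stitches the per-window predictions back
together.  This module provides the geometric backbone: tile placements,
corner+center and sliding-window layout generators, tile extraction, coverage
maps, and small translations of a tile used by variance analysis.

Conventions (used package-wide):

* Coordinates are 0-based; a tile occupies the half-open box
  ``[offset, offset + shape)`` on every spatial axis.
* Arrays are channels-last: ``(H, W)`` or ``(H, W, C)`` in 2D,
  ``(H, W, D)`` or ``(H, W, D, C)`` in 3D.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TileSpec",
    "TileLayout",
    "CoverageMap",
    "corner_center_layout",
    "sliding_window_layout",
    "single_tile_layout",
    "extract_tile",
    "place_tile",
    "coverage_map",
    "offset_crop",
]


@dataclass(frozen=True)
class TileSpec:
    """One tile placement: a 0-based ``offset`` and a ``shape``, per spatial axis."""

    offset: tuple[int, ...]
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset", tuple(int(o) for o in self.offset))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.offset) != len(self.shape):
            raise ValueError(
                f"offset has {len(self.offset)} axes but shape has {len(self.shape)}"
            )
        if any(o < 0 for o in self.offset):
            raise ValueError(f"negative offset {self.offset}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"tile shape must be >= 1 on every axis, got {self.shape}")

    @property
    def ndim(self) -> int:
        return len(self.offset)

    @property
    def end(self) -> tuple[int, ...]:
        """Exclusive upper corner, ``offset + shape``."""
        return tuple(o + s for o, s in zip(self.offset, self.shape))

    def slices(self) -> tuple[slice, ...]:
        """Index expression selecting this tile's extent from an image array."""
        return tuple(slice(o, o + s) for o, s in zip(self.offset, self.shape))

    def contains_point(self, point: Sequence[int]) -> bool:
        return all(o <= p < e for o, p, e in zip(self.offset, point, self.end))

    def to_dict(self) -> dict:
        return {"offset": list(self.offset), "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: dict) -> "TileSpec":
        return cls(tuple(d["offset"]), tuple(d["shape"]))


@dataclass(frozen=True)
class TileLayout:
    """An ordered set of tile placements over an image of known spatial shape."""

    image_shape: tuple[int, ...]
    tiles: tuple[TileSpec, ...]
    scheme: str = "single"

    _SCHEMES = ("corner_center", "sliding_window", "single")

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))
        object.__setattr__(self, "tiles", tuple(self.tiles))
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {self._SCHEMES}")
        for t in self.tiles:
            _check_bounds(t, self.image_shape)
        offsets = [t.offset for t in self.tiles]
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate tile offsets in layout")

    @property
    def ndim(self) -> int:
        return len(self.image_shape)

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self) -> Iterator[TileSpec]:
        return iter(self.tiles)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_shape": list(self.image_shape),
                "scheme": self.scheme,
                "tiles": [t.to_dict() for t in self.tiles],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TileLayout":
        d = json.loads(text)
        return cls(
            tuple(d["image_shape"]),
            tuple(TileSpec.from_dict(t) for t in d["tiles"]),
            d["scheme"],
        )


@dataclass
class CoverageMap:
    """Per-pixel count of how many tiles of a layout contain each pixel."""

    counts: np.ndarray = field(repr=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def min(self) -> int:
        return int(self.counts.min())

    @property
    def uncovered(self) -> np.ndarray:
        """Boolean grid, True where no tile covers the pixel."""
        return self.counts == 0


def _check_bounds(spec: TileSpec, image_shape: Sequence[int]) -> None:
    if spec.ndim != len(image_shape):
        raise ValueError(
            f"tile has {spec.ndim} spatial axes but image has {len(image_shape)}"
        )
    for ax, (o, s, n) in enumerate(zip(spec.offset, spec.shape, image_shape)):
        if o + s > n:
            raise ValueError(
                f"tile [{o}, {o + s}) exceeds image extent {n} on axis {ax}"
            )


def _dedupe(offsets: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    seen: set[tuple[int, ...]] = set()
    out = []
    for o in offsets:
        if o not in seen:
            seen.add(o)
            out.append(o)
    return out


def corner_center_layout(
    image_shape: Sequence[int], tile_shape: Sequence[int]
) -> TileLayout:
    """Fixed layout of the 2^d corner tiles plus one centered tile.

    In 2D this is the five-tile scheme (four corners + center); in 3D the
    nine-tile scheme (eight corners + center).  The center offset is
    ``floor((image - tile) / 2)`` per axis.  Placements that coincide exactly
    (degenerate geometry, e.g. tile == image) are deduplicated; corners come
    first in lexicographic offset order, the center tile last.
    """
    image_shape = tuple(int(s) for s in image_shape)
    tile_shape = tuple(int(s) for s in tile_shape)
    d = len(image_shape)
    if d not in (2, 3):
        raise ValueError(f"expected 2 or 3 spatial axes, got {d}")
    if len(tile_shape) != d:
        raise ValueError("image_shape and tile_shape dimensionality differ")
    for ax, (n, t) in enumerate(zip(image_shape, tile_shape)):
        if t > n:
            raise ValueError(f"tile size {t} exceeds image size {n} on axis {ax}")

    margins = [n - t for n, t in zip(image_shape, tile_shape)]
    corners = sorted(itertools.product(*[(0, m) for m in margins]))
    center = tuple(m // 2 for m in margins)
    offsets = _dedupe(corners + [center])
    tiles = tuple(TileSpec(o, tile_shape) for o in offsets)
    return TileLayout(image_shape, tiles, scheme="corner_center")


def sliding_window_layout(
    image_shape: Sequence[int],
    tile_shape: Sequence[int],
    overlap_fraction: float = 0.5,
) -> TileLayout:
    """Regular sliding-window layout with a given fractional overlap.

    The stride per axis is ``round(tile * (1 - overlap_fraction))``.  Offsets
    run 0, s, 2s, ... and the final offset is clamped to ``image - tile`` so
    the trailing boundary is always covered; the layout is the Cartesian
    product of per-axis offsets and its union covers every pixel.
    """
    image_shape = tuple(int(s) for s in image_shape)
    tile_shape = tuple(int(s) for s in tile_shape)
    if len(tile_shape) != len(image_shape):
        raise ValueError("image_shape and tile_shape dimensionality differ")
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    for ax, (n, t) in enumerate(zip(image_shape, tile_shape)):
        if t > n:
            raise ValueError(f"tile size {t} exceeds image size {n} on axis {ax}")

    per_axis: list[list[int]] = []
    for n, t in zip(image_shape, tile_shape):
        stride = round(t * (1.0 - overlap_fraction))
        if stride < 1:
            raise ValueError(
                f"overlap_fraction {overlap_fraction} gives stride 0 for tile size {t}"
            )
        last = n - t
        offs = list(range(0, last + 1, stride))
        if offs[-1] != last:
            offs.append(last)  # clamp final tile to the boundary
        per_axis.append(offs)

    offsets = _dedupe([tuple(o) for o in itertools.product(*per_axis)])
    tiles = tuple(TileSpec(o, tile_shape) for o in offsets)
    return TileLayout(image_shape, tiles, scheme="sliding_window")


def single_tile_layout(image_shape: Sequence[int]) -> TileLayout:
    """Trivial layout with one tile covering the whole image."""
    image_shape = tuple(int(s) for s in image_shape)
    tile = TileSpec((0,) * len(image_shape), image_shape)
    return TileLayout(image_shape, (tile,), scheme="single")


def extract_tile(image: np.ndarray, spec: TileSpec) -> np.ndarray:
    """Copy the tile's extent out of ``image`` (spatial axes first, channels preserved)."""
    _check_bounds(spec, image.shape[: spec.ndim])
    return image[spec.slices()].copy()


def place_tile(canvas: np.ndarray, spec: TileSpec, tile: np.ndarray) -> None:
    """Write ``tile`` back into ``canvas`` at the spec's extent (in place)."""
    _check_bounds(spec, canvas.shape[: spec.ndim])
    if tuple(tile.shape[: spec.ndim]) != spec.shape:
        raise ValueError(f"tile shape {tile.shape} does not match spec shape {spec.shape}")
    canvas[spec.slices()] = tile


def coverage_map(layout: TileLayout) -> CoverageMap:
    """Count, per pixel, the number of tiles whose extent contains it."""
    counts = np.zeros(layout.image_shape, dtype=np.int64)
    for t in layout:
        counts[t.slices()] += 1
    return CoverageMap(counts)


def offset_crop(
    image: np.ndarray, base: TileSpec, delta: Sequence[int]
) -> tuple[TileSpec, dict]:
    """Translate ``base`` by ``delta`` pixels and report the overlap region.

    Returns the translated :class:`TileSpec` and a dict with per-axis overlap
    intervals in image coordinates (``image``), in the base tile's local frame
    (``base_local``) and in the translated tile's local frame
    (``translated_local``), plus the overlap ``shape``.  The translated tile
    must lie fully inside the image: variance analysis needs exact offsets, so
    out-of-bounds deltas raise instead of clamping.
    """
    delta = tuple(int(d) for d in delta)
    if len(delta) != base.ndim:
        raise ValueError("delta dimensionality does not match base tile")
    new_offset = tuple(o + d for o, d in zip(base.offset, delta))
    if any(o < 0 for o in new_offset):
        raise ValueError(f"translated tile offset {new_offset} is out of bounds")
    moved = TileSpec(new_offset, base.shape)
    _check_bounds(moved, image.shape[: base.ndim])

    lo = tuple(max(a, b) for a, b in zip(base.offset, moved.offset))
    hi = tuple(min(a, b) for a, b in zip(base.end, moved.end))
    shape = tuple(max(0, h - l) for l, h in zip(lo, hi))
    report = {
        "image": [[l, h] for l, h in zip(lo, hi)],
        "base_local": [[l - o, h - o] for l, h, o in zip(lo, hi, base.offset)],
        "translated_local": [[l - o, h - o] for l, h, o in zip(lo, hi, moved.offset)],
        "shape": list(shape),
    }
    return moved, report
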