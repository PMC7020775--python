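"""Synthetic stand-ins for multi-modal MRI scans and building-footprint scenes.

Real evaluations of tiled inference use brain-tumour MRI (4-modality
240x240x155 scans with whole-tumour masks) and satellite building footprints
(650x650 RGB scenes with vector ground truth).  This module generates
structurally analogous phantoms so every pipeline component can be exercised
deterministically:

* :func:`make_brats_like_scan` — a 4-channel volume that is exactly zero
  outside a head-like support ellipsoid, with smooth tissue texture inside
  and a union of contrasted blobs ("tumour") defining the binary mask;
* :func:`make_building_scene` — an RGB scene of rectangular buildings,
  including tight cul-de-sac clusters of ~6 houses separated by small gaps,
  with the exact vector polygons as ground truth;
* preprocessing (percentile clipping + z-scoring of non-zero voxels),
  axial slicing, leakage-free unit-level train/val/test splitting, and
  paired geometric augmentation.

All generators are pure functions of their seed.  The phantoms emulate the
*geometry* of the real data (shapes, support, foreground structure), not MRI
physics or remote-sensing radiometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely.geometry as sgeom

from .metrics import PolygonSet, rasterize_polygons

__all__ = [
    "ScanPhantomConfig",
    "SceneConfig",
    "SplitAssignment",
    "make_brats_like_scan",
    "preprocess_scan",
    "slice_scan",
    "split_by_unit",
    "make_building_scene",
    "augment",
]


@dataclass(frozen=True)
class ScanPhantomConfig:
    """Geometry and intensity parameters of a brain-scan phantom.

    Defaults mirror the real scan geometry: 240x240 in-plane, 155 axial
    slices, 4 channels standing in for the T1 / T1Gd / T2 / FLAIR
    modalities.  ``channel_offsets`` give each modality a distinct blob
    contrast so channels are non-redundant.
    """

    shape: tuple[int, ...] = (240, 240, 155)
    channels: int = 4
    n_blobs: int = 2
    blob_radius_range: tuple[float, float] = (8.0, 20.0)
    channel_offsets: tuple[float, ...] = (1.0, 2.0, 0.5, 1.5)
    support_axes_fraction: tuple[float, ...] = (0.45, 0.4, 0.45)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if len(self.channel_offsets) < self.channels:
            raise ValueError("need one intensity offset per channel")
        rmax = self.blob_radius_range[1]
        if 2 * rmax > min(self.shape):
            raise ValueError(
                f"blob radius {rmax} does not fit inside volume shape {self.shape}"
            )


def make_brats_like_scan(
    config: ScanPhantomConfig = ScanPhantomConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one multi-channel volume phantom and its binary tumour mask.

    Returns ``(volume, mask)`` with volume shape ``shape + (channels,)`` and
    mask shape ``shape``.  The volume is exactly zero outside a centred
    support ellipsoid (consistent zero background, as in skull-stripped
    scans); inside it carries smooth low-frequency texture plus seeded
    Gaussian noise, and each blob adds a channel-specific intensity offset.
    The mask is the union of the blobs, non-empty whenever ``n_blobs >= 1``.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    axes = [f * n for f, n in zip(config.support_axes_fraction, shape)]
    support = (
        sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)) <= 1.0
    )

    # Smooth background texture: a few random low-frequency cosine modes.
    texture = np.zeros(shape)
    for _ in range(4):
        freq = rng.uniform(0.5, 2.0, size=len(shape))
        phase = rng.uniform(0, 2 * math.pi, size=len(shape))
        mode = np.ones(shape)
        for g, n, f, p in zip(grids, shape, freq, phase):
            mode = mode * np.cos(2 * math.pi * f * g / n + p)
        texture += rng.uniform(0.1, 0.3) * mode

    mask = np.zeros(shape, dtype=np.uint8)
    blob_field = np.zeros(shape)
    for _ in range(config.n_blobs):
        r = rng.uniform(*config.blob_radius_range)
        # Keep blob centers well inside the support ellipsoid.
        c = [
            ctr + 0.5 * a * u
            for ctr, a, u in zip(center, axes, rng.uniform(-1, 1, size=len(shape)))
        ]
        dist2 = sum((g - ci) ** 2 for g, ci in zip(grids, c)) / r**2
        mask |= (dist2 <= 1.0).astype(np.uint8)
        blob_field += np.exp(-3.0 * dist2)

    volume = np.zeros(shape + (config.channels,))
    for ch in range(config.channels):
        base = 1.0 + 0.2 * ch
        img = base + texture + config.channel_offsets[ch] * blob_field
        img += rng.normal(0.0, config.noise_sd, size=shape)
        img = np.clip(img, 0.05, None)  # keep in-support voxels strictly positive
        volume[..., ch] = np.where(support, img, 0.0)
    mask &= support
    return volume, mask


def preprocess_scan(
    volume: np.ndarray, percentile: float = 98.0
) -> np.ndarray:
    """Clip each channel at its percentile, then z-score its non-zero voxels.

    The percentile (linear-interpolation definition) is taken over all voxels
    of the channel; values above it are clipped to it.  Standardization uses
    the mean and standard deviation of the channel's *non-zero* voxels only,
    and zero (background) voxels remain exactly zero — the background stays
    consistent across scans.  A channel with no non-zero voxels is left
    untouched with a warning.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim < 2:
        raise ValueError("expected a multi-channel volume (channels last)")
    out = volume.copy()
    for ch in range(volume.shape[-1]):
        img = out[..., ch]
        nz = img != 0
        if not nz.any():
            warnings.warn(f"channel {ch} has no non-zero voxels; left unchanged")
            continue
        hi = np.percentile(img, percentile)
        img = np.minimum(img, hi)
        nz = img != 0  # clipping cannot create zeros from positives, but stay exact
        mu = img[nz].mean()
        sd = img[nz].std()
        if sd == 0:
            sd = 1.0
        res = np.zeros_like(img)
        res[nz] = (img[nz] - mu) / sd
        out[..., ch] = res
    return out


def slice_scan(
    volume: np.ndarray, mask: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a 3D scan into its ordered axial 2D slices.

    The slice axis is the last spatial axis; a 240x240x155 scan yields 155
    (image, mask) pairs, each image keeping its channels.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.ndim == mask.ndim:  # no channel axis
        vol_spatial = volume.shape
    else:
        vol_spatial = volume.shape[:-1]
    if vol_spatial != mask.shape:
        raise ValueError(
            f"volume spatial shape {vol_spatial} does not match mask shape {mask.shape}"
        )
    depth = mask.shape[-1]
    pairs = []
    for k in range(depth):
        img = volume[:, :, k] if volume.ndim == 3 else volume[:, :, k, :]
        pairs.append((img, mask[:, :, k]))
    return pairs


@dataclass(frozen=True)
class SplitAssignment:
    """A partition of unit ids (patients / scenes) into train/val/test."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]

    _SPLITS = ("train", "validation", "test")

    def units(self, split: str) -> list[str]:
        return [u for u, s in self.assignment.items() if s == split]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return tuple(len(self.units(s)) for s in self._SPLITS)

    def to_dict(self) -> dict:
        return {"fractions": list(self.fractions), "assignment": dict(self.assignment)}


def split_by_unit(
    unit_ids: Sequence,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Seeded random train/validation/test partition at the unit level.

    Because the split is assigned per unit (patient scan / scene), all slices
    derived from one unit land in exactly one split — leakage between splits
    is impossible by construction.  Split sizes are the floor allocation of
    the fractions with the remainder going to the training split.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(unit_ids)
    # Floor allocation; the 1e-9 guards against 335 * (30/335) = 29.999...
    n_val = int(n * fractions[1] + 1e-9)
    n_test = int(n * fractions[2] + 1e-9)
    n_train = n - n_val - n_test
    for name, size, frac in zip(("train", "validation", "test"), (n_train, n_val, n_test), fractions):
        if frac > 0 and size == 0:
            raise ValueError(f"too few units ({n}) for a non-empty {name} split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "validation"
        else:
            split = "test"
        assignment[str(unit_ids[idx])] = split
    return SplitAssignment(assignment, tuple(fractions))


# ---------------------------------------------------------------------------
# Building scenes


@dataclass(frozen=True)
class SceneConfig:
    """Layout parameters of a synthetic building scene.

    Buildings are axis-aligned or slightly rotated rectangles; a number of
    ``cul_de_sac`` clusters place ``cul_de_sac_size`` houses (default 6, the
    typical count per cul-de-sac) in a tight row separated by
    ``cluster_gap`` pixels — the configuration that merges into one blob
    under coarse tiled predictions.
    """

    image_size: tuple[int, int] = (650, 650)
    n_buildings: int = 12
    building_size_range: tuple[int, int] = (12, 40)
    min_gap: int = 6
    cul_de_sac_count: int = 1
    cul_de_sac_size: int = 6
    cluster_gap: int = 3
    rotation_range: float = 0.0  # degrees; 0 keeps rectangles axis-aligned
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_gap < 0 or self.cluster_gap < 0:
            raise ValueError("gaps must be >= 0")
        if self.building_size_range[0] < 2:
            raise ValueError("buildings must be at least 2 pixels wide")


def _rect_polygon(r0: float, c0: float, h: float, w: float, angle_deg: float) -> sgeom.Polygon:
    poly = sgeom.box(c0, r0, c0 + w, r0 + h)
    if angle_deg:
        import shapely.affinity as saff

        poly = saff.rotate(poly, angle_deg, origin="centroid")
    return poly


def make_building_scene(
    config: SceneConfig = SceneConfig(),
) -> tuple[np.ndarray, np.ndarray, PolygonSet]:
    """Generate one RGB scene, its binary mask and the exact vector polygons.

    Cul-de-sac clusters are placed first (rows of ``cul_de_sac_size`` houses
    ``cluster_gap`` pixels apart), then free-standing buildings, by rejection
    sampling against a ``min_gap`` buffer around existing footprints; an
    infeasible packing raises after bounded retries.  The mask is the
    rasterization of the polygons; buildings render brighter than the
    textured background.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.image_size
    polygons: list[sgeom.Polygon] = []

    def fits(poly: sgeom.Polygon, gap: float) -> bool:
        minx, miny, maxx, maxy = poly.bounds
        if minx < 1 or miny < 1 or maxx > W - 1 or maxy > H - 1:
            return False
        pad = poly.buffer(gap)
        return not any(pad.intersects(p) for p in polygons)

    lo, hi = config.building_size_range
    # Cul-de-sac clusters: a row of small houses with tiny gaps.
    for _ in range(config.cul_de_sac_count):
        size = max(4, lo)
        placed = False
        for _attempt in range(200):
            row_w = config.cul_de_sac_size * size + (config.cul_de_sac_size - 1) * config.cluster_gap
            if row_w > W - 2:
                raise ValueError("cul-de-sac cluster does not fit in the scene")
            r0 = rng.integers(1, max(2, H - size - 1))
            c0 = rng.integers(1, max(2, W - row_w - 1))
            houses = [
                _rect_polygon(r0, c0 + i * (size + config.cluster_gap), size, size, 0.0)
                for i in range(config.cul_de_sac_size)
            ]
            group = sgeom.MultiPolygon(houses)
            if fits(group.convex_hull, config.min_gap):
                polygons.extend(houses)
                placed = True
                break
        if not placed:
            raise ValueError("could not place a cul-de-sac cluster (packing infeasible)")

    n_free = max(0, config.n_buildings - config.cul_de_sac_count * config.cul_de_sac_size)
    for _ in range(n_free):
        placed = False
        for _attempt in range(500):
            h = int(rng.integers(lo, hi + 1))
            w = int(rng.integers(lo, hi + 1))
            r0 = int(rng.integers(1, max(2, H - h - 1)))
            c0 = int(rng.integers(1, max(2, W - w - 1)))
            angle = float(rng.uniform(-config.rotation_range, config.rotation_range)) if config.rotation_range else 0.0
            poly = _rect_polygon(r0, c0, h, w, angle)
            if fits(poly, config.min_gap):
                polygons.append(poly)
                placed = True
                break
        if not placed:
            raise ValueError("could not place a building (packing infeasible)")

    pset = PolygonSet(polygons)
    mask = rasterize_polygons(pset, (H, W))

    image = np.empty((H, W, 3))
    base = rng.uniform(0.15, 0.25, size=3)
    noise = rng.normal(0.0, 0.03, size=(H, W, 3))
    rr = np.linspace(0, 1, H)[:, None]
    cc = np.linspace(0, 1, W)[None, :]
    shade = 0.05 * np.sin(4 * math.pi * rr) * np.cos(4 * math.pi * cc)
    for ch in range(3):
        image[..., ch] = base[ch] + shade + noise[..., ch]
    roof = rng.uniform(0.65, 0.85, size=3)
    image[mask > 0] = roof + rng.normal(0.0, 0.02, size=(int(mask.sum()), 3))
    return np.clip(image, 0.0, 1.0), mask, pset


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    ops: Sequence[str] = ("flip_v", "flip_h", "rot90"),
    seed: int = 0,
    rot_degrees: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one seeded random geometric augmentation jointly to image and mask.

    ``ops`` names the randomized transforms to draw from: ``flip_v`` /
    ``flip_h`` (each applied with probability 1/2), ``rot90`` (a random
    quarter-turn count 0-3) and ``rot`` (a rotation uniform in
    ``[-rot_degrees, rot_degrees]``, or 0-360 when unset; bilinear for the
    image, nearest-neighbour for the mask, exposed corners filled with 0).
    The identical transform is applied to both arrays, so the mask stays
    binary and aligned.
    """
    valid = {"flip_v", "flip_h", "rot90", "rot"}
    for op in ops:
        if op not in valid:
            raise ValueError(f"unsupported augmentation op {op!r}")
    rng = np.random.default_rng(seed)
    img = np.asarray(image).copy()
    msk = np.asarray(mask).copy()
    if "flip_v" in ops and rng.random() < 0.5:
        img = np.flip(img, axis=0)
        msk = np.flip(msk, axis=0)
    if "flip_h" in ops and rng.random() < 0.5:
        img = np.flip(img, axis=1)
        msk = np.flip(msk, axis=1)
    if "rot90" in ops:
        k = int(rng.integers(0, 4))
        img = np.rot90(img, k, axes=(0, 1))
        msk = np.rot90(msk, k, axes=(0, 1))
    if "rot" in ops:
        from scipy import ndimage

        bound = 180.0 if rot_degrees is None else rot_degrees
        angle = float(rng.uniform(-bound, bound)) if rot_degrees is not None else float(rng.uniform(0.0, 360.0))
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=1, cval=0.0)
        msk = ndimage.rotate(msk, angle, axes=(1, 0), reshape=False, order=0, cval=0)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)
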