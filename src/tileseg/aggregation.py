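"""Stitching per-tile predictions into whole-image segmentations.

Two aggregation rules are implemented for overlapping tile predictions:

* **round after averaging** — per-pixel probabilities from all covering tiles
  are averaged, then the average is thresholded at 0.5;
* **round before averaging** — each tile is thresholded first, the binary
  tiles are averaged per pixel, and the fractional result is thresholded
  again at 0.5.

The two rules genuinely disagree: a pixel covered by tiles predicting 0.6 and
0.2 averages to 0.4 (background) under the first rule but rounds to {1, 0},
mean 0.5, foreground under the second.  Thresholding uses half-up ties
(value == threshold counts as foreground) throughout.

Also provided: stacking ordered 2D slice masks into a 3D volume, and PNG /
NIfTI mask I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .tile_geometry import TileLayout

__all__ = [
    "AggregationConfig",
    "binarize",
    "stitch_probabilities",
    "aggregate_round_after",
    "aggregate_round_before",
    "stack_slices",
    "write_mask_png",
    "read_mask_png",
    "write_mask_nifti",
    "read_mask_nifti",
]


@dataclass(frozen=True)
class AggregationConfig:
    """How overlapping tile predictions are fused into one binary mask.

    ``threshold`` applies half-up: a probability exactly equal to the
    threshold maps to foreground.  The final binarization of the
    round-before-averaging rule (fractions of {0,1} votes) always uses 0.5
    half-up — a strict-majority-or-tie vote.
    """

    mode: str = "round_after_averaging"
    threshold: float = 0.5
    tie_rule: str = "half_up"

    _MODES = ("round_after_averaging", "round_before_averaging")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {self._MODES}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.tie_rule != "half_up":
            raise ValueError(f"only the 'half_up' tie rule is supported, got {self.tie_rule!r}")


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to {0, 1}, half-up (>= threshold -> 1)."""
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def _check_tiles(tile_preds: Sequence[np.ndarray], layout: TileLayout) -> None:
    if len(tile_preds) != len(layout):
        raise ValueError(
            f"{len(tile_preds)} predictions supplied for a layout of {len(layout)} tiles"
        )
    for i, (pred, spec) in enumerate(zip(tile_preds, layout)):
        if tuple(np.shape(pred)) != spec.shape:
            raise ValueError(
                f"prediction {i} has shape {np.shape(pred)} but tile expects {spec.shape}"
            )


def stitch_probabilities(
    tile_preds: Sequence[np.ndarray], layout: TileLayout
) -> tuple[np.ndarray, dict]:
    """Average per-tile probability maps into a whole-image probability map.

    Each pixel receives the mean of the predictions from all tiles covering
    it.  Pixels covered by no tile are set to 0 and flagged in the returned
    report ``{"uncovered_count": int, "uncovered": bool grid}``.
    """
    _check_tiles(tile_preds, layout)
    acc = np.zeros(layout.image_shape, dtype=np.float64)
    counts = np.zeros(layout.image_shape, dtype=np.int64)
    for pred, spec in zip(tile_preds, layout):
        sl = spec.slices()
        acc[sl] += np.asarray(pred, dtype=np.float64)
        counts[sl] += 1
    covered = counts > 0
    out = np.zeros_like(acc)
    np.divide(acc, counts, out=out, where=covered)
    report = {"uncovered_count": int((~covered).sum()), "uncovered": ~covered}
    return out, report


def aggregate_round_after(
    tile_preds: Sequence[np.ndarray],
    layout: TileLayout,
    config: AggregationConfig | None = None,
) -> np.ndarray:
    """Average tile probabilities per pixel, then threshold the average."""
    config = config or AggregationConfig(mode="round_after_averaging")
    prob, _ = stitch_probabilities(tile_preds, layout)
    return binarize(prob, config.threshold)


def aggregate_round_before(
    tile_preds: Sequence[np.ndarray],
    layout: TileLayout,
    config: AggregationConfig | None = None,
) -> np.ndarray:
    """Threshold each tile, average the binary tiles, threshold the mean at 0.5."""
    config = config or AggregationConfig(mode="round_before_averaging")
    _check_tiles(tile_preds, layout)
    rounded = [binarize(p, config.threshold) for p in tile_preds]
    votes, _ = stitch_probabilities(rounded, layout)
    return binarize(votes, 0.5)


def aggregate(
    tile_preds: Sequence[np.ndarray],
    layout: TileLayout,
    config: AggregationConfig,
) -> np.ndarray:
    """Dispatch on ``config.mode``."""
    if config.mode == "round_after_averaging":
        return aggregate_round_after(tile_preds, layout, config)
    return aggregate_round_before(tile_preds, layout, config)


def stack_slices(slice_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Stack ordered 2D slice masks into a 3D volume (slice axis last)."""
    if len(slice_masks) == 0:
        raise ValueError("no slices to stack")
    base = np.shape(slice_masks[0])
    for k, m in enumerate(slice_masks):
        if np.shape(m) != base:
            raise ValueError(
                f"slice {k} has shape {np.shape(m)} but slice 0 has shape {base}"
            )
    return np.stack([np.asarray(m) for m in slice_masks], axis=-1)


# ---------------------------------------------------------------------------
# Mask I/O


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a 2D binary mask as an 8-bit PNG with foreground 255."""
    from PIL import Image

    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(str(path)).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_mask_nifti(path: str | Path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a 3D binary mask as NIfTI; identity affine unless one is supplied."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return (np.asarray(nib.load(str(path)).dataobj) > 0).astype(np.uint8)
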