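"""Prediction variance under flips and small input translations.

Convolutional segmentation models are often assumed to be equivariant to
flips and translations; pooling layers and zero padding break that
assumption.  A stack of ``d`` 2x2 max-pool layers is shift-equivariant only
for offsets that are multiples of its cumulative stride ``2**d`` (three
layers -> 8 pixels), and zero-padded borders make even flip symmetry fail.
This module measures those effects for *any* segmentation function:

* :func:`flip_variance` — predict on an image and its flipped copy, un-flip
  the second prediction and compare the two directly (cross-Dice + a
  trinary gray/white/black difference map);
* :func:`translation_variance` — predict on a center crop and on crops
  offset by a few pixels, compare predictions over the overlap region after
  aligning them in image coordinates;
* :func:`equivariance_check` — classify each offset as exactly equivariant
  or not, and :func:`impulse_variance_search` / :func:`restored_stride`,
  which find worst-case single-impulse inputs that expose pooling variance.

Predictors are callables mapping an image (channels-last) to a probability
or binary map; probabilistic outputs are binarized at 0.5 (half-up) before
comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .aggregation import binarize
from .metrics import dice
from .tile_geometry import TileSpec, extract_tile, offset_crop

__all__ = [
    "TrinaryDiffMap",
    "FlipReport",
    "TranslationReport",
    "trinary_diff",
    "flip_variance",
    "translation_variance",
    "equivariance_check",
    "impulse_variance_search",
    "restored_stride",
    "boundary_band",
]

AGREE, ONLY_A, ONLY_B = 0, 1, 2


@dataclass
class TrinaryDiffMap:
    """Per-pixel comparison of two binary predictions over a common region.

    ``codes`` holds 0 where the predictions agree, 1 where only prediction A
    is foreground, 2 where only prediction B is.  In the figure convention
    (A = reference/center prediction, B = transformed prediction) these are
    rendered gray, white and black respectively.
    """

    codes: np.ndarray = field(repr=False)
    n_agree: int = 0
    n_agree_fg: int = 0  # both-foreground subset of the agreements
    n_only_a: int = 0
    n_only_b: int = 0

    @property
    def region_size(self) -> int:
        return int(self.codes.size)

    @property
    def identical(self) -> bool:
        return self.n_agree == self.region_size

    @property
    def cross_dice(self) -> float:
        denom = 2 * self.n_agree_fg + self.n_only_a + self.n_only_b
        return 1.0 if denom == 0 else 2.0 * self.n_agree_fg / denom

    def to_image(self) -> np.ndarray:
        """Render as uint8 gray(128)/white(255)/black(0) pixels."""
        img = np.full(self.codes.shape, 128, dtype=np.uint8)
        img[self.codes == ONLY_A] = 255
        img[self.codes == ONLY_B] = 0
        return img

    def counts(self) -> dict:
        return {
            "agree": self.n_agree,
            "only_a": self.n_only_a,
            "only_b": self.n_only_b,
            "region_size": self.region_size,
        }


def trinary_diff(pred_a: np.ndarray, pred_b: np.ndarray) -> TrinaryDiffMap:
    """Code each pixel as agree / only-in-A / only-in-B."""
    a = np.asarray(pred_a) > 0
    b = np.asarray(pred_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    codes = np.zeros(a.shape, dtype=np.uint8)
    codes[a & ~b] = ONLY_A
    codes[~a & b] = ONLY_B
    return TrinaryDiffMap(
        codes=codes,
        n_agree=int(np.sum(a == b)),
        n_agree_fg=int(np.sum(a & b)),
        n_only_a=int(np.sum(a & ~b)),
        n_only_b=int(np.sum(~a & b)),
    )


def boundary_band(mask: np.ndarray, width: int = 3) -> np.ndarray:
    """Boolean band of pixels within ``width`` pixels of the mask boundary."""
    from scipy import ndimage

    m = np.asarray(mask) > 0
    dil = ndimage.binary_dilation(m, iterations=width)
    ero = ndimage.binary_erosion(m, iterations=width, border_value=1)
    return dil & ~ero


@dataclass
class FlipReport:
    """Flip-variance outcome for one image and one flip axis."""

    axis: int
    dice_normal: float
    dice_flipped: float
    cross_dice: float
    diff: TrinaryDiffMap
    boundary_band_fraction: float  # share of disagreements near the gt boundary

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "dice_normal": self.dice_normal,
            "dice_flipped": self.dice_flipped,
            "cross_dice": self.cross_dice,
            "diff_counts": self.diff.counts(),
            "boundary_band_fraction": self.boundary_band_fraction,
        }


def flip_variance(
    predict: Callable[[np.ndarray], np.ndarray],
    image: np.ndarray,
    gt: np.ndarray,
    axis: int = 0,
    band_width: int = 3,
) -> FlipReport:
    """Compare a model's prediction on an image with its prediction on the
    flipped image, after reversing the flip on the second prediction.

    For an exactly flip-equivariant predictor the two predictions coincide
    and the cross-Dice is 1; zero-padded convolutions generally break this.
    Both predictions are also scored against ``gt`` (flip-invariant metric
    bookkeeping), and the share of disagreeing pixels lying within
    ``band_width`` pixels of the ground-truth boundary is reported.
    """
    gt = np.asarray(gt)
    if not 0 <= axis < gt.ndim:
        raise ValueError(f"invalid flip axis {axis} for {gt.ndim}D masks")
    pred_n = binarize(predict(image))
    flipped = np.flip(image, axis=axis)
    pred_f = binarize(np.flip(predict(flipped), axis=axis))  # un-flip
    if pred_n.shape != gt.shape:
        raise ValueError(
            f"predictor output shape {pred_n.shape} does not match ground truth {gt.shape}"
        )
    diff = trinary_diff(pred_n, pred_f)
    disagree = diff.codes != AGREE
    n_dis = int(disagree.sum())
    if n_dis:
        band = boundary_band(gt, band_width)
        frac = float((disagree & band).sum() / n_dis)
    else:
        frac = 0.0
    return FlipReport(
        axis=axis,
        dice_normal=dice(pred_n, gt),
        dice_flipped=dice(pred_f, gt),
        cross_dice=dice(pred_n, pred_f),
        diff=diff,
        boundary_band_fraction=frac,
    )


def _center_offset(image_shape: Sequence[int], crop_shape: Sequence[int]) -> tuple[int, ...]:
    return tuple((n - c) // 2 for n, c in zip(image_shape, crop_shape))


def _output_lead(crop_shape: Sequence[int], out_shape: Sequence[int], output_stride: int) -> tuple[int, ...]:
    return tuple((c - o * output_stride) // 2 for c, o in zip(crop_shape, out_shape))


@dataclass
class TranslationReport:
    """Translation-variance outcome: one entry per non-zero offset vector."""

    base: TileSpec
    entries: dict[tuple[int, ...], dict] = field(default_factory=dict)

    @property
    def min_cross_dice(self) -> float:
        return min(e["cross_dice"] for e in self.entries.values())

    @property
    def all_identical(self) -> bool:
        return all(e["diff"].identical for e in self.entries.values())

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "entries": {
                ",".join(map(str, k)): {
                    "cross_dice": e["cross_dice"],
                    "overlap_shape": list(e["overlap_shape"]),
                    "diff_counts": e["diff"].counts(),
                }
                for k, e in self.entries.items()
            },
        }


def translation_variance(
    predict: Callable[[np.ndarray], np.ndarray],
    image: np.ndarray,
    crop_shape: Sequence[int],
    max_offset: int = 2,
    offsets: Sequence[Sequence[int]] | None = None,
) -> TranslationReport:
    """Predict on a center crop and on slightly offset crops; compare overlaps.

    For every non-zero offset vector with components in
    ``[-max_offset, max_offset]`` (24 offsets in 2D for ``max_offset=2``,
    unless an explicit ``offsets`` list is given), the predictions of the
    center crop and the offset crop are placed back into image coordinates
    and compared over the region both cover.  Predictors whose output is
    smaller than their input (valid padding) are aligned by their symmetric
    output margin.
    """
    crop_shape = tuple(int(c) for c in crop_shape)
    d = len(crop_shape)
    base = TileSpec(_center_offset(image.shape[:d], crop_shape), crop_shape)
    pred_base = binarize(predict(extract_tile(image, base)))
    lead = _output_lead(crop_shape, pred_base.shape, 1)
    out_shape = pred_base.shape

    if offsets is None:
        rng = range(-max_offset, max_offset + 1)
        offsets = [o for o in itertools.product(rng, repeat=d) if any(o)]
    report = TranslationReport(base=base)
    for delta in offsets:
        delta = tuple(int(x) for x in delta)
        moved, _ = offset_crop(image, base, delta)
        pred_off = binarize(predict(extract_tile(image, moved)))
        if pred_off.shape != out_shape:
            raise ValueError("predictor output shape changed between crops")
        # Output regions in image coordinates.
        start_a = tuple(o + l for o, l in zip(base.offset, lead))
        start_b = tuple(o + l for o, l in zip(moved.offset, lead))
        lo = tuple(max(a, b) for a, b in zip(start_a, start_b))
        hi = tuple(
            min(a + s, b + s) for a, b, s in zip(start_a, start_b, out_shape)
        )
        if any(h <= l for l, h in zip(lo, hi)):
            raise ValueError(f"offset {delta} leaves no prediction overlap")
        sl_a = tuple(slice(l - a, h - a) for l, h, a in zip(lo, hi, start_a))
        sl_b = tuple(slice(l - b, h - b) for l, h, b in zip(lo, hi, start_b))
        diff = trinary_diff(pred_base[sl_a], pred_off[sl_b])
        report.entries[delta] = {
            "cross_dice": dice(pred_base[sl_a], pred_off[sl_b]),
            "diff": diff,
            "overlap_shape": tuple(h - l for l, h in zip(lo, hi)),
        }
    return report


def equivariance_check(
    predict: Callable[[np.ndarray], np.ndarray],
    image: np.ndarray,
    crop_shape: Sequence[int],
    offsets: Sequence[Sequence[int] | int],
    stride: int,
    output_stride: int = 1,
) -> dict:
    """Classify each offset as exactly shift-equivariant or not.

    Two windows of ``crop_shape`` are taken from ``image`` at offset 0 and at
    each tested offset; their outputs are compared after aligning output
    indices at lag ``floor(s / output_stride)`` per axis (``output_stride``
    is the input-pixels-per-output-pixel ratio: 1 for a full encoder-decoder,
    ``2**n`` for a bare n-layer pooled stack).  At offsets that are multiples
    of ``stride`` an equivariant operator compares identical input regions,
    so "identical" is exact; elsewhere the compared regions are misaligned by
    ``s mod output_stride`` input pixels and pooling generally disagrees.

    Returns ``{"per_offset": {offset: "identical"|"differs"},
    "stride_multiples_identical": bool}``.
    """
    crop_shape = tuple(int(c) for c in crop_shape)
    d = len(crop_shape)
    base = TileSpec((0,) * d, crop_shape)
    out_a = binarize(predict(extract_tile(image, base)))
    per_offset: dict[tuple[int, ...], str] = {}
    verdict = True
    for off in offsets:
        s = (int(off),) + (0,) * (d - 1) if np.isscalar(off) else tuple(int(x) for x in off)
        moved, _ = offset_crop(image, base, s)
        out_b = binarize(predict(extract_tile(image, moved)))
        lags = tuple(si // output_stride for si in s)
        sl_a, sl_b = [], []
        ok = True
        for ax, lag in enumerate(lags):
            n = out_a.shape[ax]
            lo = max(0, lag)
            hi = min(n, n + lag)
            if hi <= lo:
                ok = False
                break
            sl_a.append(slice(lo, hi))
            sl_b.append(slice(lo - lag, hi - lag))
        if not ok:
            raise ValueError(f"offset {s} leaves no output overlap")
        same = bool(np.array_equal(out_a[tuple(sl_a)], out_b[tuple(sl_b)]))
        per_offset[s] = "identical" if same else "differs"
        if all(si % stride == 0 for si in s) and not same:
            verdict = False
    return {"per_offset": per_offset, "stride_multiples_identical": verdict}


def impulse_variance_search(
    predict: Callable[[np.ndarray], np.ndarray],
    length: int,
    window: int,
    shift: int,
    output_stride: int,
) -> int | None:
    """Exhaustively search single-impulse 1D strips for an equivariance violation.

    For each impulse position on a zero strip of ``length`` pixels, the
    windows ``[0, window)`` and ``[shift, shift + window)`` are evaluated and
    their outputs compared at lag ``floor(shift / output_stride)``.  Returns
    the first impulse position producing a disagreement, or None if the
    shift is exactly equivariant over all impulse inputs.
    """
    for pos in range(length):
        strip = np.zeros(length)
        strip[pos] = 1.0
        out_a = np.asarray(predict(strip[0:window]))
        out_b = np.asarray(predict(strip[shift : shift + window]))
        lag = shift // output_stride
        n = out_a.shape[0]
        lo, hi = max(0, lag), min(n, n + lag)
        if hi <= lo:
            raise ValueError(f"shift {shift} leaves no output overlap")
        if not np.array_equal(out_a[lo:hi], out_b[lo - lag : hi - lag]):
            return pos
    return None


def restored_stride(
    n_pool_layers: int,
    length: int = 64,
    max_shift: int = 16,
    pool_size: int = 2,
) -> dict:
    """Find the shift period at which a pooled stack becomes equivariant again.

    Composes ``n_pool_layers`` non-overlapping ``pool_size`` max-pool layers
    and, for each shift 1..``max_shift``, searches exhaustively over
    single-impulse strips for a disagreement between the pooled outputs of
    the unshifted and shifted windows.  Returns the per-shift verdicts and
    the smallest shift whose multiples are all equivariant while every
    non-multiple below ``max_shift`` is violable — the cumulative pooling
    stride (``pool_size ** n_pool_layers``).
    """
    from .unet import maxpool_stack

    stride = pool_size**n_pool_layers
    window = length - max_shift
    predict = lambda x: maxpool_stack(x, n_pool_layers, pool_size)
    violating: dict[int, int | None] = {}
    for s in range(1, max_shift + 1):
        violating[s] = impulse_variance_search(predict, length, window, s, stride)
    candidates = [
        p
        for p in range(1, max_shift + 1)
        if all(violating[s] is None for s in range(p, max_shift + 1, p))
        and all(violating[s] is not None for s in range(1, max_shift + 1) if s % p)
    ]
    return {
        "per_shift_violations": violating,
        "restored_stride": min(candidates) if candidates else None,
    }
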