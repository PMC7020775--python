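# tileseg

**Quantifying the adverse effects of image tiling on semantic segmentation.**

Large biomedical and satellite images are routinely too big for a
segmentation network's memory budget, so inference is run on *tiles* —
corner+center crops or overlapping sliding windows — whose predictions are
stitched back into a whole-image mask. Tiling is usually treated as
harmless because convolutional networks are assumed translation-equivariant.
They are not: every 2×2 max-pooling layer restricts exact equivariance to
shifts that are multiples of the cumulative stride (a stack of three pool
layers is shift-equivariant only at multiples of 2³ = 8 pixels), and
zero-padded convolutions inject border artifacts at every tile edge. The
whole image is therefore *not* the sum of its tiles.

`tileseg` is a library + CLI for measuring these effects, built for
researchers evaluating tiled inference pipelines on data shaped like
multi-modal brain MRI (4-channel 240×240×155 volumes with whole-tumour
masks) and building-footprint scenes (RGB images with vector ground truth):

- **tile_geometry** — corner+center layouts (5 tiles in 2D, 9 in 3D),
  sliding windows with fractional overlap (final tile clamped to the
  boundary), coverage maps, tile extraction, offset crops.
- **aggregation** — the two stitching rules for overlapping tiles:
  *rounding after averaging* (average probabilities, then threshold) and
  *rounding before averaging* (threshold tiles, then average the votes);
  they genuinely disagree on ambiguous pixels. Plus slice-stacking to 3D
  and PNG/NIfTI mask I/O.
- **metrics** — pixelwise Dice, `2·TP/(2·TP+FP+FN)`, and the instance-level
  polygon F1: masks are polygonized by pixel connectivity, proposals matched
  one-to-one to ground-truth polygons at IoU > 0.5, and F1 is the harmonic
  mean of precision and recall. A single blob covering two buildings keeps a
  high Dice but scores F1 = 0.
- **unet** — a from-scratch, deterministic, seeded U-Net *forward engine*
  (no framework, no training): exact shape arithmetic for valid vs
  zero-padded convolutions (a valid-padded depth-4 net maps 236×236 →
  52×52), input-admissibility verdicts derived from the pool/upsample/skip
  recurrence (dimensions must be divisible by 2^depth when same-padded),
  and the max-pooling variance mechanism itself.
- **variance** — flip variance (predict, flip-predict-unflip, cross-Dice +
  gray/white/black difference maps), translation variance over ±1/±2-pixel
  offset crops compared on their overlap, and exhaustive impulse searches
  that certify exactly where pooling breaks equivariance.
- **synthetic** — seeded phantom generators standing in for the real data:
  4-channel blob-bearing scan volumes with zero background outside a support
  ellipsoid, percentile-clip + non-zero z-score preprocessing, axial
  slicing, leakage-free patient-level splits, and building scenes with
  cul-de-sac clusters of ~6 houses and exact vector ground truth.
- **pipeline** — tiled vs whole-image comparison, tile-size sweeps
  (Dice + polygon F1 per tile size and aggregation mode), variance report
  bundles, and the `tileseg` CLI (`generate`, `infer`, `evaluate`,
  `variance`, `sweep`, `demo-maxpool`).

## Worked example

```python
import numpy as np
import tileseg as ts

# The five-tile corner+center layout of a 240x240 slice with 128x128 tiles.
layout = ts.corner_center_layout((240, 240), (128, 128))
print([t.offset for t in layout])
# [(0, 0), (0, 112), (112, 0), (112, 112), (56, 56)]

# Two tiles overlap on a pixel and predict 0.6 and 0.2: the two stitching
# rules disagree (mean 0.4 -> 0, but votes {1, 0} -> 0.5 -> 1).
from tileseg.tile_geometry import TileLayout, TileSpec
two = TileLayout((4, 6), (TileSpec((0, 0), (4, 4)), TileSpec((0, 2), (4, 4))), "sliding_window")
preds = [np.full((4, 4), 0.6), np.full((4, 4), 0.2)]
print("round after :", ts.aggregate_round_after(preds, two)[0, 3])   # 0
print("round before:", ts.aggregate_round_before(preds, two)[0, 3])  # 1

# A seeded (untrained, instance-normalized) depth-2 U-Net on a blob image:
# whole-image inference vs corner+center tiled inference.
rng = np.random.default_rng(0)
yy, xx = np.mgrid[0:64, 0:64]
gt = ((yy - 30) ** 2 + (xx - 34) ** 2 <= 12 ** 2).astype(np.uint8)
image = gt * 1.5 + 0.1 * rng.random((64, 64))
model = ts.build_unet(ts.UNetConfig(depth=2, in_channels=1, norm="instance", seed=3))
res = ts.compare_whole_vs_tiled(model, image, ts.corner_center_layout((64, 64), (32, 32)))
print("pixels where whole-image and tiled predictions disagree:", res["n_differing"])
# pixels where whole-image and tiled predictions disagree: 514

# Flip variance: predict on the flipped image, un-flip, compare directly.
flip = ts.flip_variance(ts.make_predictor(model), image, gt, axis=0)
print(f"flip cross-Dice: {flip.cross_dice:.4f}")
# flip cross-Dice: 0.4751

# Where does pooling restore equivariance?  Exhaustive impulse search over
# three stacked 2x2 max-pool layers:
print(ts.restored_stride(3, length=64, max_shift=16)["restored_stride"])
# 8
```

The disagreement counts and cross-Dice quantify exactly what tiling and
small input shifts change in the prediction; for an equivariant (pointwise)
model all of them collapse to zero disagreement and cross-Dice 1.0 — that
oracle is what the test suite pins the stitching path against.

## Scope

The engine is untrained by design: every quantity measured here (shape
arithmetic, admissibility moduli, equivariance breakpoints, aggregation
discrepancies) is a property of network *geometry*, not of learned weights.
Reproducing trained-model accuracy on the real MRI or satellite datasets is
out of scope; see `docs/methods.md` for the full account of the models,
parameters and limitations.
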