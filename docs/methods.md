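# Methods

## The problem being measured

Tiled ("sliding-window" or patch-based) inference runs a segmentation model
on windows of a large image and stitches the per-window outputs into one
mask. The package quantifies, under controlled synthetic conditions, the
ways this changes the prediction relative to whole-image inference:
max-pooling restricts exact shift equivariance to offsets that are
multiples of the cumulative stride 2^depth; zero-padded convolutions make
every tile border a source of artifacts; and the rule used to fuse
overlapping tile predictions changes labels on ambiguous pixels.

## Coordinate and array conventions

All coordinates are 0-based with half-open tile extents
`[offset, offset + shape)`. Arrays are channels-last: `(H, W[, C])` in 2D,
`(H, W, D[, C])` in 3D, with the axial slice axis last. These conventions
are used identically across every module.

## Tile layouts

*Corner+center*: the 2^d corner placements (offset 0 or image−tile per
axis) plus one centered tile at `floor((image − tile)/2)` per axis — the
floor matters only on odd margins (e.g. the 155-slice axis: margin 27 gives
center offset 13). Exact duplicate placements arising from degenerate
geometry are removed; corners are ordered lexicographically with the center
tile last, so layouts are deterministic. *Sliding window*: per-axis stride
`round(tile·(1−overlap))`, offsets `0, s, 2s, …`, with the final offset
clamped to `image − tile` so the boundary is always covered — clamping
(rather than zero-padding partial tiles) was chosen because it keeps every
tile a genuine image crop; the union always covers every pixel. Coverage
maps count covering tiles per pixel and are verified against a brute-force
interval-membership oracle in the tests.

## Aggregation rules

Both fusion rules average with uniform weight 1/coverage (no
distance-to-center weighting). *Round after averaging* thresholds the
per-pixel mean probability at 0.5; *round before averaging* thresholds each
tile first and then thresholds the per-pixel vote fraction at 0.5. All
thresholding is half-up (value == threshold → foreground); the final
binarization of the vote fraction uses half-up at 0.5, i.e. a tie between
covering tiles resolves to foreground. This tie rule is exposed in
`AggregationConfig` because fractional vote averages (e.g. exactly 2 tiles
disagreeing) are common at 50% overlap. Pixels covered by no tile are set
to background and reported rather than raised, so partial layouts remain
usable.

## Metrics

Dice is `2·TP/(2·TP + FP + FN)` with the empty-vs-empty case defined as
1.0 (the convention used by brain-tumour segmentation challenges for
foreground-free scans). Polygonization labels foreground components
(4-connectivity by default, 8 available) and merges each component's unit
pixel squares into an exact pixel-boundary polygon, so polygon area equals
pixel count and interior holes become rings that subtract from the area;
this exactness is what lets geometric IoU be validated against a
rasterized pixel-set IoU oracle to 1e-9. Polygon matching is greedy in
descending IoU with index tie-breaks, one-to-one, and counts a true
positive only for IoU *strictly* above 0.5. F1 is the harmonic mean of
precision and recall, 0 when undefined. Polygon coordinates are pixel
space; GeoJSON export accepts an optional coordinate-transform hook for
geo-referenced output but no projection logic is built in.

## The forward engine

The U-Net engine is written from scratch on numpy so that its outputs are
bit-reproducible functions of `(config, seed, input)` and so that its
*geometry* — not learned behaviour — is the object of study. Architecture:
`depth` levels of (`convs_per_block` convolutions, kernel `k`, channels
doubling from `base_filters`; 2×2 max-pool), a bottleneck block, and a
decoder of nearest-neighbour ×2 upsampling followed by a 1×1
channel-halving convolution, skip concatenation, and `convs_per_block`
convolutions, closed by a 1×1 sigmoid head. The 1×1 post-upsample
convolution (rather than 3×3) is what makes the valid-padding shape
recurrence per decoder level "double, then lose 2·(k−1)", which is the
recurrence that maps 236×236 → 52×52 and 572×572 → 388×388 at depth 4.
Valid-mode skip connections are center-cropped with the extra pixel (odd
differences) removed from the leading side.

Weights are drawn layer-by-layer in a fixed order from one seeded
generator, uniform(−a, a) with `a = sqrt(1/fan_in)`. The initialization
scheme is irrelevant to every property measured (shape arithmetic,
equivariance breakpoints, aggregation discrepancies are
weight-independent), but fixing it makes every number in the reports
reproducible. There is no training path, by design.

Input admissibility is decided by running the symbolic shape recurrence —
pooling floor-halves, upsampling doubles, skips must align (same mode) or
be croppable (valid mode) — rather than by testing divisibility directly;
for same-padded models the recurrence accepts exactly the shapes divisible
by 2^depth, and that modulus is included in rejection messages.

Instance normalization (per-channel mean/variance of the current input,
eps 1e-5) is available and is the default for the pipeline's seeded
evaluation models: an untrained, norm-free network drives the sigmoid to
one side of 0.5 everywhere, producing constant binary masks on which
tiling effects are invisible. Normalization keeps outputs straddling the
threshold. The trade-off is that instance norm depends on whole-window
statistics and therefore breaks *exact* equivariance; all equivariance
oracle tests use norm-free models and compare continuous outputs exactly.

## Variance protocols

*Flip variance* predicts on the image and on its flipped copy, un-flips
the second prediction (reversing the linear transform) and compares the
two directly: cross-Dice, a trinary difference map (gray = agree, white =
only in the reference prediction, black = only in the transformed one,
encoded 128/255/0 in PNG exports), and the share of disagreeing pixels
within a 3-pixel band of the ground-truth boundary. *Translation variance*
predicts on a centered crop and on crops offset by every non-zero vector
with components in ±`max_offset` (24 offsets in 2D at the default 2),
maps predictions back to image coordinates — valid-padded predictors are
aligned by their symmetric output margin — and compares the overlap.
"Identical" always means exact binary equality on the full overlap;
probabilistic outputs are binarized at 0.5 half-up first.

*Equivariance checks* compare the outputs of an unshifted and a shifted
window at output-index lag `floor(s/output_stride)`: at stride multiples
this aligns identical input regions (so "identical" holds for every
input), while at non-multiples the compared receptive fields are
misaligned by `s mod output_stride` pixels and a worst-case single-impulse
input exposes the difference. The exhaustive impulse search over a
64-pixel strip certifies, for three stacked 2×2 pools, that equivariance
holds exactly at multiples of 8 and fails at every other shift.

## Synthetic data

The scan phantom emulates the *geometry* of skull-stripped multi-modal
MRI: default 240×240×155 voxels, 4 channels, exactly zero outside a
centered support ellipsoid (axes 0.45/0.4/0.45 of the volume), smooth
low-frequency texture plus Gaussian noise (sd 0.05) inside, and 2 spherical
blobs (radius 8–20 voxels) whose union is the mask, each channel receiving
a distinct blob contrast so channels are non-redundant. It does not model
MRI physics, bias fields, or pathology appearance — so passing tests
demonstrate correctness of the measurement machinery, not performance on
real scans. Preprocessing clips each channel at its 98th percentile
(linear-interpolation percentile over all voxels of the channel —
parameterized, since restricting to non-zero voxels is equally defensible)
and z-scores using non-zero-voxel moments only, leaving background exactly
zero.

The building scene emulates footprint extraction: rectangles (default
12–40 px) placed by rejection sampling with a minimum 6-px buffer, plus
one cul-de-sac cluster of 6 houses separated by 3-px gaps — the
configuration that merges into a single blob under coarse predictions and
collapses polygon F1 while Dice stays high. Ground truth is the exact
vector polygon set; the mask is its rasterization by pixel-center
containment.

Splits are assigned at the unit (patient/scene) level with floor
allocation and the remainder to training, so slice-level leakage is
impossible by construction; 335 units at proportions 270/335, 30/335,
35/335 give (270, 30, 35).

All generators are pure functions of their seed.

## Problem sizes

The test and report defaults operate at phantom scale chosen to exercise
every code path with comfortable margins: 64×64 evaluation images with
depth-2 models and 16/32-px tiles, 48×48×20 volumes for preprocessing
checks, a 64-px strip for the exhaustive impulse searches, and one
default-geometry 240×240×155×4 phantom where the full-scale shape facts
are asserted. All headline geometric quantities (tile counts, 236→52,
modulus 2^depth, the 8-pixel pooling period, split sizes) are exact at any
scale.

## Known limitations

- Absolute segmentation quality of the seeded models is meaningless: they
  are untrained. Directional claims that depend on learned representations
  (e.g. larger tiles scoring better against ground truth) are not
  reproduced and not asserted.
- The flip-variance "null case" (cross-Dice 1 on a flip-symmetric input)
  holds only for flip-equivariant predictors; a generic predictor's
  prediction on a symmetric image need not be symmetric.
- Polygonization under 8-connectivity represents corner-touching component
  parts as separate rings/features; the default 4-connectivity has no such
  ambiguity.
- Sliding-window layouts handle image boundaries by clamping the final
  tile, not by padding; models requiring modulus-aligned inputs therefore
  constrain usable tile sizes, and a 650×650 image is rejected outright by
  a 5-level same-padded model (modulus 32) rather than silently resized.
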