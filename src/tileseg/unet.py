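"""A deterministic, from-scratch U-Net forward engine (no framework, no training).

The engine exists to expose the *geometry* of encoder-decoder segmentation
networks — shape arithmetic under valid vs zero-padded convolutions, the
divisibility constraints that max-pooling imposes on input sizes, and the
translational variance that pooling introduces — with bit-reproducible
outputs.  Weights are drawn once from a seeded generator and never trained:
every property this package measures (shape recurrences, equivariance and
its violations, whole-image vs tiled disagreement) is independent of the
particular weight values but requires that they be fixed and reproducible.

Architecture: ``depth`` resolution levels, each with ``convs_per_block``
convolutions (kernel ``k``, channels doubling per level from
``base_filters``) followed by 2x max-pooling; a bottleneck block; a decoder
that upsamples by nearest-neighbour x2 + 1x1 convolution, concatenates the
skip connection (center-cropped in valid mode) and applies
``convs_per_block`` convolutions; and a 1x1 sigmoid head producing a
single-channel probability map.

Shape arithmetic (per spatial axis):

* ``same_zero`` padding preserves sizes through convolutions, so an input is
  admissible iff every pooling halves exactly and every upsampling restores
  the skip's size — equivalently, iff each dimension is divisible by
  ``2**depth``.
* ``valid`` padding shrinks each axis by ``k - 1`` per convolution; a
  depth-4, two-3x3-convs-per-level network maps 236 -> 52 and 572 -> 388.

Arrays are channels-last; spatial dims may be 2 or 3.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "UNetConfig",
    "UNetModel",
    "ShapeVerdict",
    "build_unet",
    "validate_input_shape",
    "valid_output_shape",
    "maxpool",
    "maxpool_stack",
    "forward",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters of the forward engine.

    ``depth`` is the number of 2x pooling levels, so the cumulative encoder
    stride is ``2**depth`` — the modulus that input dimensions must respect
    under ``same_zero`` padding.  ``pad_mode`` is ``"same_zero"``
    (zero-padded convolutions, output size == input size) or ``"valid"``
    (no padding, borders are progressively lost).
    """

    ndim: int = 2
    depth: int = 4
    base_filters: int = 8
    in_channels: int = 1
    pad_mode: str = "same_zero"
    kernel: int = 3
    convs_per_block: int = 2
    activation: str = "relu"
    norm: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError(f"ndim must be 2 or 3, got {self.ndim}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValueError(f"kernel must be odd and positive, got {self.kernel}")
        if self.pad_mode not in ("same_zero", "valid"):
            raise ValueError(f"pad_mode must be 'same_zero' or 'valid', got {self.pad_mode!r}")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.norm not in ("none", "instance"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.base_filters < 1 or self.in_channels < 1 or self.convs_per_block < 1:
            raise ValueError("base_filters, in_channels and convs_per_block must be >= 1")

    @property
    def cumulative_stride(self) -> int:
        return 2**self.depth

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, text: str) -> "UNetConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ShapeVerdict:
    accepted: bool
    reason: str = ""
    modulus: int | None = None

    def __bool__(self) -> bool:
        return self.accepted


# ---------------------------------------------------------------------------
# Primitive ops


def _activate(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    return np.where(x >= 0.0, x, 0.01 * x)  # leaky_relu


def _instance_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    axes = tuple(range(x.ndim - 1))
    mu = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, pad: bool) -> np.ndarray:
    """N-d cross-correlation, channels-last; w has shape (k,)*nd + (Cin, Cout)."""
    nd = w.ndim - 2
    k = w.shape[0]
    if pad and k > 1:
        p = k // 2
        x = np.pad(x, [(p, p)] * nd + [(0, 0)])
    if k == 1:
        return np.tensordot(x, w.reshape(w.shape[-2], w.shape[-1]), axes=([-1], [0])) + b
    for ax in range(nd):
        if x.shape[ax] < k:
            raise ValueError(f"input too small for kernel {k} on axis {ax}")
    win = sliding_window_view(x, (k,) * nd, axis=tuple(range(nd)))
    # win: out_spatial... , Cin, k... ; w: k..., Cin, Cout
    w_perm = np.moveaxis(w, -2, 0)  # Cin, k..., Cout
    out = np.tensordot(win, w_perm, axes=(list(range(nd, 2 * nd + 1)), list(range(nd + 1))))
    return out + b


def maxpool(x: np.ndarray, k: int = 2, spatial_ndim: int | None = None) -> np.ndarray:
    """Non-overlapping k-window max pooling with floor semantics.

    Trailing remainder rows/columns that do not fill a window are dropped.
    All axes are pooled unless ``spatial_ndim`` restricts pooling to the
    leading axes (channels-last feature maps).
    """
    x = np.asarray(x)
    nd = spatial_ndim if spatial_ndim is not None else x.ndim
    for ax in range(nd):
        if x.shape[ax] < k:
            raise ValueError(f"axis {ax} of size {x.shape[ax]} smaller than pool size {k}")
    out = x
    for ax in range(nd):
        n = (out.shape[ax] // k) * k
        out = np.take(out, np.arange(n), axis=ax)
        new_shape = out.shape[:ax] + (n // k, k) + out.shape[ax + 1 :]
        out = out.reshape(new_shape).max(axis=ax + 1)
    return out


def maxpool_stack(x: np.ndarray, n_layers: int, k: int = 2, spatial_ndim: int | None = None) -> np.ndarray:
    """Apply ``n_layers`` successive max-pool layers (cumulative stride k**n)."""
    for _ in range(n_layers):
        x = maxpool(x, k, spatial_ndim)
    return x


def _upsample_nn(x: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(nd):
        x = np.repeat(x, 2, axis=ax)
    return x


def _center_crop(x: np.ndarray, target: Sequence[int], nd: int) -> np.ndarray:
    """Symmetric center crop of the leading ``nd`` axes; when the total crop
    is odd, the extra pixel is removed from the leading side."""
    sl = []
    for ax in range(nd):
        diff = x.shape[ax] - target[ax]
        if diff < 0:
            raise ValueError(f"cannot crop axis {ax} from {x.shape[ax]} to {target[ax]}")
        lead = (diff + 1) // 2
        sl.append(slice(lead, lead + target[ax]))
    return x[tuple(sl)]


# ---------------------------------------------------------------------------
# Shape recurrence


def _shape_trace(config: UNetConfig, input_shape: Sequence[int]) -> dict:
    """Run the per-axis shape recurrence through encoder, bottleneck and
    decoder; raises ValueError when a dimension collapses or (valid mode)
    a skip cannot be cropped, returns the stage-by-stage shapes otherwise."""
    shape = tuple(int(s) for s in input_shape)
    if len(shape) != config.ndim:
        raise ValueError(f"expected {config.ndim} spatial dims, got {len(shape)}")
    loss = (config.kernel - 1) * config.convs_per_block  # per axis, per conv block
    same = config.pad_mode == "same_zero"

    def conv_block(s: tuple[int, ...], stage: str) -> tuple[int, ...]:
        if same:
            return s
        out = tuple(d - loss for d in s)
        if any(d <= 0 for d in out):
            raise ValueError(f"input too small: dimension collapses in {stage} (shape {s})")
        return out

    skips: list[tuple[int, ...]] = []
    trace = {"input": shape}
    for level in range(config.depth):
        shape = conv_block(shape, f"encoder level {level}")
        skips.append(shape)
        if any(d < 2 for d in shape):
            raise ValueError(f"input too small: cannot pool at encoder level {level} (shape {shape})")
        shape = tuple(d // 2 for d in shape)
    shape = conv_block(shape, "bottleneck")
    trace["bottleneck"] = shape
    for level in reversed(range(config.depth)):
        shape = tuple(2 * d for d in shape)
        skip = skips[level]
        if same:
            if shape != skip:
                raise ValueError(
                    f"skip connection at level {level} has shape {skip} but the "
                    f"upsampled decoder path has {shape}; input dimensions must be "
                    f"divisible by {config.cumulative_stride}"
                )
        else:
            if any(d > s for d, s in zip(shape, skip)):
                raise ValueError(
                    f"decoder shape {shape} exceeds skip shape {skip} at level {level}"
                )
        shape = conv_block(shape, f"decoder level {level}")
    trace["output"] = shape
    trace["skips"] = skips
    return trace


def valid_output_shape(config: UNetConfig, input_shape: Sequence[int]) -> tuple[int, ...]:
    """Output spatial shape of a valid-padded model for a given input shape.

    Evaluates the recurrence in which each convolution shrinks every axis by
    ``kernel - 1``, pooling floor-halves, upsampling doubles and skips are
    center-cropped.  A depth-4 kernel-3 network maps 236 -> 52.
    """
    if config.pad_mode != "valid":
        raise ValueError("valid_output_shape requires pad_mode='valid'")
    return _shape_trace(config, input_shape)["output"]


def validate_input_shape(config: UNetConfig, image_shape: Sequence[int]) -> ShapeVerdict:
    """Decide whether a spatial shape is admissible for this architecture.

    The verdict is determined by running the full shape recurrence (pooling,
    upsampling, skip alignment), not by a divisibility shortcut; for
    ``same_zero`` padding the recurrence aligns exactly when each dimension
    is divisible by ``2**depth``, and that modulus is reported on rejection.
    """
    try:
        _shape_trace(config, image_shape)
    except ValueError as e:
        return ShapeVerdict(False, str(e), modulus=config.cumulative_stride)
    return ShapeVerdict(True, "accepted", modulus=config.cumulative_stride)


# ---------------------------------------------------------------------------
# Model


@dataclass(frozen=True)
class UNetModel:
    """Seeded weights plus a pure forward function (same input -> same output)."""

    config: UNetConfig
    weights: dict[str, np.ndarray] = field(repr=False)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return forward(self, image)

    def weight_checksum(self) -> str:
        crc = 0
        for name in sorted(self.weights):
            crc = zlib.crc32(self.weights[name].tobytes(), crc)
        return f"{crc:08x}"

    def save_weights(self, path: str | Path) -> None:
        """Flat binary container (concatenated float64 buffers) + JSON manifest."""
        path = Path(path)
        manifest = []
        with open(path, "wb") as fh:
            offset = 0
            for name in sorted(self.weights):
                arr = np.ascontiguousarray(self.weights[name], dtype=np.float64)
                buf = arr.tobytes()
                fh.write(buf)
                manifest.append(
                    {
                        "name": name,
                        "shape": list(arr.shape),
                        "offset": offset,
                        "crc32": f"{zlib.crc32(buf):08x}",
                    }
                )
                offset += len(buf)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"config": self.config.__dict__, "tensors": manifest})
        )

    @classmethod
    def load_weights(cls, path: str | Path) -> "UNetModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        config = UNetConfig(**meta["config"])
        raw = path.read_bytes()
        weights = {}
        for t in meta["tensors"]:
            n = int(np.prod(t["shape"])) * 8
            buf = raw[t["offset"] : t["offset"] + n]
            if f"{zlib.crc32(buf):08x}" != t["crc32"]:
                raise ValueError(f"checksum mismatch for tensor {t['name']}")
            weights[t["name"]] = np.frombuffer(buf, dtype=np.float64).reshape(t["shape"]).copy()
        return cls(config, weights)


def _layer_plan(config: UNetConfig) -> list[tuple[str, int, int, int]]:
    """Ordered (name, kernel, in_ch, out_ch) conv layers of the architecture."""
    plan: list[tuple[str, int, int, int]] = []
    k = config.kernel
    ch_in = config.in_channels
    for level in range(config.depth):
        ch_out = config.base_filters * 2**level
        for j in range(config.convs_per_block):
            plan.append((f"enc{level}_conv{j}", k, ch_in, ch_out))
            ch_in = ch_out
    ch_bn = config.base_filters * 2**config.depth
    for j in range(config.convs_per_block):
        plan.append((f"bottleneck_conv{j}", k, ch_in, ch_bn))
        ch_in = ch_bn
    for level in reversed(range(config.depth)):
        ch_out = config.base_filters * 2**level
        plan.append((f"dec{level}_up", 1, ch_in, ch_out))
        ch_in = 2 * ch_out  # after skip concatenation
        for j in range(config.convs_per_block):
            plan.append((f"dec{level}_conv{j}", k, ch_in, ch_out))
            ch_in = ch_out
    plan.append(("head", 1, ch_in, 1))
    return plan


def build_unet(config: UNetConfig) -> UNetModel:
    """Draw all weights from one seeded generator, in fixed layer order.

    Each layer's weights and biases are uniform(-a, a) with
    ``a = sqrt(1 / fan_in)`` and ``fan_in = kernel**ndim * in_channels``; the
    same config and seed therefore reproduce bit-identical weights.
    """
    rng = np.random.default_rng(config.seed)
    weights: dict[str, np.ndarray] = {}
    for name, k, cin, cout in _layer_plan(config):
        fan_in = (k**config.ndim) * cin
        a = np.sqrt(1.0 / fan_in)
        w_shape = (k,) * config.ndim + (cin, cout)
        weights[f"{name}.w"] = rng.uniform(-a, a, size=w_shape)
        weights[f"{name}.b"] = rng.uniform(-a, a, size=(cout,))
    return UNetModel(config, weights)


def forward(model: UNetModel, image: np.ndarray) -> np.ndarray:
    """Run the encoder-decoder forward pass; returns a probability map.

    The input is channels-last with ``config.in_channels`` channels (a bare
    spatial array is accepted when ``in_channels == 1``); the output is the
    sigmoid head's single channel with the channel axis squeezed, values in
    (0, 1).  Output spatial shape equals the input's for ``same_zero``
    padding and follows :func:`valid_output_shape` for ``valid``.
    """
    cfg = model.config
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == cfg.ndim:
        if cfg.in_channels != 1:
            raise ValueError(f"model expects {cfg.in_channels} channels, got a bare spatial array")
        x = x[..., np.newaxis]
    if x.ndim != cfg.ndim + 1 or x.shape[-1] != cfg.in_channels:
        raise ValueError(
            f"expected channels-last input with {cfg.in_channels} channels and "
            f"{cfg.ndim} spatial dims, got shape {x.shape}"
        )
    verdict = validate_input_shape(cfg, x.shape[: cfg.ndim])
    if not verdict:
        raise ValueError(f"input shape rejected: {verdict.reason}")

    same = cfg.pad_mode == "same_zero"
    W = model.weights

    def block(x: np.ndarray, prefix: str) -> np.ndarray:
        for j in range(cfg.convs_per_block):
            x = _conv(x, W[f"{prefix}_conv{j}.w"], W[f"{prefix}_conv{j}.b"], pad=same)
            if cfg.norm == "instance":
                x = _instance_norm(x)
            x = _activate(x, cfg.activation)
        return x

    skips: list[np.ndarray] = []
    for level in range(cfg.depth):
        x = block(x, f"enc{level}")
        skips.append(x)
        x = maxpool(x, 2, spatial_ndim=cfg.ndim)
    x = block(x, "bottleneck")
    for level in reversed(range(cfg.depth)):
        x = _upsample_nn(x, cfg.ndim)
        x = _conv(x, W[f"dec{level}_up.w"], W[f"dec{level}_up.b"], pad=same)
        skip = skips[level]
        if not same:
            skip = _center_crop(skip, x.shape[: cfg.ndim], cfg.ndim)
        x = np.concatenate([skip, x], axis=-1)
        x = block(x, f"dec{level}")
    logits = _conv(x, W["head.w"], W["head.b"], pad=same)
    prob = 1.0 / (1.0 + np.exp(-logits))
    return prob[..., 0]
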