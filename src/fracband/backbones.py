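"""Frozen convolutional feature extractors.

Two backbones support numeric forward passes in pure numpy:

* ``tiny`` — three conv/ReLU/maxpool blocks with random (seeded) weights;
  fast enough to train and test the full pipeline on a CPU.
* ``efficientnetv2b2`` — the EfficientNetV2-B2 feature extractor built from
  the published base stage configuration with width coefficient 1.1 and
  depth coefficient 1.2 (randomly initialised; no pretrained weights are
  shipped or downloaded).  On a 128x128x3 input its final feature map is
  4x4 with 1408 channels.

The remaining classification backbones from the ablation grid are
registered structurally: their stage topology (strides, padding, output
channels) supports exact feature-shape computation, but no numeric
forward pass is provided.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np

__all__ = [
    "BACKBONE_REGISTRY",
    "Backbone",
    "EfficientNetV2B2Backbone",
    "StructuralBackbone",
    "TinyConvBackbone",
    "conv2d",
    "create_backbone",
    "depthwise_conv2d",
    "maxpool2d",
]


# ---------------------------------------------------------------------------
# numpy layer primitives (forward only; backbones are frozen)
# ---------------------------------------------------------------------------

def _pad_same(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    _, h, w, _ = x.shape
    out_h, out_w = math.ceil(h / stride), math.ceil(w / stride)
    pad_h = max((out_h - 1) * stride + kh - h, 0)
    pad_w = max((out_w - 1) * stride + kw - w, 0)
    return np.pad(
        x,
        ((0, 0), (pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
    )


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, padding: str = "same") -> np.ndarray:
    """NHWC convolution with a (kh, kw, cin, cout) kernel."""
    kh, kw = w.shape[:2]
    if padding == "same":
        x = _pad_same(x, kh, kw, stride)
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]
    return np.tensordot(windows, w, axes=([4, 5, 3], [0, 1, 2]))


def depthwise_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, padding: str = "same") -> np.ndarray:
    """Per-channel NHWC convolution with a (kh, kw, c) kernel."""
    kh, kw = w.shape[:2]
    if padding == "same":
        x = _pad_same(x, kh, kw, stride)
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]
    return np.einsum("nhwckl,klc->nhwc", windows, w)


def maxpool2d(x: np.ndarray, size: int = 2, stride: int | None = None) -> np.ndarray:
    stride = stride or size
    windows = np.lib.stride_tricks.sliding_window_view(x, (size, size), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]
    return windows.max(axis=(4, 5))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe logistic
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def _swish(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _he_kernel(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float64) * np.sqrt(2.0 / fan_in)


# ---------------------------------------------------------------------------
# Backbone interface
# ---------------------------------------------------------------------------

class Backbone:
    """Frozen feature extractor: maps (n, H, W, 3) to (n, fh, fw, fc)."""

    name: str = "base"
    supports_forward: bool = True

    def feature_shape(self, input_hw: tuple[int, int]) -> tuple[int, int, int]:
        raise NotImplementedError

    def features(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def checksum(self) -> str:
        digest = hashlib.sha256()
        for p in self.parameters():
            digest.update(np.ascontiguousarray(p).tobytes())
        return digest.hexdigest()


class TinyConvBackbone(Backbone):
    """Three random-weight conv/ReLU/maxpool blocks; 128 -> 16 spatial."""

    name = "tiny"

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = (8, 16, 32)):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.kernels: list[np.ndarray] = []
        cin = 3
        for cout in self.channels:
            self.kernels.append(_he_kernel(rng, (3, 3, cin, cout), fan_in=9 * cin))
            cin = cout

    def feature_shape(self, input_hw: tuple[int, int]) -> tuple[int, int, int]:
        h, w = input_hw
        for _ in self.channels:
            h, w = math.ceil(h / 1) // 2, math.ceil(w / 1) // 2
        return h, w, self.channels[-1]

    def features(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float64)
        for kernel in self.kernels:
            out = np.maximum(conv2d(out, kernel, stride=1, padding="same"), 0.0)
            out = maxpool2d(out, 2)
        return out

    def parameters(self) -> list[np.ndarray]:
        return list(self.kernels)


# ---------------------------------------------------------------------------
# EfficientNetV2-B2
# ---------------------------------------------------------------------------

# Base (B0) stage configuration; B2 applies width 1.1 / depth 1.2 scaling.
_V2_BASE_BLOCKS = [
    # conv_type, kernel, repeats, in_f, out_f, expand, se_ratio, stride
    ("fused", 3, 1, 32, 16, 1, 0.0, 1),
    ("fused", 3, 2, 16, 32, 4, 0.0, 2),
    ("fused", 3, 2, 32, 48, 4, 0.0, 2),
    ("mbconv", 3, 3, 48, 96, 4, 0.25, 2),
    ("mbconv", 3, 5, 96, 112, 6, 0.25, 1),
    ("mbconv", 3, 8, 112, 192, 6, 0.25, 2),
]


def round_filters(filters: float, width_coefficient: float, divisor: int = 8) -> int:
    """Channel rounding used by the compound-scaling family: scale by the
    width coefficient and round to the nearest multiple of ``divisor``,
    never dropping below 90% of the scaled value."""
    filters *= width_coefficient
    new_filters = max(divisor, int(filters + divisor / 2) // divisor * divisor)
    if new_filters < 0.9 * filters:
        new_filters += divisor
    return int(new_filters)


def round_repeats(repeats: int, depth_coefficient: float) -> int:
    return int(math.ceil(depth_coefficient * repeats))


class EfficientNetV2B2Backbone(Backbone):
    """EfficientNetV2-B2 feature extractor (head removed, random weights).

    Stem conv (stride 2) -> six fused-MBConv / MBConv stages -> 1x1 top
    conv.  All BN layers act as identity at inference with default
    affine parameters and are therefore omitted.
    """

    name = "efficientnetv2b2"
    width_coefficient = 1.1
    depth_coefficient = 1.2

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self._params: list[np.ndarray] = []
        self.blocks: list[dict] = []

        def kernel(kh, kw, cin, cout):
            k = _he_kernel(rng, (kh, kw, cin, cout), fan_in=kh * kw * cin)
            self._params.append(k)
            return k

        def dw_kernel(kh, kw, c):
            k = _he_kernel(rng, (kh, kw, c), fan_in=kh * kw)
            self._params.append(k)
            return k

        self.stem_filters = round_filters(_V2_BASE_BLOCKS[0][3], self.width_coefficient)
        self.stem_kernel = kernel(3, 3, 3, self.stem_filters)

        cin = self.stem_filters
        for conv_type, k, repeats, in_f, out_f, expand, se_ratio, stride in _V2_BASE_BLOCKS:
            out_f = round_filters(out_f, self.width_coefficient)
            for rep in range(round_repeats(repeats, self.depth_coefficient)):
                s = stride if rep == 0 else 1
                expanded = cin * expand
                block: dict = {
                    "type": conv_type,
                    "stride": s,
                    "residual": s == 1 and cin == out_f,
                }
                if conv_type == "fused":
                    if expand != 1:
                        block["expand"] = kernel(k, k, cin, expanded)
                        block["project"] = kernel(1, 1, expanded, out_f)
                    else:
                        block["single"] = kernel(k, k, cin, out_f)
                else:
                    if expand != 1:
                        block["expand"] = kernel(1, 1, cin, expanded)
                    block["depthwise"] = dw_kernel(k, k, expanded)
                    if se_ratio > 0:
                        se_filters = max(1, int(cin * se_ratio))
                        block["se_reduce"] = kernel(1, 1, expanded, se_filters)
                        block["se_expand"] = kernel(1, 1, se_filters, expanded)
                    block["project"] = kernel(1, 1, expanded, out_f)
                self.blocks.append(block)
                cin = out_f

        self.top_filters = round_filters(1280, self.width_coefficient)
        self.top_kernel = kernel(1, 1, cin, self.top_filters)

    def feature_shape(self, input_hw: tuple[int, int]) -> tuple[int, int, int]:
        h, w = input_hw
        h, w = math.ceil(h / 2), math.ceil(w / 2)  # stem
        for block in self.blocks:
            s = block["stride"]
            h, w = math.ceil(h / s), math.ceil(w / s)
        return h, w, self.top_filters

    def features(self, x: np.ndarray) -> np.ndarray:
        out = _swish(conv2d(np.asarray(x, dtype=np.float64), self.stem_kernel, stride=2))
        for block in self.blocks:
            inp = out
            if block["type"] == "fused":
                if "single" in block:
                    out = _swish(conv2d(out, block["single"], stride=block["stride"]))
                else:
                    out = _swish(conv2d(out, block["expand"], stride=block["stride"]))
                    out = conv2d(out, block["project"], stride=1)
            else:
                if "expand" in block:
                    out = _swish(conv2d(out, block["expand"], stride=1))
                out = _swish(depthwise_conv2d(out, block["depthwise"], stride=block["stride"]))
                if "se_reduce" in block:
                    se = out.mean(axis=(1, 2), keepdims=True)
                    se = _swish(conv2d(se, block["se_reduce"]))
                    se = _sigmoid(conv2d(se, block["se_expand"]))
                    out = out * se
                out = conv2d(out, block["project"], stride=1)
            if block["residual"]:
                out = out + inp
        return _swish(conv2d(out, self.top_kernel, stride=1))

    def parameters(self) -> list[np.ndarray]:
        return list(self._params)


# ---------------------------------------------------------------------------
# Structural (shape-only) backbones
# ---------------------------------------------------------------------------

class StructuralBackbone(Backbone):
    """Topology-only backbone: exact output shapes, no numeric forward.

    ``ops`` is the ordered list of spatial operations as
    (kernel, stride, padding) triples; ``out_channels`` is the channel
    count of the final feature map.
    """

    supports_forward = False

    def __init__(self, name: str, ops: list[tuple[int, int, str]], out_channels: int):
        self.name = name
        self.ops = ops
        self.out_channels = out_channels

    def feature_shape(self, input_hw: tuple[int, int]) -> tuple[int, int, int]:
        h, w = input_hw
        for kernel, stride, padding in self.ops:
            if padding == "same":
                h, w = math.ceil(h / stride), math.ceil(w / stride)
            else:
                h = (h - kernel) // stride + 1
                w = (w - kernel) // stride + 1
        return h, w, self.out_channels

    def features(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError(
            f"backbone {self.name!r} is registered for architecture/shape "
            "inspection only; use 'tiny' or 'efficientnetv2b2' for a numeric "
            "forward pass"
        )


def _stride32_same(name: str, out_channels: int) -> StructuralBackbone:
    return StructuralBackbone(name=name, ops=[(3, 2, "same")] * 5, out_channels=out_channels)


_INCEPTIONV3_OPS = [
    (3, 2, "valid"), (3, 1, "valid"), (3, 1, "same"), (3, 2, "valid"),
    (1, 1, "valid"), (3, 1, "valid"), (3, 2, "valid"),
    (3, 2, "valid"), (3, 2, "valid"),
]

BACKBONE_REGISTRY: dict[str, type | object] = {
    "tiny": TinyConvBackbone,
    "efficientnetv2b2": EfficientNetV2B2Backbone,
    "resnet50": lambda seed=0: _stride32_same("resnet50", 2048),
    "densenet201": lambda seed=0: _stride32_same("densenet201", 1920),
    "mobilenetv2": lambda seed=0: _stride32_same("mobilenetv2", 1280),
    "xception": lambda seed=0: _stride32_same("xception", 2048),
    "vgg16": lambda seed=0: _stride32_same("vgg16", 512),
    "inceptionv3": lambda seed=0: StructuralBackbone(
        name="inceptionv3", ops=list(_INCEPTIONV3_OPS), out_channels=2048
    ),
}


def create_backbone(backbone_id: str, seed: int = 0) -> Backbone:
    key = backbone_id.lower()
    if key not in BACKBONE_REGISTRY:
        raise ValueError(
            f"unregistered backbone {backbone_id!r}; available: {sorted(BACKBONE_REGISTRY)}"
        )
    return BACKBONE_REGISTRY[key](seed=seed)
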