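"""The image-domain attenuation-correction network.

A 20-layer 3D residual convolutional network mapping a non-AC PET volume to
a predicted attenuation-corrected volume at unchanged resolution.  The first
seven layers use ordinary 3x3x3 kernels; the remaining layers use dilated
3x3x3 kernels (rates 2 then 4) to grow the receptive field enough to sense
the body-scale attenuation context that determines how much each voxel's
counts were suppressed.  Identity residual connections join every two
layers; batch normalization and ReLU are interleaved.  The final layer is a
linear convolution producing one output channel — attenuation correction is
voxel-wise intensity regression, so no squashing output nonlinearity is
applied by default (a softmax head remains available as a configuration
option for fidelity experiments).

Volumes are normalized per case by their 99th-percentile intensity before
entering the network and the scale is inverted on output, so training is
stable across simulated injected-dose variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import VoxelGrid
from .nn import BatchNorm3d, Conv3d, ReLU

DEFAULT_DILATION_SCHEDULE = (((8, 14), 2), ((15, 20), 4))


@dataclass
class ModelSpec:
    """Architecture description.

    ``dilation_schedule`` lists ``((first_layer, last_layer), dilation)``
    ranges (1-based, inclusive) covering every layer after the
    ``early_layers`` dilation-1 block, up to ``n_layers``.  Layer
    ``n_layers`` doubles as the linear one-channel output head.
    """

    n_layers: int = 20
    early_layers: int = 7
    dilation_schedule: tuple = DEFAULT_DILATION_SCHEDULE
    kernel: tuple[int, int, int] = (3, 3, 3)
    base_features: int = 16
    residual_period: int = 2
    norm: bool = True
    activation: str = "relu"
    output_head: str = "linear"
    #: add the input back onto the head output, so the trunk learns the
    #: additive attenuation correction rather than the absolute image —
    #: the "skip connections preserving spatial information" alongside the
    #: per-block residual connections
    global_skip: bool = True

    def __post_init__(self) -> None:
        if self.kernel != (3, 3, 3):
            raise ValueError("only 3x3x3 kernels are supported")
        if self.output_head not in ("linear", "softmax"):
            raise ValueError("output_head must be 'linear' or 'softmax'")
        if self.residual_period != 2:
            raise ValueError("residual connections are wired every two layers")
        if self.activation != "relu":
            raise ValueError("activation must be 'relu'")
        if (self.n_layers - 2) % 2 != 0:
            raise ValueError("n_layers minus stem and head must be even")
        covered = []
        for (lo, hi), dil in self.dilation_schedule:
            if dil < 1:
                raise ValueError("dilations must be >= 1")
            covered.extend(range(lo, hi + 1))
        expected = list(range(self.early_layers + 1, self.n_layers + 1))
        if sorted(covered) != expected:
            raise ValueError(
                f"dilation schedule must cover layers {self.early_layers + 1}"
                f"..{self.n_layers} exactly once; covers {sorted(covered)}"
            )

    def layer_dilation(self, layer: int) -> int:
        """Dilation of 1-based layer index."""
        if layer <= self.early_layers:
            return 1
        for (lo, hi), dil in self.dilation_schedule:
            if lo <= layer <= hi:
                return dil
        raise ValueError(f"layer {layer} outside schedule")

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "early_layers": self.early_layers,
            "dilation_schedule": [[list(r), d] for r, d in self.dilation_schedule],
            "kernel": list(self.kernel),
            "base_features": self.base_features,
            "residual_period": self.residual_period,
            "norm": self.norm,
            "activation": self.activation,
            "output_head": self.output_head,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["dilation_schedule"] = tuple((tuple(r), dil) for r, dil in d["dilation_schedule"])
        d["kernel"] = tuple(d["kernel"])
        return cls(**d)


class _Identity:
    def params(self):
        return []

    def forward(self, x, train=True):
        return x

    def backward(self, gy):
        return gy


@dataclass
class _ResBlock:
    conv1: Conv3d
    bn1: object
    relu1: ReLU
    conv2: Conv3d
    bn2: object
    relu_out: ReLU

    def params(self):
        return (self.conv1.params() + self.bn1.params() + self.conv2.params()
                + self.bn2.params())

    def forward(self, x, train=True):
        t = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        t = self.bn2.forward(self.conv2.forward(t, train), train)
        return self.relu_out.forward(x + t, train)

    def backward(self, gy):
        g = self.relu_out.backward(gy)
        gt = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        return g + gt


class ResNet3D:
    """The wired network; build with :func:`build_model`."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        F = spec.base_features
        norm = (lambda: BatchNorm3d(F)) if spec.norm else _Identity

        self.stem_conv = Conv3d(1, F, dilation=spec.layer_dilation(1), rng=rng)
        self.stem_bn = norm()
        self.stem_relu = ReLU()
        self.blocks: list[_ResBlock] = []
        layer = 2
        while layer < spec.n_layers:
            self.blocks.append(_ResBlock(
                conv1=Conv3d(F, F, dilation=spec.layer_dilation(layer), rng=rng),
                bn1=norm(),
                relu1=ReLU(),
                conv2=Conv3d(F, F, dilation=spec.layer_dilation(layer + 1), rng=rng),
                bn2=norm(),
                relu_out=ReLU(),
            ))
            layer += 2
        # final layer: the linear head (small init so the net starts near zero)
        self.head = Conv3d(F, 1, dilation=spec.layer_dilation(spec.n_layers),
                           rng=rng, weight_scale=0.01)

    def conv_layers(self) -> list[Conv3d]:
        convs = [self.stem_conv]
        for blk in self.blocks:
            convs.extend([blk.conv1, blk.conv2])
        convs.append(self.head)
        return convs

    def params(self):
        ps = self.stem_conv.params() + self.stem_bn.params()
        for blk in self.blocks:
            ps.extend(blk.params())
        ps.extend(self.head.params())
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """``x`` has shape (B, 1, X, Y, Z); internally the layers run
        channel-first, (C, B, X, Y, Z)."""
        xc = np.ascontiguousarray(x.transpose(1, 0, 2, 3, 4))
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(xc, train), train), train
        )
        for blk in self.blocks:
            h = blk.forward(h, train)
        out = self.head.forward(h, train)
        if self.spec.output_head == "softmax":
            e = np.exp(out - out.max(axis=0, keepdims=True))
            out = e / e.sum(axis=0, keepdims=True)
        elif self.spec.global_skip:
            out = out + xc
        return out.transpose(1, 0, 2, 3, 4)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.spec.output_head == "softmax":
            raise NotImplementedError("training the softmax head is not supported")
        g = np.ascontiguousarray(gy.transpose(1, 0, 2, 3, 4))
        g = self.head.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        g = self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))
        return g.transpose(1, 0, 2, 3, 4)

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p["value"]).sum() for p in self.params()))


def build_model(spec: Optional[ModelSpec] = None, seed: int = 0) -> ResNet3D:
    """Build the network with deterministic initialization for ``seed``."""
    return ResNet3D(spec or ModelSpec(), seed)


def count_conv_layers(model: ResNet3D) -> int:
    return len(model.conv_layers())


def normalization_scale(data: np.ndarray) -> float:
    """Per-volume intensity scale: the 99th-percentile value (floored)."""
    return max(float(np.percentile(data, 99)), 1e-6)


def _tile_starts(extent: int, patch: int, stride: int) -> list[int]:
    if patch >= extent:
        return [0]
    starts = list(range(0, extent - patch, stride))
    starts.append(extent - patch)
    return sorted(set(starts))


def predict_volume(
    model: ResNet3D,
    non_ac: VoxelGrid,
    patch_size: Optional[tuple[int, int, int]] = None,
    overlap: Optional[tuple[int, int, int]] = None,
) -> VoxelGrid:
    """Full-volume prediction, patch-tiled with uniform-weight blending.

    With ``patch_size=None`` (or a patch at least as large as the volume)
    the whole volume goes through in a single forward pass.  Output is
    clipped at zero: activity is non-negative.
    """
    data = non_ac.data
    scale = normalization_scale(data)
    x = (data / scale).astype(np.float32)
    shape = data.shape

    def _run(block: np.ndarray) -> np.ndarray:
        # axial axis leading: slab-shaped inputs then keep long contiguous
        # runs in the conv gather, which dominates CPU cost
        out = model.forward(block.transpose(2, 0, 1)[None, None], train=False)
        return out[0, 0].transpose(1, 2, 0)

    if patch_size is None or all(p >= s for p, s in zip(patch_size, shape)):
        pred = _run(x)
    else:
        patch = tuple(min(p, s) for p, s in zip(patch_size, shape))
        overlap = overlap or tuple(p // 2 for p in patch)
        stride = tuple(max(1, p - o) for p, o in zip(patch, overlap))
        acc = np.zeros(shape, dtype=np.float64)
        weight = np.zeros(shape, dtype=np.float64)
        for sx in _tile_starts(shape[0], patch[0], stride[0]):
            for sy in _tile_starts(shape[1], patch[1], stride[1]):
                for sz in _tile_starts(shape[2], patch[2], stride[2]):
                    sl = (slice(sx, sx + patch[0]), slice(sy, sy + patch[1]),
                          slice(sz, sz + patch[2]))
                    acc[sl] += _run(x[sl])
                    weight[sl] += 1.0
        pred = acc / weight
    return non_ac.with_data(np.maximum(pred * scale, 0.0).astype(np.float32))


def save_checkpoint(model: ResNet3D, path) -> None:
    """Weights plus an embedded JSON architecture header."""
    arrays = {}
    for i, conv in enumerate(model.conv_layers()):
        arrays[f"conv{i}_W"] = conv.W
        arrays[f"conv{i}_b"] = conv.b
    bns = [model.stem_bn] + [bn for blk in model.blocks for bn in (blk.bn1, blk.bn2)]
    for i, bn in enumerate(bns):
        if isinstance(bn, BatchNorm3d):
            arrays[f"bn{i}_gamma"] = bn.gamma
            arrays[f"bn{i}_beta"] = bn.beta
            arrays[f"bn{i}_rmean"] = bn.running_mean
            arrays[f"bn{i}_rvar"] = bn.running_var
    header = json.dumps({"spec": model.spec.to_dict(), "seed": model.seed})
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ResNet3D:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        model = ResNet3D(ModelSpec.from_dict(header["spec"]), header["seed"])
        for i, conv in enumerate(model.conv_layers()):
            conv.W[...] = data[f"conv{i}_W"]
            conv.b[...] = data[f"conv{i}_b"]
        bns = [model.stem_bn] + [bn for blk in model.blocks for bn in (blk.bn1, blk.bn2)]
        for i, bn in enumerate(bns):
            if isinstance(bn, BatchNorm3d):
                bn.gamma[...] = data[f"bn{i}_gamma"]
                bn.beta[...] = data[f"bn{i}_beta"]
                bn.running_mean[...] = data[f"bn{i}_rmean"]
                bn.running_var[...] = data[f"bn{i}_rvar"]
    return model
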