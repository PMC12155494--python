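"""Minimal deterministic 3D conv-net primitives in NumPy.

Forward and backward passes are written explicitly (no autograd) so that
training is bit-reproducible on CPU from fixed seeds.  Convolutions gather
the 27 dilated kernel offsets into one im2col matrix and evaluate a single
(C_out, 27*C_in) x (27*C_in, batch*voxels) GEMM, keeping all heavy
arithmetic inside BLAS at a favorable inner dimension.

Array convention: activations are float32 with channel-first shape
(C, B, X, Y, Z) — channel leading so offset slices flatten to GEMM operands
without transposition.  "Same" padding preserves the spatial shape for any
dilation.
"""

from __future__ import annotations

import numpy as np


class Conv3d:
    """3D convolution, kernel 3 (dilated) or 1, same padding, with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None, weight_scale: float | None = None):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((c_out, c_in, kernel, kernel, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.kernel = kernel
        self.dilation = int(dilation)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None
        self._train_cols: np.ndarray | None = None

    # scratch arrays shared by every conv layer: allocating 10s-of-MB
    # im2col matrices afresh each step costs more in page faults than the
    # GEMMs.  Only the training-time cols cache must outlive the call (it
    # feeds the weight gradient), so that one is per-layer.
    _scratch: dict = {}

    @classmethod
    def _shared(cls, name: str, shape: tuple) -> np.ndarray:
        buf = cls._scratch.get(name)
        if buf is None or buf.shape != shape:
            buf = cls._scratch[name] = np.zeros(shape, dtype=np.float32)
        return buf

    def _own_cols(self, shape: tuple) -> np.ndarray:
        if self._train_cols is None or self._train_cols.shape != shape:
            self._train_cols = np.zeros(shape, dtype=np.float32)
        return self._train_cols

    def params(self):
        return [
            {"value": self.W, "grad": self.gW},
            {"value": self.b, "grad": self.gb},
        ]

    @property
    def _offsets(self):
        d = self.dilation
        k = self.kernel
        return [(i * d, j * d, l * d) for i in range(k) for j in range(k) for l in range(k)]

    def _w_matrix(self) -> np.ndarray:
        co, ci = self.W.shape[:2]
        # offset-major rows to match the im2col layout
        return np.ascontiguousarray(
            self.W.reshape(co, ci, -1).transpose(0, 2, 1).reshape(co, -1)
        )

    def _im2col(self, x: np.ndarray, train: bool) -> np.ndarray:
        C, B, X, Y, Z = x.shape
        d = self.dilation
        xp = self._shared(f"xp{d}", (C, B, X + 2 * d, Y + 2 * d, Z + 2 * d))
        xp[:, :, d:-d, d:-d, d:-d] = x  # borders stay zero
        n = B * X * Y * Z
        shape = (len(self._offsets) * C, n)
        cols = self._own_cols(shape) if train else self._shared("cols", shape)
        for idx, (oi, oj, ol) in enumerate(self._offsets):
            dst = cols[idx * C : (idx + 1) * C].reshape(C, B, X, Y, Z)
            dst[...] = xp[:, :, oi : oi + X, oj : oj + Y, ol : ol + Z]
        return cols

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        C, B, X, Y, Z = x.shape
        co = self.W.shape[0]
        if self.kernel == 1:
            cols = x.reshape(C, -1)
            out = self.W[:, :, 0, 0, 0] @ cols + self.b[:, None]
        else:
            cols = self._im2col(x, train)
            out = self._w_matrix() @ cols + self.b[:, None]
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(co, B, X, Y, Z)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._shape is None:
            raise RuntimeError("backward called before a training forward pass")
        C, B, X, Y, Z = self._shape
        co = self.W.shape[0]
        gyf = gy.reshape(co, -1)
        self.gb += gyf.sum(axis=1)
        if self.kernel == 1:
            self.gW[:, :, 0, 0, 0] += gyf @ self._cols.T
            gx = self.W[:, :, 0, 0, 0].T @ gyf
            return gx.reshape(C, B, X, Y, Z)
        gw_mat = gyf @ self._cols.T  # (co, 27*C)
        self.gW += gw_mat.reshape(co, -1, C).transpose(0, 2, 1).reshape(self.W.shape)
        dcols = self._shared("dcols", self._cols.shape)
        np.matmul(self._w_matrix().T, gyf, out=dcols)
        d = self.dilation
        gxp = self._shared(f"gxp{d}", (C, B, X + 2 * d, Y + 2 * d, Z + 2 * d))
        gxp[...] = 0.0
        for idx, (oi, oj, ol) in enumerate(self._offsets):
            gxp[:, :, oi : oi + X, oj : oj + Y, ol : ol + Z] += dcols[
                idx * C : (idx + 1) * C
            ].reshape(C, B, X, Y, Z)
        return gxp[:, :, d:-d, d:-d, d:-d].copy()


class BatchNorm3d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [
            {"value": self.gamma, "grad": self.ggamma},
            {"value": self.beta, "grad": self.gbeta},
        ]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (1, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        sh = (-1, 1, 1, 1, 1)
        xhat = (x - mean.astype(np.float32).reshape(sh)) * inv.reshape(sh)
        if train:
            self._cache = (xhat, inv)
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (1, 2, 3, 4)
        sh = (-1, 1, 1, 1, 1)
        self.ggamma += (gy * xhat).sum(axis=axes)
        self.gbeta += gy.sum(axis=axes)
        g_mean = gy.mean(axis=axes).reshape(sh)
        gx_mean = (gy * xhat).mean(axis=axes).reshape(sh)
        return (self.gamma * inv).reshape(sh) * (gy - g_mean - xhat * gx_mean)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, np.float32(0.0))
        return np.maximum(x, np.float32(0.0))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, np.float32(0.0))


class Adam:
    """Adaptive-moment optimizer; ``beta1`` is the momentum knob."""

    def __init__(self, params: list[dict], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p["grad"][...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p["value"] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient wrt ``pred``.

    The per-voxel derivative is sign(residual), bounded by 1 — the property
    that makes L1 robust to artifact outliers during stage-1 training.
    """
    r = pred - target
    return float(np.abs(r).mean()), np.sign(r).astype(np.float32) / r.size


def l2_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient wrt ``pred`` (proportional to the
    residual, hence sensitive to outliers — reserved for purified data)."""
    r = pred - target
    return float((r.astype(np.float64) ** 2).mean()), (2.0 * r / r.size).astype(np.float32)


LOSSES = {"L1": l1_loss, "L2": l2_loss}
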