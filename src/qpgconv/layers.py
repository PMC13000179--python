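"""Convolution layers: classical, quantum-generated, and low-rank baselines.

All kernels use the (C_in, C_out, K_h, K_w) index order and all convolutions
are cross-correlations (no kernel flip) with stride 1 and "same" zero
padding by default — the usual deep-learning contract.

`QPGConv` holds no weight array at all: its trainable state is the circuit
angles (plus an optional LPP head), and the kernel is regenerated from them
on every forward pass during training.  `QPGAConv` adds a quantum-generated
increment to a frozen base kernel, the adapter analogue.  `ConvLoRA` is the
matched low-rank baseline: each kernel position (i, j) gets its own rank-r
factorization of the C_out x C_in slice, which is the factorization implied
by the r*(C_in + C_out)*K_h*K_w trainable-parameter count.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Module, Parameter, Tensor
from .generator import (AllocationPlan, QPGLayerConfig, allocate,
                        count_trainable, generate_kernel, kernel_tensor)
from .statevector import CircuitSpec

__all__ = [
    "conv2d", "maxpool2", "upsample2",
    "Conv2d", "QPGConv", "QPGAConv", "ConvLoRA",
    "classic_param_count", "convlora_param_count",
]


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding="same") -> Tensor:
    """2-D cross-correlation of (B, C_in, H, W) with (C_in, C_out, kh, kw)."""
    xd, wd = x.data, weight.data
    if xd.ndim != 4 or wd.ndim != 4:
        raise ValueError("conv2d expects a 4-D input batch and a 4-D kernel")
    B, ci, H, W = xd.shape
    ciw, co, kh, kw = wd.shape
    if ci != ciw:
        raise ValueError(f"input has {ci} channels but the kernel expects {ciw}")
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
    else:
        ph = pw = int(padding)
    Ho = (H + 2 * ph - kh) // stride + 1
    Wo = (W + 2 * pw - kw) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    out = np.zeros((B, co, Ho, Wo))
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
            out += np.einsum("io,bihw->bohw", wd[:, :, i, j], xs, optimize=True)

    def backward(g):
        dw = np.empty_like(wd)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i, i + stride * Ho, stride),
                      slice(j, j + stride * Wo, stride))
                dw[:, :, i, j] = np.einsum("bohw,bihw->io", g, xp[sl], optimize=True)
                dxp[sl] += np.einsum("io,bohw->bihw", wd[:, :, i, j], g, optimize=True)
        dx = dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp
        return dx, dw

    result = Tensor.from_op(out, (x, weight), backward)
    if bias is not None:
        result = result + bias.reshape(1, co, 1, 1)
    return result


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    r = (x.data.reshape(B, C, H // 2, 2, W // 2, 2)
         .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4))
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = (dr.reshape(B, C, H // 2, W // 2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W))
        return (dx,)

    return Tensor.from_op(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    B, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        return (g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return Tensor.from_op(out, (x,), backward)


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def classic_param_count(c_in: int, c_out: int, k_h: int, k_w: int) -> int:
    """Weight count of a plain conv kernel (bias-free accounting)."""
    return int(c_in) * int(c_out) * int(k_h) * int(k_w)


def convlora_param_count(c_in: int, c_out: int, k_h: int, k_w: int, r: int) -> int:
    """Trainable count of the per-position rank-r factorization baseline."""
    if int(r) < 1:
        raise ValueError("rank must be >= 1")
    return int(r) * (int(c_in) + int(c_out)) * int(k_h) * int(k_w)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Conv2d(Module):
    """Classical convolution layer; weight stored as (C_in, C_out, kh, kw)."""

    def __init__(self, c_in: int, c_out: int, k_h: int, k_w: int,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 stride: int = 1, padding="same"):
        rng = rng or np.random.default_rng()
        fan_in = c_in * k_h * k_w
        self.weight = Parameter(_kaiming(rng, (c_in, c_out, k_h, k_w), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class QPGConv(Module):
    """Convolution whose kernel is generated by per-channel circuits.

    Trainable state: the circuit angles and, under the LPP strategy, one
    shared (w, b) head.  A forward pass regenerates the kernel so that
    gradient steps on the angles immediately change the convolution; for
    inference, `materialize()` caches the kernel once.
    """

    def __init__(self, c_in: int, c_out: int, k_h: int, k_w: int,
                 rng: np.random.Generator | None = None,
                 n_blocks: int = 1, rotations: str = "ry_rx",
                 strategy: str = "sst", entangler: str = "ring",
                 stride: int = 1, padding="same"):
        rng = rng or np.random.default_rng()
        self.plan = allocate(c_in, c_out, k_h, k_w)
        cfg = QPGLayerConfig.init(self.plan, rng, n_blocks=n_blocks,
                                  rotations=rotations, strategy=strategy,
                                  entangler=entangler)
        self.circuit: CircuitSpec = cfg.circuit
        self.strategy = strategy
        self.angles = Parameter(cfg.angles)
        if strategy == "lpp":
            self.head_w = Parameter(cfg.head.w)
            self.head_b = Parameter(np.array(cfg.head.b))
        else:
            self.head_w = None
            self.head_b = None
        self.stride, self.padding = stride, padding
        self._cached: np.ndarray | None = None

    def kernel(self) -> Tensor:
        """Differentiable generated kernel (C_in, C_out, kh, kw)."""
        return kernel_tensor(self.angles, self.plan, self.circuit,
                             self.strategy, self.head_w, self.head_b)

    def config(self) -> QPGLayerConfig:
        from .generator import LPPHead
        head = None
        if self.strategy == "lpp":
            head = LPPHead(w=self.head_w.data.copy(), b=float(self.head_b.data))
        return QPGLayerConfig(plan=self.plan, circuit=self.circuit,
                              strategy=self.strategy,
                              angles=self.angles.data.copy(), head=head)

    def materialize(self) -> np.ndarray:
        """Generate and cache the kernel once (inference-time use)."""
        self._cached = generate_kernel(self.config()).weights
        return self._cached

    def ledger(self):
        return count_trainable(self.plan, self.circuit, self.strategy)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.kernel(), None, self.stride, self.padding)


class QPGAConv(Module):
    """Adapter convolution: frozen base kernel plus a generated increment.

    The base kernel (e.g. pre-trained weights) never receives gradient; only
    the increment's circuit angles train.  W' = W + increment.
    """

    def __init__(self, base_kernel: np.ndarray,
                 rng: np.random.Generator | None = None,
                 n_blocks: int = 1, rotations: str = "ry_rx",
                 strategy: str = "sst", entangler: str = "ring",
                 stride: int = 1, padding="same"):
        base = np.asarray(base_kernel, dtype=np.float64)
        if base.ndim != 4:
            raise ValueError("base kernel must be 4-D (C_in, C_out, kh, kw)")
        c_in, c_out, k_h, k_w = base.shape
        self.base = base            # plain array: frozen by construction
        self.qpg = QPGConv(c_in, c_out, k_h, k_w, rng=rng, n_blocks=n_blocks,
                           rotations=rotations, strategy=strategy,
                           entangler=entangler, stride=stride, padding=padding)
        self.stride, self.padding = stride, padding

    @property
    def plan(self) -> AllocationPlan:
        return self.qpg.plan

    def effective_kernel(self) -> Tensor:
        return Tensor(self.base) + self.qpg.kernel()

    def ledger(self):
        return self.qpg.ledger()

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_kernel(), None, self.stride, self.padding)


class ConvLoRA(Module):
    """Low-rank adaptation baseline for conv kernels.

    For each kernel position, the C_out x C_in weight slice gets an additive
    update B_pos @ A_pos with A_pos (r x C_in) and B_pos (C_out x r); B is
    zero-initialised so training starts from the frozen base.  No alpha/r
    scaling is applied.
    """

    def __init__(self, base_kernel: np.ndarray, rank: int,
                 rng: np.random.Generator | None = None,
                 stride: int = 1, padding="same"):
        rng = rng or np.random.default_rng()
        base = np.asarray(base_kernel, dtype=np.float64)
        if base.ndim != 4:
            raise ValueError("base kernel must be 4-D (C_in, C_out, kh, kw)")
        if int(rank) < 1:
            raise ValueError("rank must be >= 1")
        c_in, c_out, k_h, k_w = base.shape
        self.base = base
        self.rank = int(rank)
        npos = k_h * k_w
        self.A = Parameter(_kaiming(rng, (npos, self.rank, c_in), c_in))
        self.B = Parameter(np.zeros((npos, c_out, self.rank)))
        self.stride, self.padding = stride, padding

    def param_count(self) -> int:
        c_in, c_out, k_h, k_w = self.base.shape
        return convlora_param_count(c_in, c_out, k_h, k_w, self.rank)

    def effective_kernel(self) -> Tensor:
        c_in, c_out, k_h, k_w = self.base.shape
        npos = k_h * k_w
        # delta[pos, co, ci] = sum_r B[pos, co, r] * A[pos, r, ci]
        prod = (self.B.reshape(npos, c_out, self.rank, 1)
                * self.A.reshape(npos, 1, self.rank, c_in))
        delta = prod.sum(axis=2)                       # (npos, c_out, c_in)
        delta = delta.reshape(k_h, k_w, c_out, c_in).transpose(3, 2, 0, 1)
        return Tensor(self.base) + delta

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_kernel(), None, self.stride, self.padding)
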