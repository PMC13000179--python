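"""A miniature UNext-style encoder-decoder with switchable training modes.

Six named components cover the network: ``encoder1``, ``block1`` and
``block2`` form the downsampling path, ``dblock1`` and ``dblock2`` the
upsampling path with skip connections, and ``finalconv`` is the 1x1 output
head.  Each component can be trained classically, via QPGConv (kernel fully
quantum-generated), or via QPGAConv (quantum increment on a frozen base).
Eleven integration schemes select which components go quantum; scheme 0 (or
an empty set) is the fully classical model.

With base width w the channel trajectory is
1 -> w -> 2w -> 4w -> (6w -> 2w) -> (3w -> w) -> 1, so the encoder hits the
channel-up branch of the allocation rule (C_in <= C_out) and the decoder
the channel-down branch.  Default desk scale is w = 8 at 32x32 input;
256x256 inputs work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Module, Parameter, Tensor, cat
from .layers import Conv2d, QPGAConv, QPGConv, maxpool2, upsample2

__all__ = ["COMPONENTS", "SCHEMES", "SchemeSpec", "ModelSpec", "MiniUNext",
           "build_model", "scheme_components"]

COMPONENTS = ("encoder1", "block1", "block2", "dblock1", "dblock2", "finalconv")

# integration schemes 1-11: which components are quantum-trained
SCHEMES: dict[int, frozenset] = {
    1: frozenset({"encoder1", "finalconv"}),
    2: frozenset({"encoder1", "block2", "finalconv"}),
    3: frozenset({"encoder1", "block2", "dblock2"}),
    4: frozenset({"block1", "block2"}),
    5: frozenset({"block1", "block2", "dblock1"}),
    6: frozenset({"block1", "block2", "dblock2"}),
    7: frozenset({"block1", "block2", "dblock1", "dblock2"}),
    8: frozenset({"block1", "block2", "dblock1", "dblock2", "finalconv"}),
    9: frozenset({"block2", "finalconv"}),
    10: frozenset({"block2", "dblock2", "finalconv"}),
    11: frozenset({"block2", "dblock1", "dblock2", "finalconv"}),
}


def scheme_components(scheme) -> frozenset:
    """Resolve a scheme id (0-11) or an iterable of component names."""
    if scheme is None:
        return frozenset()
    if isinstance(scheme, int):
        if scheme == 0:
            return frozenset()
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme id {scheme}; valid ids are 0-11")
        return SCHEMES[scheme]
    comps = frozenset(scheme)
    unknown = comps - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    return comps


@dataclass(frozen=True)
class SchemeSpec:
    scheme_id: int
    components: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "components",
                           scheme_components(self.scheme_id)
                           if not self.components else frozenset(self.components))

    @classmethod
    def from_id(cls, scheme_id: int) -> "SchemeSpec":
        return cls(scheme_id=scheme_id, components=scheme_components(scheme_id))


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the miniature segmentation model."""

    size: int = 32
    in_channels: int = 1
    base_width: int = 8
    scheme: int | frozenset = 0
    strategy: str = "sst"
    n_blocks: int = 1
    rotations: str = "ry_rx"
    adapter: bool = False     # True: QPGAConv over a frozen classical base

    def quantum_components(self) -> frozenset:
        return scheme_components(self.scheme)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Batch-independent (unlike batch norm), so per-sample outputs do not
    depend on batch composition and no running statistics are needed.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class _Stage(Module):
    """One conv (+ instance norm) + activation stage, classical or quantum."""

    def __init__(self, c_in: int, c_out: int, k: int, quantum: bool,
                 spec: ModelSpec, rng: np.random.Generator, activation: str,
                 norm: bool = True):
        self.activation = activation
        if quantum and spec.adapter:
            base = Conv2d(c_in, c_out, k, k, rng=rng, bias=False).weight.data
            self.conv: Module = QPGAConv(base, rng=rng, n_blocks=spec.n_blocks,
                                         rotations=spec.rotations,
                                         strategy=spec.strategy)
        elif quantum:
            self.conv = QPGConv(c_in, c_out, k, k, rng=rng,
                                n_blocks=spec.n_blocks,
                                rotations=spec.rotations,
                                strategy=spec.strategy)
        else:
            self.conv = Conv2d(c_in, c_out, k, k, rng=rng, bias=True)
        self.norm = InstanceNorm2d(c_out) if norm else None
        self.quantum = quantum
        self.shape = (c_in, c_out, k, k)

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv(x)
        if self.norm is not None:
            out = self.norm(out)
        if self.activation == "relu":
            return out.relu()
        if self.activation == "sigmoid":
            return out.sigmoid()
        return out

    def report(self) -> dict:
        c_in, c_out, k, _ = self.shape
        generated = c_in * c_out * k * k
        norm_params = 0 if self.norm is None else 2 * c_out
        if self.quantum:
            ledger = self.conv.ledger()
            return {"kind": "qpg",
                    "trainable_classical": ledger.postprocess_params + norm_params,
                    "trainable_quantum": ledger.vqc_params,
                    "generated_weights": generated,
                    "conv_trainable": ledger.total}
        n_class = generated + (0 if getattr(self.conv, "bias", None) is None
                               else c_out)
        return {"kind": "classical",
                "trainable_classical": n_class + norm_params,
                "trainable_quantum": 0, "generated_weights": 0,
                "conv_trainable": n_class}


class MiniUNext(Module):
    """Miniature encoder-decoder; output is a (B, 1, H, W) mask probability."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if spec.size % 4:
            raise ValueError("input size must be divisible by 4")
        q = spec.quantum_components()
        w = spec.base_width
        self.spec = spec
        self.encoder1 = _Stage(spec.in_channels, w, 3, "encoder1" in q, spec, rng, "relu")
        self.block1 = _Stage(w, 2 * w, 3, "block1" in q, spec, rng, "relu")
        self.block2 = _Stage(2 * w, 4 * w, 3, "block2" in q, spec, rng, "relu")
        self.dblock1 = _Stage(6 * w, 2 * w, 3, "dblock1" in q, spec, rng, "relu")
        self.dblock2 = _Stage(3 * w, w, 3, "dblock2" in q, spec, rng, "relu")
        self.finalconv = _Stage(w, 1, 1, "finalconv" in q, spec, rng, "sigmoid",
                                norm=False)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected input (B, {self.spec.in_channels}, H, W), got {x.shape}")
        e1 = self.encoder1(x)                       # (B, w, H, W)
        b1 = self.block1(maxpool2(e1))              # (B, 2w, H/2, W/2)
        b2 = self.block2(maxpool2(b1))              # (B, 4w, H/4, W/4)
        d1 = self.dblock1(cat([upsample2(b2), b1], axis=1))   # (B, 2w, H/2, W/2)
        d2 = self.dblock2(cat([upsample2(d1), e1], axis=1))   # (B, w, H, W)
        return self.finalconv(d2)                   # (B, 1, H, W) in (0, 1)

    def components(self) -> dict:
        return {name: getattr(self, name) for name in COMPONENTS}

    def parameter_report(self) -> dict:
        """Per-component classical/quantum trainable counts plus totals."""
        per = {name: stage.report() for name, stage in self.components().items()}
        totals = {
            "trainable_classical": sum(r["trainable_classical"] for r in per.values()),
            "trainable_quantum": sum(r["trainable_quantum"] for r in per.values()),
        }
        totals["trainable_total"] = (totals["trainable_classical"]
                                     + totals["trainable_quantum"])
        return {"components": per, "totals": totals}

    def quantum_parameters(self):
        for name, stage in self.components().items():
            if stage.quantum:
                yield from (p for _, p in stage.named_parameters(name + "."))

    def freeze_quantum(self):
        for p in self.quantum_parameters():
            p.requires_grad = False

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        if set(params) != set(state):
            raise ValueError("state dict does not match the model's parameters")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def build_model(spec: ModelSpec, seed: int | None = None) -> MiniUNext:
    """Build a model from its spec; `seed` fixes the initialization."""
    rng = np.random.default_rng(seed)
    return MiniUNext(spec, rng=rng)
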