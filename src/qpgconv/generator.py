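"""Quantum parameter generation: circuits to convolution weights.

A convolution kernel W[c_in, c_out, k_h, k_w] is generated by a family of
independent variational circuits, one per *target* channel and kernel
position.  The target axis is the smaller of the two channel axes, so a
layer needs min(C_in, C_out) * K_h * K_w circuits, and each circuit must
produce max(C_in, C_out) values — which takes only ceil(log2 max(C_in,
C_out)) qubits, because an N-qubit state has 2^N basis outcomes.  Only the
circuit angles (plus, for the LPP strategy, one small shared linear head)
are trainable; the kernel itself is re-generated from them at every forward
pass.

Three post-processing strategies map circuit outputs to weight values:

RCE   y_i = Re(psi_i), in [-1, 1]                 (amplitude real part)
LPP   y_i = w . (p_i || bits(i)) + b              (learned linear head)
SST   y_i = (pi/2) (p_i - 1/2), in [-pi/4, pi/4]  (shift and scale)

Because each channel owns its own circuit, perturbing one circuit's angles
can only change that channel's kernel slice (channel independence), and the
Born rule normalizes each circuit's probability vector to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log2

import numpy as np

from ._tensor import Tensor
from .statevector import (AngleSet, CircuitSpec, adjoint_backward,
                          probabilities, simulate_batch)

__all__ = [
    "AllocationPlan", "LPPHead", "QPGLayerConfig", "GeneratedKernel",
    "ParameterLedger", "allocate", "count_trainable",
    "postprocess_rce", "postprocess_lpp", "postprocess_sst",
    "binary_encoding", "generate_kernel", "vqc_output", "kernel_tensor",
    "STRATEGIES",
]

STRATEGIES = ("rce", "lpp", "sst")


@dataclass(frozen=True)
class AllocationPlan:
    """How a conv layer's kernel entries are shared out across circuits."""

    c_in: int
    c_out: int
    k_h: int
    k_w: int
    target_axis: str        # "input" or "output"
    n_vqcs: int             # min(C_in, C_out) * K_h * K_w
    qubits_per_vqc: int     # ceil(log2 max(C_in, C_out)), floor 1
    values_per_vqc: int     # max(C_in, C_out)

    @property
    def target_channels(self) -> int:
        return min(self.c_in, self.c_out)

    @property
    def classic_params(self) -> int:
        return self.c_in * self.c_out * self.k_h * self.k_w


def allocate(c_in: int, c_out: int, k_h: int, k_w: int) -> AllocationPlan:
    """Apply the channel-indexing rule: the smaller channel axis is the target.

    Ties (C_in == C_out) go to the input axis, per the C_in <= C_out branch.
    """
    for name, v in (("c_in", c_in), ("c_out", c_out), ("k_h", k_h), ("k_w", k_w)):
        if int(v) < 1:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    c_in, c_out, k_h, k_w = int(c_in), int(c_out), int(k_h), int(k_w)
    target_axis = "input" if c_in <= c_out else "output"
    values = max(c_in, c_out)
    return AllocationPlan(
        c_in=c_in, c_out=c_out, k_h=k_h, k_w=k_w,
        target_axis=target_axis,
        n_vqcs=min(c_in, c_out) * k_h * k_w,
        qubits_per_vqc=max(1, ceil(log2(values))),
        values_per_vqc=values,
    )


@dataclass(frozen=True)
class ParameterLedger:
    """Trainable-parameter accounting for one QPG-managed layer."""

    vqc_params: int
    postprocess_params: int

    @property
    def total(self) -> int:
        return self.vqc_params + self.postprocess_params

    def as_dict(self) -> dict:
        return {"vqc_params": self.vqc_params,
                "postprocess_params": self.postprocess_params,
                "total": self.total}


def count_trainable(plan: AllocationPlan, circuit: CircuitSpec,
                    strategy: str = "sst") -> ParameterLedger:
    """Count trainable parameters: circuit angles plus any head parameters.

    The shared LPP head adds qubits_per_vqc + 2 parameters per layer
    (a weight per probability-plus-bit slot and a bias); RCE and SST add
    none.  Headline counts are quoted with the SST default.
    """
    if circuit.n_qubits != plan.qubits_per_vqc:
        raise ValueError(
            f"circuit has {circuit.n_qubits} qubits but the plan requires "
            f"{plan.qubits_per_vqc}")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    vqc = plan.n_vqcs * circuit.n_blocks * circuit.rotations_per_block
    post = plan.qubits_per_vqc + 2 if strategy == "lpp" else 0
    return ParameterLedger(vqc_params=vqc, postprocess_params=post)


# ---------------------------------------------------------------------------
# post-processing strategies (plain-numpy forms)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LPPHead:
    """Shared linear head of the LPP strategy: y = w . (p || bits) + b."""

    w: np.ndarray = field(repr=False)
    b: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.w, dtype=np.float64)
        if arr.ndim != 1 or not np.all(np.isfinite(arr)) or not np.isfinite(self.b):
            raise ValueError("LPP head parameters must be a finite vector and scalar")
        object.__setattr__(self, "w", arr)


def postprocess_rce(amplitudes: np.ndarray) -> np.ndarray:
    """Real component extraction: y_i = Re(psi_i), in [-1, 1]."""
    return np.asarray(amplitudes).real.astype(np.float64, copy=True)


def postprocess_sst(probs: np.ndarray) -> np.ndarray:
    """Shift-and-scale: y_i = (pi/2)(p_i - 1/2), in [-pi/4, pi/4]."""
    p = np.asarray(probs, dtype=np.float64)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("probabilities must lie in [0, 1]")
    return (np.pi / 2.0) * (p - 0.5)


def binary_encoding(n_bits: int) -> np.ndarray:
    """(2^n_bits, n_bits) matrix of bit values; column j holds bit d_j
    (d_0 least significant) of each basis index."""
    i = np.arange(1 << n_bits)
    return ((i[:, None] >> np.arange(n_bits)[None, :]) & 1).astype(np.float64)


def postprocess_lpp(probs: np.ndarray, head: LPPHead) -> np.ndarray:
    """Linear probability projection: y_i = w . (p_i || d_0..d_k) + b."""
    p = np.asarray(probs, dtype=np.float64)
    n_bits = int(np.log2(p.shape[-1]))
    if head.w.shape[0] != n_bits + 1:
        raise ValueError(
            f"LPP head length {head.w.shape[0]} != qubits + 1 = {n_bits + 1}")
    bits = binary_encoding(n_bits)
    return head.w[0] * p + bits @ head.w[1:] + head.b


# ---------------------------------------------------------------------------
# layer configuration and kernel generation
# ---------------------------------------------------------------------------

@dataclass
class QPGLayerConfig:
    """Everything needed to generate one layer's kernel.

    `angles` stacks the per-circuit angle matrices as
    (n_vqcs, n_blocks, rotations_per_block); circuit v corresponds to target
    channel v // (K_h*K_w) and kernel position divmod(v % (K_h*K_w), K_w).
    """

    plan: AllocationPlan
    circuit: CircuitSpec
    strategy: str = "sst"
    angles: np.ndarray | None = None
    head: LPPHead | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.circuit.n_qubits != self.plan.qubits_per_vqc:
            raise ValueError("circuit qubit count does not match the plan")
        if self.angles is None:
            self.angles = np.zeros((self.plan.n_vqcs,) + self.circuit.angle_shape)
        else:
            self.angles = np.asarray(self.angles, dtype=np.float64)
            expect = (self.plan.n_vqcs,) + self.circuit.angle_shape
            if self.angles.shape != expect:
                raise ValueError(
                    f"angles shape {self.angles.shape} != {expect} "
                    "(one AngleSet per VQC)")
        if self.strategy == "lpp" and self.head is None:
            self.head = LPPHead(w=np.zeros(self.plan.qubits_per_vqc + 1), b=0.0)

    @classmethod
    def init(cls, plan: AllocationPlan, rng: np.random.Generator,
             n_blocks: int = 1, rotations: str = "ry_rx",
             strategy: str = "sst", entangler: str = "ring") -> "QPGLayerConfig":
        """Fresh config: angles uniform over [0, 1) radians, head by
        variance-scaling (fan_in = qubits + 1) when LPP is used."""
        circuit = CircuitSpec(plan.qubits_per_vqc, n_blocks,
                              entangler=entangler, rotations=rotations)
        angles = rng.random((plan.n_vqcs,) + circuit.angle_shape)
        head = None
        if strategy == "lpp":
            fan_in = plan.qubits_per_vqc + 1
            head = LPPHead(w=rng.normal(0.0, np.sqrt(2.0 / fan_in), fan_in), b=0.0)
        return cls(plan=plan, circuit=circuit, strategy=strategy,
                   angles=angles, head=head)

    def angle_sets(self) -> list:
        return [AngleSet(a) for a in self.angles]


@dataclass(frozen=True)
class GeneratedKernel:
    """A 4-D convolution weight array in (C_in, C_out, K_h, K_w) order."""

    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.weights, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError("kernel must be 4-D (C_in, C_out, K_h, K_w)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("kernel entries must be finite")
        object.__setattr__(self, "weights", arr)


def _values_to_kernel(values: np.ndarray, plan: AllocationPlan) -> np.ndarray:
    """Arrange per-circuit outputs (n_vqcs, values_per_vqc) into the 4-D kernel."""
    t = plan.target_channels
    block = values.reshape(t, plan.k_h, plan.k_w, plan.values_per_vqc)
    if plan.target_axis == "output":
        # W[c_in, c_out, kh, kw] = output c_in of circuit (c_out, kh, kw)
        return block.transpose(3, 0, 1, 2)
    return block.transpose(0, 3, 1, 2)


def generate_kernel(config: QPGLayerConfig) -> GeneratedKernel:
    """Run every circuit, post-process, and assemble the kernel.

    Each circuit's first values_per_vqc basis outcomes populate the
    non-target axis; when that count is not a power of two the remaining
    outcomes are simply ignored.
    """
    amps = simulate_batch(config.circuit, config.angles)
    if config.strategy == "rce":
        y = postprocess_rce(amps)
    else:
        p = probabilities(amps)
        y = postprocess_sst(p) if config.strategy == "sst" \
            else postprocess_lpp(p, config.head)
    used = y[:, :config.plan.values_per_vqc]
    return GeneratedKernel(_values_to_kernel(used, config.plan))


# ---------------------------------------------------------------------------
# autodiff bridge
# ---------------------------------------------------------------------------

def vqc_output(angles: Tensor, spec: CircuitSpec, mode: str = "probs") -> Tensor:
    """Differentiable batched circuit output.

    `angles` is a (V, n_blocks, slots) tensor; the result is (V, 2^N) —
    outcome probabilities (`mode="probs"`) or amplitude real parts
    (`mode="real"`).  The backward pass runs adjoint differentiation of the
    statevector, so gradients flow classically from the loss into the angles.
    """
    amps = simulate_batch(spec, angles.data)
    if mode == "probs":
        out = probabilities(amps)

        def backward(g):
            lam = g * amps
            return (adjoint_backward(spec, angles.data, amps, lam),)
    elif mode == "real":
        out = amps.real.copy()

        def backward(g):
            lam = (g / 2.0).astype(complex)
            return (adjoint_backward(spec, angles.data, amps, lam),)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Tensor.from_op(out, (angles,), backward)


def kernel_tensor(angles: Tensor, plan: AllocationPlan, spec: CircuitSpec,
                  strategy: str, head_w: Tensor | None = None,
                  head_b: Tensor | None = None) -> Tensor:
    """Differentiable kernel generation (the autograd twin of generate_kernel)."""
    if strategy == "rce":
        y = vqc_output(angles, spec, mode="real")
    else:
        p = vqc_output(angles, spec, mode="probs")
        if strategy == "sst":
            y = (p - 0.5) * (np.pi / 2.0)
        elif strategy == "lpp":
            if head_w is None or head_b is None:
                raise ValueError("LPP strategy requires head parameters")
            bits = Tensor(binary_encoding(spec.n_qubits))
            enc = (bits * head_w[1:]).sum(axis=1)      # (2^N,)
            y = p * head_w[0] + enc + head_b
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    used = y[:, :plan.values_per_vqc]
    t = plan.target_channels
    block = used.reshape(t, plan.k_h, plan.k_w, plan.values_per_vqc)
    if plan.target_axis == "output":
        return block.transpose(3, 0, 1, 2)
    return block.transpose(0, 3, 1, 2)
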