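"""Exact statevector simulation of the shallow strongly-entangling ansatz.

The circuit acts on N qubits, all initialised to |0>, and consists of a
Hadamard layer followed by K repeated blocks; each block applies a layer of
RY rotations, a layer of RX rotations, and a layer of CNOTs arranged on a
ring (qubit j controls j+1, the last qubit wrapping to the first).  Three
rotation modes are supported:

``ry_rx``
    one RY and one RX per qubit per block (the default ansatz),
``ry_only``
    one RY per qubit per block,
``minimal``
    a single RY on qubit 1 per block — the cheapest trainable circuit,
    used when quoting the minimum possible parameter count.

Basis-state convention: index ``i`` has qubit 1 as its least-significant bit,
so for N=2 the amplitudes are ordered |q2 q1> = |00>, |01>, |10>, |11> with
qubit 1 varying fastest.

Simulation is exact (complex128 amplitudes, no shot noise).  Gradients used
in training are computed classically by adjoint (reverse-mode) differentiation
of the statevector; the two-point parameter-shift rule is provided as an
independent verification path, as it would be on hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "CircuitSpec", "AngleSet", "StateVector",
    "initial_superposition", "run_circuit", "probabilities",
    "sample_counts", "gradient_parameter_shift",
    "simulate_batch", "adjoint_backward",
    "H_GATE", "CNOT_GATE", "ry_matrix", "rx_matrix",
]

H_GATE = np.array([[1.0, 1.0], [1.0, -1.0]], dtype=complex) / np.sqrt(2.0)
CNOT_GATE = np.array([[1, 0, 0, 0],
                      [0, 1, 0, 0],
                      [0, 0, 0, 1],
                      [0, 0, 1, 0]], dtype=complex)

_ROTATION_MODES = ("ry_rx", "ry_only", "minimal")
_ENTANGLERS = ("ring", "chain", "none")


def ry_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def rx_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)


@dataclass(frozen=True)
class CircuitSpec:
    """Geometry of one variational circuit: N qubits, K blocks."""

    n_qubits: int
    n_blocks: int = 1
    entangler: str = "ring"
    rotations: str = "ry_rx"

    def __post_init__(self):
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.entangler not in _ENTANGLERS:
            raise ValueError(f"unknown entangler {self.entangler!r}")
        if self.rotations not in _ROTATION_MODES:
            raise ValueError(f"unknown rotation mode {self.rotations!r}")
        if self.n_qubits == 1:
            # no pair of qubits exists to entangle
            object.__setattr__(self, "entangler", "none")

    @property
    def dim(self) -> int:
        return 1 << self.n_qubits

    @property
    def rotations_per_block(self) -> int:
        if self.rotations == "ry_rx":
            return 2 * self.n_qubits
        if self.rotations == "ry_only":
            return self.n_qubits
        return 1  # minimal

    @property
    def n_angles(self) -> int:
        return self.n_blocks * self.rotations_per_block

    @property
    def angle_shape(self) -> tuple:
        return (self.n_blocks, self.rotations_per_block)


@dataclass(frozen=True)
class AngleSet:
    """Trainable rotation angles, indexed (block, gate slot), in radians.

    Within a block the first N slots are the RY angles of qubits 1..N and,
    in ``ry_rx`` mode, the next N slots the RX angles.
    """

    angles: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.angles, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("angles must be a (n_blocks, slots) matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "angles", arr)

    @classmethod
    def random(cls, spec: CircuitSpec, rng: np.random.Generator) -> "AngleSet":
        """Uniform initialization over [0, 1) radians."""
        return cls(rng.random(spec.angle_shape))

    @classmethod
    def zeros(cls, spec: CircuitSpec) -> "AngleSet":
        return cls(np.zeros(spec.angle_shape))

    def validate_for(self, spec: CircuitSpec) -> None:
        if self.angles.shape != spec.angle_shape:
            raise ValueError(
                f"angle shape {self.angles.shape} does not match the circuit's "
                f"{spec.angle_shape}")


@dataclass(frozen=True)
class StateVector:
    """Complex amplitudes of an N-qubit pure state (length 2^N)."""

    amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.amplitudes, dtype=complex)
        if arr.ndim != 1 or arr.size & (arr.size - 1):
            raise ValueError("amplitudes must be a 1-D vector of length 2^N")
        object.__setattr__(self, "amplitudes", arr)

    @property
    def n_qubits(self) -> int:
        return int(self.amplitudes.size).bit_length() - 1

    @property
    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.amplitudes) ** 2)))


# ---------------------------------------------------------------------------
# low-level batched kernels
# ---------------------------------------------------------------------------

def _entangler_pairs(spec: CircuitSpec) -> list:
    n = spec.n_qubits
    if spec.entangler == "none" or n < 2:
        return []
    if spec.entangler == "chain":
        return [(j, j + 1) for j in range(n - 1)]
    return [(j, (j + 1) % n) for j in range(n)]  # ring


@lru_cache(maxsize=None)
def _cnot_perm(n: int, control: int, target: int) -> np.ndarray:
    i = np.arange(1 << n)
    flip = ((i >> control) & 1).astype(bool)
    return np.where(flip, i ^ (1 << target), i)


def _rotation_schedule(spec: CircuitSpec) -> list:
    """Per block: list of (pauli, qubit, slot) in application order."""
    n = spec.n_qubits
    if spec.rotations == "ry_rx":
        return ([("y", q, q) for q in range(n)]
                + [("x", q, n + q) for q in range(n)])
    if spec.rotations == "ry_only":
        return [("y", q, q) for q in range(n)]
    return [("y", 0, 0)]


def _rot_mats(theta: np.ndarray, pauli: str) -> np.ndarray:
    """(B,) angles -> (B, 2, 2) rotation matrices exp(-i theta P / 2)."""
    c = np.cos(theta / 2.0)
    s = np.sin(theta / 2.0)
    mats = np.empty((theta.shape[0], 2, 2), dtype=complex)
    if pauli == "y":
        mats[:, 0, 0] = c
        mats[:, 0, 1] = -s
        mats[:, 1, 0] = s
        mats[:, 1, 1] = c
    elif pauli == "x":
        mats[:, 0, 0] = c
        mats[:, 0, 1] = -1j * s
        mats[:, 1, 0] = -1j * s
        mats[:, 1, 1] = c
    else:  # pragma: no cover
        raise ValueError(pauli)
    return mats


def _apply_1q(state: np.ndarray, mats: np.ndarray, qubit: int, n: int) -> np.ndarray:
    """Apply per-batch 2x2 matrices to one qubit of a (B, 2^n) state batch."""
    B = state.shape[0]
    hi = 1 << (n - 1 - qubit)
    lo = 1 << qubit
    s = state.reshape(B, hi, 2, lo)
    out = np.einsum("Bab,Bhbl->Bhal", mats, s, optimize=True)
    return out.reshape(B, -1)


def _apply_pauli(state: np.ndarray, qubit: int, n: int, pauli: str) -> np.ndarray:
    B = state.shape[0]
    hi = 1 << (n - 1 - qubit)
    lo = 1 << qubit
    s = state.reshape(B, hi, 2, lo)
    out = np.empty_like(s)
    if pauli == "x":
        out[:, :, 0] = s[:, :, 1]
        out[:, :, 1] = s[:, :, 0]
    else:  # y
        out[:, :, 0] = -1j * s[:, :, 1]
        out[:, :, 1] = 1j * s[:, :, 0]
    return out.reshape(B, -1)


def simulate_batch(spec: CircuitSpec, angles: np.ndarray) -> np.ndarray:
    """Run B circuits of identical geometry with per-circuit angles.

    Parameters
    ----------
    angles : (B, n_blocks, rotations_per_block) array of radians.

    Returns
    -------
    (B, 2^N) complex amplitudes.
    """
    angles = np.asarray(angles, dtype=np.float64)
    if angles.ndim != 3 or angles.shape[1:] != spec.angle_shape:
        raise ValueError(
            f"angles must have shape (B,) + {spec.angle_shape}, got {angles.shape}")
    n = spec.n_qubits
    B = angles.shape[0]
    state = np.full((B, spec.dim), 2.0 ** (-n / 2.0), dtype=complex)
    perms = [_cnot_perm(n, c, t) for c, t in _entangler_pairs(spec)]
    sched = _rotation_schedule(spec)
    for k in range(spec.n_blocks):
        th = angles[:, k]
        for pauli, qubit, slot in sched:
            state = _apply_1q(state, _rot_mats(th[:, slot], pauli), qubit, n)
        for perm in perms:
            state = state[:, perm]
    return state


def adjoint_backward(spec: CircuitSpec, angles: np.ndarray,
                     final_state: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Reverse-mode gradient of a real loss through the statevector.

    `lam` is the complex cotangent defined so that
    dL/dtheta = 2 Re( lam^dagger  d psi / d theta ).
    For a loss through probabilities p_i = |psi_i|^2 with upstream gradient
    g: lam = g * psi.  For a loss through Re(psi) with upstream gradient
    g: lam = g / 2.

    Returns an array shaped like `angles`.
    """
    angles = np.asarray(angles, dtype=np.float64)
    n = spec.n_qubits
    perms = [_cnot_perm(n, c, t) for c, t in _entangler_pairs(spec)]
    sched = _rotation_schedule(spec)
    ket = np.array(final_state, dtype=complex, copy=True)
    bra = np.array(lam, dtype=complex, copy=True)
    grads = np.zeros_like(angles)
    for k in reversed(range(spec.n_blocks)):
        th = angles[:, k]
        for perm in reversed(perms):
            ket = ket[:, perm]
            bra = bra[:, perm]
        for pauli, qubit, slot in reversed(sched):
            # d R/d theta = (-i/2) P R  =>  dL/dtheta = Im( bra^dag P ket )
            pket = _apply_pauli(ket, qubit, n, pauli)
            grads[:, k, slot] = np.einsum(
                "bd,bd->b", np.conj(bra), pket, optimize=True).imag
            inv = _rot_mats(-th[:, slot], pauli)
            ket = _apply_1q(ket, inv, qubit, n)
            bra = _apply_1q(bra, inv, qubit, n)
    return grads


# ---------------------------------------------------------------------------
# public single-circuit API
# ---------------------------------------------------------------------------

def _angles_array(spec: CircuitSpec, angles) -> np.ndarray:
    if isinstance(angles, AngleSet):
        angles.validate_for(spec)
        return angles.angles
    arr = np.asarray(angles, dtype=np.float64)
    if arr.shape != spec.angle_shape:
        raise ValueError(
            f"angle shape {arr.shape} does not match the circuit's {spec.angle_shape}")
    return arr


def initial_superposition(spec: CircuitSpec) -> StateVector:
    """State after the Hadamard layer: all 2^N amplitudes equal to 2^(-N/2)."""
    return StateVector(np.full(spec.dim, 2.0 ** (-spec.n_qubits / 2.0), dtype=complex))


def run_circuit(spec: CircuitSpec, angles) -> StateVector:
    """Final state |psi_final> of the full ansatz for one set of angles."""
    arr = _angles_array(spec, angles)
    return StateVector(simulate_batch(spec, arr[None])[0])


def probabilities(state) -> np.ndarray:
    """Born-rule outcome probabilities of a (normalized) state.

    Computed as |psi_i|^2 renormalized by their sum; for a unit-norm state the
    sum is 1 up to one ulp, and the renormalization makes exactly-uniform
    states yield exactly p_i = 2^-N.
    """
    amps = state.amplitudes if isinstance(state, StateVector) else np.asarray(state)
    p = amps.real ** 2 + amps.imag ** 2
    return p / p.sum(axis=-1, keepdims=True)


def sample_counts(state, shots: int, rng: np.random.Generator) -> np.ndarray:
    """Optional shot-sampling mode: multinomial counts over basis outcomes.

    Provided for experimentation only; parameter generation always uses the
    exact probabilities.
    """
    p = probabilities(state)
    return rng.multinomial(int(shots), p)


def gradient_parameter_shift(spec: CircuitSpec, angles, output_index: int,
                             wrt_angle) -> float:
    """d p[output_index] / d theta via the two-point parameter-shift rule.

    `wrt_angle` is either a flat index into the angle matrix or a
    (block, slot) pair.  Rotation generators have eigenvalues +-1/2, so
    dp/dtheta = ( p(theta + pi/2) - p(theta - pi/2) ) / 2.
    """
    arr = _angles_array(spec, angles).copy()
    if isinstance(wrt_angle, (tuple, list)):
        k, s = wrt_angle
        if not (0 <= k < arr.shape[0] and 0 <= s < arr.shape[1]):
            raise IndexError(f"angle index {wrt_angle} out of range")
        idx = (int(k), int(s))
    else:
        flat = int(wrt_angle)
        if not 0 <= flat < arr.size:
            raise IndexError(f"angle index {flat} out of range")
        idx = np.unravel_index(flat, arr.shape)
    if not 0 <= int(output_index) < spec.dim:
        raise IndexError(f"output index {output_index} out of range")

    shifted = arr.copy()
    shifted[idx] += np.pi / 2.0
    p_plus = probabilities(run_circuit(spec, shifted))[output_index]
    shifted[idx] -= np.pi
    p_minus = probabilities(run_circuit(spec, shifted))[output_index]
    return float((p_plus - p_minus) / 2.0)
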