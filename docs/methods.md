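# Methods

## The circuit and its conventions

Each variational circuit acts on N qubits initialised to |0…0⟩: a Hadamard
on every qubit, then K blocks of (RY layer, RX layer, CNOT layer). The CNOT
layer is a *ring*: qubit j controls qubit j+1 for j = 1…N, with the last
CNOT wrapping to qubit 1 — the natural reading of a strongly-entangling
block; a `chain` variant (no wrap) is exposed for ablation, and the
entangling layer is skipped for N = 1, where no pair exists. Basis index i
carries qubit 1 as its least-significant bit. Three rotation modes exist:
`ry_rx` (default; 2N angles per block), `ry_only` (N), and `minimal` (a
single RY on qubit 1 per block — the cheapest trainable circuit, used when
quoting minimum parameter counts, where one angle per circuit suffices).

Simulation is exact complex128 statevector arithmetic; there is no shot
noise or hardware noise model (a multinomial shot-sampling helper exists for
experimentation but is never used in parameter generation). Probabilities
are computed as |ψᵢ|² divided by Σ|ψᵢ|²; the divisor is 1 up to one ulp, and
the renormalization makes the zero-angle uniform state yield exactly
pᵢ = 2⁻ᴺ, so the shift-and-scale strategy's zero-angle kernel is exactly
zero rather than zero up to rounding — which is what makes the adapter
layer's "increment off" limit bitwise exact.

Gradients used in training are classical: adjoint (reverse-mode)
differentiation of the statevector, batched over a layer's circuits. The
backward pass for probabilities ignores the ulp-level renormalization term
(the normalizer is identically 1 in exact arithmetic). The two-point
parameter-shift rule, dp/dθ = [p(θ+π/2) − p(θ−π/2)]/2, is implemented as an
independent verification path and agrees with adjoint and finite-difference
gradients to better than 1e-6 in the test suite.

## From circuits to kernels

For a kernel W[C_in, C_out, K_h, K_w] the smaller channel axis is the
target; ties go to the input axis. One circuit per target channel and
kernel position gives min(C_in, C_out)·K_h·K_w circuits, each sized
⌈log₂ max(C_in, C_out)⌉ qubits (floor of one qubit). When
max(C_in, C_out) is not a power of two, the first max(C_in, C_out) basis
outcomes are used and the tail is discarded — the smallest circuit covering
the axis.

Post-processing strategies:

- **RCE** — yᵢ = Re(ψᵢ) ∈ [−1, 1]. Uses exact simulator amplitudes; no
  tomography emulation is attempted.
- **SST** — yᵢ = (π/2)(pᵢ − ½) ∈ [−π/4, π/4]. Parameter-free.
- **LPP** — yᵢ = w·(pᵢ ∥ d₀…d_k) + b, with (d_k…d₀)₂ = i. One (w, b) head
  is *shared across all circuits of a layer*, so LPP adds only
  qubits + 2 parameters per layer. The ledger reports circuit angles and
  head parameters separately; headline counts are quoted under SST, which
  adds none.

Trainable-parameter accounting is bias-free on both sides of the
comparison: QPG-managed layers have no bias term, and the classic count is
C_in·C_out·K_h·K_w. The low-rank baseline gives each kernel position its
own rank-r factorization of the C_out×C_in slice (trainable count
r·(C_in + C_out)·K_h·K_w); this per-position form — rather than a
flattened-matrix factorization — is the one consistent with the quoted
counts (9216 = 8·(64+64)·9). No α/r scaling is applied to the low-rank
update, and its B factor is zero-initialised so training starts at the
frozen base.

During training the kernel is regenerated from the angles at every forward
pass; `materialize()` caches it once for inference.

## The miniature segmentation model

The full UNext (tokenized-MLP stages) is reduced to a faithful conv-level
miniature, since the hybrid framework operates at the convolution level:
encoder1/block1/block2 are 3×3 conv stages separated by 2×2 max-pooling,
dblock1/dblock2 are 3×3 conv stages after nearest-neighbour upsampling with
skip concatenation, and finalconv is a 1×1 sigmoid head. With base width w
(default 8) the channel path 1→w→2w→4w→(6w→2w)→(3w→w)→1 exercises both
branches of the allocation rule. Input sizes divisible by 4 work; 32×32 is
the desk-scale default and 256×256 is supported unchanged.

Every stage except the head is conv → instance normalization → ReLU.
The normalization is load-bearing, not cosmetic: at uniform-[0, 1) angle
initialization an N-qubit circuit's probabilities all sit near 2⁻ᴺ, so an
SST kernel is nearly the constant (π/2)(2⁻ᴺ − ½) < 0. Convolving a
non-negative image with an almost-constant negative kernel and applying
ReLU yields identically zero activations *and* zero gradients — the layer
can never escape. Unnormalized LPP fails in the opposite direction
(unbounded activation scale). Per-sample instance normalization removes the
offset, rescales the informative angle-dependent variation to unit size,
and keeps outputs independent of batch composition (no running statistics,
deterministic evaluation). Classical conv stages carry a bias; QPG stages
do not (the counting contract above).

Eleven integration schemes name which of the six components are
quantum-trained; scheme 0 is fully classical. The per-component parameter
report itemizes classical weights (incl. norm affine parameters and biases)
against circuit angles.

## Training and evaluation

Adam with learning rate 0.001, weight decay 5e-4 (L2-coupled), batch size
8, 20 epochs, no learning-rate scheduler. Loss defaults to BCE + soft-Dice
(smoothing constant 1), the standard choice for binary medical
segmentation; plain BCE and Dice are configurable. Circuit angles are
initialised uniformly on [0, 1) radians and classical weights by fan-in
variance scaling — never all-zero, which would stall training. A fixed seed
makes runs bitwise reproducible (initialisation, batch order, and data all
derive from it). Non-finite losses abort with a diagnostic.

IoU and DSC are computed per test sample from masks binarised at 0.5
(configurable) and aggregated with equal sample weights; the reported
spread is the population standard deviation (divisor n). The 0/0 cases are
defined as: both masks empty → 1, exactly one empty → 0, so a correctly
predicted absent target scores perfect rather than undefined. When a test
split is supplied, the loop evaluates after every epoch and retains the
best-epoch test metrics as the run's result.

## The synthetic testbed

The generator emulates the data contract of single-channel abdominal CT
slices for kidney-tumor work: a bright, roughly elliptical organ (random
center in the central band, semi-axes 0.14–0.28 of the image side, random
orientation, fully in frame, area fraction ≈ 6–25%) on a darker background;
a smaller irregular hypodense tumor (harmonic-modulated boundary) strictly
inside the organ; a mild illumination ramp, light Gaussian smoothing, and
i.i.d. pixel noise (σ = 0.03 default), clipped to [0, 1]. Samples are
bit-reproducible per seed. The organ task uses full frames; the tumor task
crops the tight bounding box of organ ∪ tumor and resizes, mimicking
ROI-cropped tumor slices. Splits are 9:1 with the first 90% training.

What it does *not* emulate: HU windowing, 3-D structure and slice
correlation, scanner noise statistics, anatomical variability, ambiguous
boundaries, or class imbalance across slices (every synthetic frame
contains an organ). Passing the end-to-end tests therefore demonstrates
that the hybrid machinery trains and segments correctly — not that it
attains any particular accuracy on real CT.

## Problem sizes and defaults

Desk-scale defaults were chosen so the full workflow runs in minutes on one
CPU with exact simulation: 32×32 images, 200 samples, base width 8, one
circuit block (deeper circuits add parameters without changing behaviour
qualitatively). The end-to-end check trains the scheme-3 model for the full
20 epochs on five seeds; the parameter-recovery check fits a single 4→1
3×3 SST layer to a target kernel drawn from hidden random angles through
the same generator (an unconstrained target is unreachable: the Born rule
fixes each generated column's sum, so only model-family targets make the
recovery well-posed), using Adam at lr 0.05 for 500 steps.

## Known limitations

- Exact statevector simulation scales as O(2^N) per circuit; desk-scale
  widths keep N ≤ 6. Real-hardware effects (shot noise, decoherence,
  tomography cost for RCE) are out of scope.
- The numpy autodiff engine is single-threaded and eager; it is sized for
  the miniature model, not for 256×256 production training.
- The low-rank baseline and the quantum adapter share the convolution
  contract (cross-correlation, stride 1, same padding) but no other
  architectural tricks (no scaling factors, dropout, or merging schedules).
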