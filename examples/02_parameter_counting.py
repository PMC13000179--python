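"""Count trainable parameters: quantum generation vs classic vs low-rank.

Reproduces the headline accounting: a 64->1 3x3 layer needs 576 classical
weights but only 108 circuit angles; a 64->64 3x3 layer needs 36864 weights,
6912 angles, and 9216/18432 low-rank parameters at ranks 8/16.
"""

from qpgconv import allocate, classic_param_count, convlora_param_count, \
    count_trainable
from qpgconv.statevector import CircuitSpec

for c_in, c_out, k in [(64, 1, 3), (64, 64, 3)]:
    plan = allocate(c_in, c_out, k, k)
    circuit = CircuitSpec(plan.qubits_per_vqc, n_blocks=1)
    ledger = count_trainable(plan, circuit, strategy="sst")
    print(f"{c_in}->{c_out} {k}x{k}: target axis {plan.target_axis}, "
          f"{plan.n_vqcs} circuits of {plan.qubits_per_vqc} qubits")
    print(f"  quantum angles {ledger.vqc_params:>6d}   "
          f"classic weights {classic_param_count(c_in, c_out, k, k):>6d}")

for r in (8, 16):
    print(f"ConvLoRA rank {r} on 64->64 3x3: "
          f"{convlora_param_count(64, 64, 3, 3, r)} parameters")

# Logarithmic growth along the non-target axis: doubling the input channels
# of a c->1 3x3 layer adds one qubit per circuit (18 angles), while the
# classic count doubles.
for c in (64, 128, 256):
    plan = allocate(c, 1, 3, 3)
    ledger = count_trainable(plan, CircuitSpec(plan.qubits_per_vqc, 1), "sst")
    print(f"C_in={c:>3d}: quantum {ledger.vqc_params:>3d} vs "
          f"classic {classic_param_count(c, 1, 3, 3):>4d}")
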