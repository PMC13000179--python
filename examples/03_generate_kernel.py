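"""Generate a convolution kernel from circuits under each strategy.

A 6->2 2x2 layer gets 8 independent 3-qubit circuits (one per output channel
and kernel position); each circuit's measurement statistics are post-
processed into the 6 weights of its kernel column.
"""

import numpy as np

from qpgconv import QPGLayerConfig, allocate, generate_kernel

plan = allocate(6, 2, 2, 2)
print(f"plan: {plan.n_vqcs} circuits x {plan.qubits_per_vqc} qubits, "
      f"target axis = {plan.target_axis}, "
      f"{plan.values_per_vqc} values per circuit (2 of 8 outcomes unused)")

rng = np.random.default_rng(42)
for strategy in ("rce", "sst", "lpp"):
    config = QPGLayerConfig.init(plan, rng, strategy=strategy)
    kernel = generate_kernel(config).weights
    print(f"{strategy.upper()}: kernel shape {kernel.shape}, "
          f"range [{kernel.min():+.4f}, {kernel.max():+.4f}]")
# RCE stays inside [-1, 1] (amplitude real parts), SST inside
# [-pi/4, pi/4] ~ [-0.785, 0.785]; LPP is unbounded because its linear head
# is trainable.
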