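"""Adapter-style fine-tuning: quantum increments vs low-rank updates.

A frozen pre-trained kernel is refined either by a quantum-generated
increment (QPGAConv) or by a per-position low-rank factorization (ConvLoRA).
Both start exactly at the base kernel; only their small trainable sets move.
"""

import numpy as np

from qpgconv import ConvLoRA, QPGAConv, Tensor, conv2d

rng = np.random.default_rng(0)
base = rng.normal(0, 0.1, size=(2, 1, 3, 3))     # a "pre-trained" kernel
x = rng.normal(size=(1, 2, 8, 8))

adapter = QPGAConv(base, rng=rng, strategy="sst")
adapter.qpg.angles.data[:] = 0.0                 # 1-qubit circuits: p = 1/2
out = adapter(Tensor(x)).data
ref = conv2d(Tensor(x), Tensor(base)).data
print("quantum increment at zero angles:",
      np.abs(adapter.qpg.kernel().data).max())
print("adapter output == frozen-base conv:", np.array_equal(out, ref))
print("trainable angles:", adapter.ledger().vqc_params,
      "(vs", base.size, "base weights, which never receive gradient)")

lora = ConvLoRA(base, rank=1, rng=rng)
print("ConvLoRA rank-1 update at init:",
      np.abs(lora.effective_kernel().data - base).max(),
      "| trainable:", lora.param_count())
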