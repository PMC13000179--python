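"""Train the miniature segmentation model with hybrid quantum-classical
training on synthetic organ data.

Scheme 3 puts quantum-generated kernels at encoder1, block2 and dblock2
while the rest of the network trains classically; one Adam step updates
classical weights and circuit angles together.  Takes about half a minute
on one CPU.
"""

from qpgconv import (DatasetManifest, ModelSpec, TrainConfig, build_dataset,
                     build_model, dataset_arrays, train)

manifest = DatasetManifest(n_samples=200, size=32, seed=0)
train_samples, test_samples = build_dataset(manifest)
xtr, ytr = dataset_arrays(train_samples)
xte, yte = dataset_arrays(test_samples)
print(f"dataset: {len(train_samples)} train / {len(test_samples)} test, "
      f"{manifest.size}x{manifest.size}")

model = build_model(ModelSpec(size=32, scheme=3, strategy="sst"), seed=0)
totals = model.parameter_report()["totals"]
print(f"trainable: {totals['trainable_classical']} classical + "
      f"{totals['trainable_quantum']} quantum angles")

history = train(model, xtr, ytr, xte, yte, TrainConfig(epochs=20, seed=0))
for record in history.epochs[::5] + history.epochs[-1:]:
    print(f"epoch {record['epoch']:>2d}: loss {record['train_loss']:.4f}  "
          f"test IoU {record['test_iou']:.4f}  test DSC {record['test_dsc']:.4f}")
best = history.best_metrics
print(f"best epoch {history.best_epoch}: "
      f"IoU {best.iou_mean:.4f} +- {best.iou_std:.4f}, "
      f"DSC {best.dsc_mean:.4f} +- {best.dsc_std:.4f}")
# IoU/DSC are computed per test sample and then averaged, so small organs
# count as much as large ones.
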