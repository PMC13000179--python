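"""Tests for metrics, losses, and the hybrid training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qpgconv._tensor import Tensor
from qpgconv.data import DatasetManifest, build_dataset, dataset_arrays
from qpgconv.models import ModelSpec, build_model
from qpgconv.training import (MetricsReport, TrainConfig, aggregate, bce_loss,
                              dice_loss, dsc, evaluate, iou,
                              segmentation_loss, train, write_history_csv,
                              write_metrics_csv, write_summary_json)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return m


class TestIoUDsc:
    def test_identical_masks(self):
        m = _mask((4, 4), [(0, 0), (1, 1)])
        assert iou(m, m) == 1.0
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _mask((4, 4), [(0, 0)])
        b = _mask((4, 4), [(3, 3)])
        assert iou(a, b) == 0.0
        assert dsc(a, b) == 0.0

    def test_pixel_counting(self):
        """|A| = |B| = 4 with overlap 2: IoU = 2/6, DSC = 4/8."""
        a = _mask((4, 4), [(0, 0), (0, 1), (1, 0), (1, 1)])
        b = _mask((4, 4), [(1, 0), (1, 1), (2, 0), (2, 1)])
        assert iou(a, b) == pytest.approx(2 / 6)
        assert dsc(a, b) == pytest.approx(0.5)

    def test_empty_mask_conventions(self):
        empty = np.zeros((3, 3), dtype=bool)
        full = _mask((3, 3), [(1, 1)])
        assert iou(empty, empty) == 1.0 and dsc(empty, empty) == 1.0
        assert iou(empty, full) == 0.0 and dsc(full, empty) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_dsc_iou_identity_and_ordering(self, seed):
        """DSC = 2 IoU / (1 + IoU) and DSC >= IoU on random mask pairs."""
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) > 0.6
        b = rng.random((8, 8)) > 0.6
        i, d = iou(a, b), dsc(a, b)
        assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)
        assert d >= i
        assert 0.0 <= i <= 1.0 and 0.0 <= d <= 1.0


class TestAggregate:
    def test_mean_over_samples(self):
        a1 = _mask((2, 2), [(0, 0)])
        b2 = _mask((2, 2), [(0, 0), (0, 1)])
        report = aggregate([a1, b2], [a1, a1])
        assert report.iou_mean == pytest.approx((1.0 + 0.5) / 2)
        assert report.dsc.shape == (2,)

    def test_single_sample_std_zero(self):
        m = _mask((2, 2), [(0, 0)])
        report = aggregate([m], [m])
        assert report.iou_std == 0.0 and report.dsc_std == 0.0

    def test_constant_vector(self):
        m = _mask((2, 2), [(0, 0)])
        report = aggregate([m, m, m], [m, m, m])
        assert report.dsc_mean == 1.0 and report.dsc_std == 0.0

    def test_population_std(self):
        report = MetricsReport(iou=np.array([0.0, 1.0]), dsc=np.array([0.0, 1.0]))
        assert report.iou_std == pytest.approx(0.5)  # population divisor n

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], [])


class TestLosses:
    def test_bce_perfect_prediction_near_zero(self):
        y = Tensor(np.array([1.0, 0.0]))
        p = Tensor(np.array([1.0 - 1e-7, 1e-7]))
        assert bce_loss(p, y).item() < 1e-5

    def test_dice_loss_zero_on_match(self):
        y = Tensor(np.ones((2, 8)))
        assert dice_loss(y, y).item() == pytest.approx(0.0, abs=1e-6)

    def test_combined_is_sum(self, rng):
        p = Tensor(rng.uniform(0.1, 0.9, (4, 4)))
        y = Tensor((rng.random((4, 4)) > 0.5).astype(float))
        combined = segmentation_loss(p, y, "bce_plus_dice").item()
        assert combined == pytest.approx(
            bce_loss(p, y).item() + dice_loss(p, y).item())


@pytest.fixture(scope="module")
def toy_data():
    manifest = DatasetManifest(n_samples=16, size=16, seed=5)
    train_s, test_s = build_dataset(manifest)
    xtr, ytr = dataset_arrays(train_s)
    xte, yte = dataset_arrays(test_s)
    return xtr, ytr, xte, yte


class TestTrainLoop:
    def test_loss_decreases_on_easy_blob_data(self, toy_data):
        """One epoch on a few bright-blob samples: finite losses that drop
        within the first handful of steps."""
        xtr, ytr, _, _ = toy_data
        model = build_model(ModelSpec(scheme=0, base_width=4, size=16), seed=0)
        config = TrainConfig(epochs=1, batch_size=2, seed=0)
        history = train(model, xtr[:8], ytr[:8], config=config)
        losses = history.step_losses
        assert len(losses) == 4
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_identical_seeds_identical_curves(self, toy_data):
        xtr, ytr, xte, yte = toy_data
        curves = []
        for _ in range(2):
            model = build_model(ModelSpec(scheme=9, base_width=4, size=16),
                                seed=3)
            history = train(model, xtr[:8], ytr[:8], xte, yte,
                            TrainConfig(epochs=2, batch_size=4, seed=3))
            curves.append(history.step_losses)
        assert curves[0] == curves[1]

    def test_frozen_angles_keep_kernels_constant(self, toy_data):
        xtr, ytr, _, _ = toy_data
        model = build_model(ModelSpec(scheme=9, base_width=4, size=16), seed=2)
        model.freeze_quantum()
        kernels_before = [s.conv.kernel().data.copy()
                          for s in model.components().values() if s.quantum]
        train(model, xtr[:8], ytr[:8],
              config=TrainConfig(epochs=1, batch_size=4, seed=2))
        kernels_after = [s.conv.kernel().data
                         for s in model.components().values() if s.quantum]
        for before, after in zip(kernels_before, kernels_after):
            np.testing.assert_array_equal(before, after)

    def test_empty_dataset_rejected(self):
        model = build_model(ModelSpec(scheme=0, base_width=4, size=16), seed=0)
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 1, 16, 16)), np.zeros((0, 1, 16, 16)))

    def test_non_finite_loss_aborts_with_diagnostic(self, toy_data):
        xtr, ytr, _, _ = toy_data
        model = build_model(ModelSpec(scheme=0, base_width=4, size=16), seed=0)
        model.encoder1.conv.weight.data[:] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, xtr[:4], ytr[:4],
                  config=TrainConfig(epochs=1, batch_size=2, seed=0))

    def test_best_epoch_metrics_retained(self, toy_data):
        xtr, ytr, xte, yte = toy_data
        model = build_model(ModelSpec(scheme=0, base_width=4, size=16), seed=1)
        history = train(model, xtr, ytr, xte, yte,
                        TrainConfig(epochs=3, batch_size=4, seed=1))
        best = max(r["test_dsc"] for r in history.epochs)
        assert history.best_metrics.dsc_mean == pytest.approx(best)
        assert history.epochs[history.best_epoch]["test_dsc"] == \
            pytest.approx(best)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")


class TestHybridGradient:
    def test_backprop_matches_finite_difference_through_model(self, toy_data):
        """The loss gradient w.r.t. a circuit angle, obtained by backprop
        through the network and the simulator, matches a central finite
        difference through the whole model."""
        xtr, ytr, _, _ = toy_data
        model = build_model(ModelSpec(scheme=9, base_width=4, size=16), seed=4)
        x, y = Tensor(xtr[:2]), Tensor(ytr[:2])

        def loss_value():
            return segmentation_loss(model(x), y, "bce_plus_dice").item()

        model.zero_grad()
        segmentation_loss(model(x), y, "bce_plus_dice").backward()
        angles = model.block2.conv.angles
        rng = np.random.default_rng(0)
        flat_idx = rng.choice(angles.size, 5, replace=False)
        h = 1e-5
        for fi in flat_idx:
            idx = np.unravel_index(fi, angles.data.shape)
            orig = angles.data[idx]
            angles.data[idx] = orig + h
            fp = loss_value()
            angles.data[idx] = orig - h
            fm = loss_value()
            angles.data[idx] = orig
            assert angles.grad[idx] == pytest.approx((fp - fm) / (2 * h),
                                                     abs=1e-4)


class TestEvaluateAndWriters:
    def test_evaluate_shapes(self, toy_data):
        xtr, ytr, xte, yte = toy_data
        model = build_model(ModelSpec(scheme=0, base_width=4, size=16), seed=0)
        report = evaluate(model, xte, yte)
        assert report.iou.shape == (xte.shape[0],)
        assert np.all(report.dsc >= report.iou)

    def test_report_files(self, tmp_path):
        report = MetricsReport(iou=np.array([0.5, 1.0]), dsc=np.array([2 / 3, 1.0]))
        write_metrics_csv(report, tmp_path / "metrics.csv")
        write_summary_json(report, tmp_path / "summary.json")
        lines = (tmp_path / "metrics.csv").read_text().strip().splitlines()
        assert lines[0] == "sample,iou,dsc" and len(lines) == 3
        import json
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["n_samples"] == 2
        assert summary["iou_mean"] == pytest.approx(0.75)

    def test_history_csv(self, tmp_path, toy_data):
        xtr, ytr, xte, yte = toy_data
        model = build_model(ModelSpec(scheme=0, base_width=4, size=16), seed=0)
        history = train(model, xtr[:4], ytr[:4], xte, yte,
                        TrainConfig(epochs=2, batch_size=4, seed=0))
        write_history_csv(history, tmp_path / "history.csv")
        lines = (tmp_path / "history.csv").read_text().strip().splitlines()
        assert len(lines) == 3
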