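"""Tests for channel allocation, post-processing, and kernel generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qpgconv.generator import (LPPHead, QPGLayerConfig, allocate,
                               binary_encoding, count_trainable,
                               generate_kernel, kernel_tensor,
                               postprocess_lpp, postprocess_rce,
                               postprocess_sst)
from qpgconv.statevector import CircuitSpec, probabilities, simulate_batch
from qpgconv._tensor import Tensor


class TestAllocate:
    @pytest.mark.parametrize("dims,n_vqcs,qubits,axis", [
        ((512, 32, 2, 2), 128, 9, "output"),   # channel-downsampling scenario
        ((64, 256, 3, 3), 576, 8, "input"),    # channel-upsampling scenario
        ((64, 1, 3, 3), 9, 6, "output"),
        ((4, 4, 1, 1), 4, 2, "input"),         # tie goes to the input axis
        ((1, 1, 1, 1), 1, 1, "input"),         # qubit floor of 1
    ])
    def test_worked_examples(self, dims, n_vqcs, qubits, axis):
        plan = allocate(*dims)
        assert plan.n_vqcs == n_vqcs
        assert plan.qubits_per_vqc == qubits
        assert plan.target_axis == axis

    def test_rejects_non_positive_dimensions(self):
        for bad in [(0, 1, 1, 1), (1, -2, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)]:
            with pytest.raises(ValueError):
                allocate(*bad)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(c_in=st.integers(1, 600), c_out=st.integers(1, 600),
           k=st.integers(1, 7))
    def test_invariants(self, c_in, c_out, k):
        plan = allocate(c_in, c_out, k, k)
        assert plan.n_vqcs == min(c_in, c_out) * k * k
        assert plan.values_per_vqc == max(c_in, c_out)
        assert 2 ** plan.qubits_per_vqc >= plan.values_per_vqc
        assert plan.qubits_per_vqc == 1 or \
            2 ** (plan.qubits_per_vqc - 1) < plan.values_per_vqc
        assert plan.target_axis == ("input" if c_in <= c_out else "output")


class TestCountTrainable:
    def test_printed_counts(self):
        """Quantum ledger values for the layers whose counts are quoted."""
        cases = [((64, 1, 3, 3), "ry_rx", 108),
                 ((64, 64, 3, 3), "ry_rx", 6912),
                 ((4, 4, 1, 1), "minimal", 4)]
        for dims, rotations, expected in cases:
            plan = allocate(*dims)
            circ = CircuitSpec(plan.qubits_per_vqc, 1, rotations=rotations)
            assert count_trainable(plan, circ, "sst").vqc_params == expected

    def test_lpp_head_accounting(self):
        plan = allocate(64, 1, 3, 3)
        circ = CircuitSpec(plan.qubits_per_vqc, 1)
        ledger = count_trainable(plan, circ, "lpp")
        assert ledger.postprocess_params == plan.qubits_per_vqc + 2
        assert ledger.total == ledger.vqc_params + ledger.postprocess_params
        assert count_trainable(plan, circ, "sst").postprocess_params == 0
        assert count_trainable(plan, circ, "rce").postprocess_params == 0

    def test_blocks_scale_linearly(self):
        plan = allocate(8, 8, 3, 3)
        one = count_trainable(plan, CircuitSpec(3, 1), "sst").vqc_params
        three = count_trainable(plan, CircuitSpec(3, 3), "sst").vqc_params
        assert three == 3 * one

    def test_mismatched_circuit_rejected(self):
        plan = allocate(64, 1, 3, 3)
        with pytest.raises(ValueError):
            count_trainable(plan, CircuitSpec(3, 1), "sst")


class TestPostprocessing:
    def test_rce_is_real_part(self):
        amps = np.array([-0.6 + 0.8j, 0.0 + 1.0j])
        np.testing.assert_array_equal(postprocess_rce(amps), [-0.6, 0.0])

    def test_rce_uniform(self):
        np.testing.assert_allclose(
            postprocess_rce(np.full(4, 0.5 + 0j)), [0.5] * 4)

    def test_sst_endpoints(self):
        np.testing.assert_allclose(
            postprocess_sst(np.array([0.5, 1.0, 0.0])),
            [0.0, np.pi / 4, -np.pi / 4], atol=1e-12)

    def test_sst_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            postprocess_sst(np.array([1.2]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 999))
    def test_sst_range_property(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(8))
        y = postprocess_sst(p)
        assert np.all(y >= -np.pi / 4 - 1e-12)
        assert np.all(y <= np.pi / 4 + 1e-12)

    def test_lpp_binary_encoding(self):
        bits = binary_encoding(3)
        np.testing.assert_array_equal(bits[5], [1, 0, 1])  # 5 = (101)_2
        np.testing.assert_array_equal(bits[0], [0, 0, 0])
        np.testing.assert_array_equal(bits[6], [0, 1, 1])

    def test_lpp_constant_head(self):
        head = LPPHead(w=np.zeros(4), b=0.3)
        p = np.random.default_rng(0).dirichlet(np.ones(8))
        np.testing.assert_allclose(postprocess_lpp(p, head), 0.3)

    def test_lpp_identity_on_probability_slot(self):
        head = LPPHead(w=np.array([1.0, 0, 0, 0]), b=0.0)
        p = np.random.default_rng(1).dirichlet(np.ones(8))
        np.testing.assert_allclose(postprocess_lpp(p, head), p)

    def test_lpp_head_length_mismatch(self):
        with pytest.raises(ValueError):
            postprocess_lpp(np.full(8, 0.125), LPPHead(w=np.ones(2), b=0.0))


class TestGenerateKernel:
    def test_indexing_scenario(self):
        """With C_in > C_out the kernel entry (c_in, c_out, kh, kw) is output
        c_in of the circuit owned by (c_out, kh, kw)."""
        plan = allocate(6, 2, 2, 2)           # target axis = output
        rng = np.random.default_rng(0)
        cfg = QPGLayerConfig.init(plan, rng, strategy="sst")
        kernel = generate_kernel(cfg).weights
        assert kernel.shape == (6, 2, 2, 2)
        # circuit v owns target channel v // 4, position divmod(v % 4, 2)
        probs = probabilities(simulate_batch(cfg.circuit, cfg.angles))
        y = postprocess_sst(probs)
        for c_out in range(2):
            for kh in range(2):
                for kw in range(2):
                    v = c_out * 4 + kh * 2 + kw
                    np.testing.assert_array_equal(
                        kernel[:, c_out, kh, kw], y[v, :6])

    def test_input_target_indexing(self):
        plan = allocate(2, 5, 1, 1)           # target axis = input
        rng = np.random.default_rng(3)
        cfg = QPGLayerConfig.init(plan, rng, strategy="sst")
        kernel = generate_kernel(cfg).weights
        y = postprocess_sst(probabilities(simulate_batch(cfg.circuit, cfg.angles)))
        for c_in in range(2):
            np.testing.assert_array_equal(kernel[c_in, :, 0, 0], y[c_in, :5])

    def test_zero_angles_single_qubit_sst_gives_zero_kernel(self):
        plan = allocate(2, 1, 1, 1)
        cfg = QPGLayerConfig(plan=plan, circuit=CircuitSpec(1, 1), strategy="sst")
        kernel = generate_kernel(cfg).weights
        assert np.all(kernel == 0.0)

    def test_sst_kernel_bounded(self):
        plan = allocate(5, 3, 3, 3)
        cfg = QPGLayerConfig.init(plan, np.random.default_rng(9), strategy="sst")
        kernel = generate_kernel(cfg).weights
        assert np.abs(kernel).max() <= np.pi / 4 + 1e-12

    def test_rce_kernel_bounded(self):
        plan = allocate(5, 3, 3, 3)
        cfg = QPGLayerConfig.init(plan, np.random.default_rng(9), strategy="rce")
        kernel = generate_kernel(cfg).weights
        assert np.abs(kernel).max() <= 1.0 + 1e-12

    def test_channel_independence(self):
        """Perturbing one circuit's angles only changes the kernel slice of
        the target channel that owns it (exact slice locality)."""
        for dims in [(6, 2, 2, 2), (2, 6, 3, 1)]:
            plan = allocate(*dims)
            rng = np.random.default_rng(4)
            cfg = QPGLayerConfig.init(plan, rng, strategy="sst")
            base = generate_kernel(cfg).weights
            kpos = plan.k_h * plan.k_w
            for v in range(plan.n_vqcs):
                angles = cfg.angles.copy()
                angles[v] += 0.37
                pert = generate_kernel(QPGLayerConfig(
                    plan=plan, circuit=cfg.circuit, strategy="sst",
                    angles=angles)).weights
                changed = base != pert
                t, pos = divmod(v, kpos)
                kh, kw = divmod(pos, plan.k_w)
                owned = np.zeros_like(changed)
                if plan.target_axis == "output":
                    owned[:, t, kh, kw] = True
                else:
                    owned[t, :, kh, kw] = True
                assert changed.any()
                assert not np.any(changed & ~owned)

    def test_truncation_uses_first_outcomes(self):
        """Non-power-of-two channel count: exactly the first values_per_vqc
        basis outcomes are used, the tail ignored."""
        plan = allocate(6, 1, 1, 1)            # 6 values from 8 outcomes
        rng = np.random.default_rng(8)
        cfg = QPGLayerConfig.init(plan, rng, strategy="sst")
        kernel = generate_kernel(cfg).weights
        y = postprocess_sst(probabilities(simulate_batch(cfg.circuit, cfg.angles)))
        np.testing.assert_array_equal(kernel[:, 0, 0, 0], y[0, :6])

    def test_used_slice_probability_mass(self):
        """Each circuit's full 2^N probability vector sums to 1; the used
        slice therefore carries at most unit mass."""
        plan = allocate(6, 3, 2, 2)
        cfg = QPGLayerConfig.init(plan, np.random.default_rng(1), strategy="sst")
        p = probabilities(simulate_batch(cfg.circuit, cfg.angles))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p[:, :plan.values_per_vqc].sum(axis=1) <= 1.0 + 1e-10)

    def test_deterministic(self):
        plan = allocate(4, 3, 3, 3)
        cfg = QPGLayerConfig.init(plan, np.random.default_rng(6), strategy="lpp")
        k1 = generate_kernel(cfg).weights
        k2 = generate_kernel(cfg).weights
        np.testing.assert_array_equal(k1, k2)

    def test_autodiff_kernel_matches_plain(self):
        """kernel_tensor (autodiff path) and generate_kernel (plain path)
        agree bitwise for every strategy."""
        plan = allocate(5, 3, 2, 2)
        for strategy in ("sst", "rce", "lpp"):
            cfg = QPGLayerConfig.init(plan, np.random.default_rng(2),
                                      strategy=strategy)
            plain = generate_kernel(cfg).weights
            head_w = Tensor(cfg.head.w) if strategy == "lpp" else None
            head_b = Tensor(np.array(cfg.head.b)) if strategy == "lpp" else None
            auto = kernel_tensor(Tensor(cfg.angles), plan, cfg.circuit,
                                 strategy, head_w, head_b).data
            np.testing.assert_array_equal(plain, auto)

    def test_config_validation(self):
        plan = allocate(4, 4, 1, 1)
        with pytest.raises(ValueError):
            QPGLayerConfig(plan=plan, circuit=CircuitSpec(2, 1),
                           strategy="sst", angles=np.zeros((3, 1, 4)))
        with pytest.raises(ValueError):
            QPGLayerConfig(plan=plan, circuit=CircuitSpec(5, 1), strategy="sst")
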