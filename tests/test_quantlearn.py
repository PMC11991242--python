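"""Quantization machinery: codebook, loss, renormalization, hard rounding."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalchirp.grunet import NetworkConfig, forward, init_params, iter_neuron_rows
from vitalchirp.quantlearn import (
    NeuronAffine,
    QuantConfig,
    affine_dot,
    cross_entropy,
    hard_quantize,
    naive_quantize,
    normalize_neuron,
    quant_grid,
    quant_loss,
    quant_reg_grads,
    quantize_network,
    total_loss,
)


class TestQuantGrid:
    def test_two_bit_plus_sign_has_seven_levels(self):
        g = quant_grid(2)
        np.testing.assert_allclose(
            g, [-1, -2 / 3, -1 / 3, 0, 1 / 3, 2 / 3, 1]
        )

    def test_four_bit_plus_sign_has_31_levels_16_magnitudes(self):
        g = quant_grid(4)
        assert g.size == 31
        assert np.unique(np.abs(g)).size == 16
        assert QuantConfig(bit_depth=4).multiplier == 15

    def test_bit_depth_below_two_rejected(self):
        with pytest.raises(ValueError):
            quant_grid(1)

    def test_grid_points_are_loss_minima(self):
        for B in (2, 3, 4):
            assert quant_loss(quant_grid(B), B) == pytest.approx(0.0, abs=1e-9)


class TestQuantLoss:
    def test_zero_weight_and_on_grid_weights_cost_nothing(self):
        assert quant_loss([0.0], 4) == 0.0
        assert quant_loss([1 / 15], 4) == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_costs_exactly_one_per_weight(self):
        assert quant_loss([1 / 30], 4) == pytest.approx(1.0)
        assert quant_loss([1 / 30, -1 / 30, 3 / 30], 4) == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=20))
    def test_nonnegative_and_symmetric(self, ws):
        w = np.array(ws)
        assert quant_loss(w, 4) >= 0
        assert quant_loss(-w, 4) == pytest.approx(quant_loss(w, 4), rel=1e-9)

    def test_minima_spacing_is_one_over_multiplier(self):
        B, M = 4, 15
        mid = 7 / 30  # midpoint between 3/15 and 4/15
        offsets = np.linspace(0, 1 / M, 101)
        losses = np.array([quant_loss([mid + o], B) for o in offsets])
        # maximal at the midpoint, zero half a step later, maximal again
        assert losses[0] == pytest.approx(1.0)
        assert losses[50] == pytest.approx(0.0, abs=1e-9)
        assert losses[100] == pytest.approx(1.0)


class TestTotalLoss:
    logits = np.array([[2.0, -1.0], [0.5, 0.5]])
    labels = np.array([0, 1])

    def test_before_activation_epoch_is_pure_cce(self):
        qc = QuantConfig(lam=0.7)
        off_grid = [1 / 30]
        assert total_loss(self.logits, self.labels, off_grid, qc, epoch=1) == (
            pytest.approx(cross_entropy(self.logits, self.labels))
        )

    def test_lambda_zero_is_pure_cce_at_every_epoch(self):
        qc = QuantConfig(lam=0.0)
        for epoch in (1, 6, 20):
            assert total_loss(self.logits, self.labels, [1 / 30], qc, epoch) == (
                pytest.approx(cross_entropy(self.logits, self.labels))
            )

    def test_on_grid_weights_add_nothing_after_activation(self):
        qc = QuantConfig(lam=0.7)
        assert total_loss(self.logits, self.labels, [2 / 15, -1.0], qc, 6) == (
            pytest.approx(cross_entropy(self.logits, self.labels), rel=1e-9)
        )

    def test_off_grid_weights_are_penalized_after_activation(self):
        qc = QuantConfig(lam=0.7)
        cce = cross_entropy(self.logits, self.labels)
        assert total_loss(self.logits, self.labels, [1 / 30], qc, 6) == (
            pytest.approx(cce + 0.7)
        )


class TestNormalizeNeuron:
    def test_symmetric_vector(self):
        na = normalize_neuron([-2.0, 0.0, 2.0])
        np.testing.assert_allclose(na.w_hat, [-1, 0, 1])
        assert na.scale == 2.0 and na.offset == 0.0

    def test_shifted_vector(self):
        na = normalize_neuron([1.0, 3.0])
        np.testing.assert_allclose(na.w_hat, [-1, 1])
        assert na.scale == 1.0 and na.offset == 2.0

    def test_constant_vector_convention(self):
        na = normalize_neuron([0.7, 0.7])
        np.testing.assert_array_equal(na.w_hat, [0, 0])
        assert na.scale == 0.0 and na.offset == 0.7

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_extremes_map_to_plus_minus_one(self, seed, n):
        w = np.random.default_rng(seed).normal(size=n)
        if w.max() == w.min():
            return
        na = normalize_neuron(w)
        assert na.w_hat.min() == pytest.approx(-1.0)
        assert na.w_hat.max() == pytest.approx(1.0)


class TestAffineDot:
    def test_worked_example(self):
        na = normalize_neuron([1.0, 3.0])
        assert affine_dot([1.0, 1.0], na) == pytest.approx(4.0)

    def test_zero_input_gives_zero(self):
        na = NeuronAffine(np.array([0.5, -1.0]), 2.0, 3.0)
        assert affine_dot([0.0, 0.0], na) == 0.0

    def test_zero_offset_reduces_to_scaled_dot(self):
        na = NeuronAffine(np.array([0.5, -1.0]), 2.0, 0.0)
        x = np.array([1.0, 2.0])
        assert affine_dot(x, na) == pytest.approx(2.0 * (x @ na.w_hat))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            affine_dot([1.0], normalize_neuron([1.0, 2.0]))

    def test_identity_on_1000_random_draws(self):
        """k (x . w_hat) + B sum(x) reproduces x . w to 1e-12 relative."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            w = rng.normal(0, rng.uniform(0.1, 10), n)
            x = rng.normal(0, rng.uniform(0.1, 10), n)
            direct = float(x @ w)
            assert affine_dot(x, normalize_neuron(w)) == pytest.approx(
                direct, rel=1e-12, abs=1e-10
            )


class TestHardQuantize:
    grid = quant_grid(4)

    def test_nearest_level(self):
        assert hard_quantize(0.09, self.grid) == pytest.approx(1 / 15)

    def test_exact_levels_are_fixed_points(self):
        np.testing.assert_array_equal(hard_quantize(self.grid, self.grid), self.grid)

    def test_midpoint_ties_round_away_from_zero(self):
        assert hard_quantize(1 / 30, self.grid) == pytest.approx(1 / 15)
        assert hard_quantize(-1 / 30, self.grid) == pytest.approx(-1 / 15)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 1, 200)
        once = hard_quantize(v, self.grid)
        np.testing.assert_array_equal(hard_quantize(once, self.grid), once)

    def test_out_of_range_clips_to_extremes(self):
        assert hard_quantize(3.7, self.grid) == 1.0
        assert hard_quantize(-9.9, self.grid) == -1.0


class TestQuantizeNetwork:
    cfg = NetworkConfig(3, 4, 2, use_bn_dropout=True)
    qc = QuantConfig()

    def _trained_like_params(self, seed=0):
        params = init_params(self.cfg, seed)
        rng = np.random.default_rng(seed)
        for layer in params["layers"]:
            for k in layer:
                layer[k] += rng.normal(0, 0.2, layer[k].shape)
        params["bn"]["running_mean"] = rng.normal(0, 1, 3)
        params["bn"]["running_var"] = rng.uniform(0.5, 2, 3)
        return params

    def test_all_codes_within_codebook(self):
        qnet = quantize_network(self._trained_like_params(), self.cfg, self.qc)
        for grp in qnet.groups.values():
            for qn in grp.neurons:
                assert qn.codes.min() >= -15 and qn.codes.max() <= 15
                assert abs(qn.k_code) <= 15 and abs(qn.b_code) <= 15

    def test_idempotent(self):
        qnet = quantize_network(self._trained_like_params(), self.cfg, self.qc)
        qnet2 = quantize_network(qnet)
        X = np.random.default_rng(1).random((12, 3))
        np.testing.assert_allclose(
            forward(self.cfg, qnet.to_float_params(), X),
            forward(self.cfg, qnet2.to_float_params(), X),
            rtol=1e-9, atol=1e-12,
        )

    def test_reconstruction_error_bounded(self):
        """|w - reconstructed| <= k/(2M) (weight-code rounding) plus the
        relative slack of the logarithmic scale/offset codes (~15% each)."""
        params = self._trained_like_params()
        qnet = quantize_network(params, self.cfg, self.qc)
        rec = qnet.to_float_params()
        M = self.qc.multiplier
        rel = 0.18  # half a log step: 1 - sqrt(10^(-2/14)), with margin
        for (loc, row), (_, row2) in zip(
            iter_neuron_rows(params), iter_neuron_rows(rec)
        ):
            na = normalize_neuron(row)
            bound = (na.scale * (1 + rel) / (2 * M)
                     + rel * (abs(na.scale) + abs(na.offset)))
            assert np.max(np.abs(row - row2)) <= bound + 1e-9

    def test_quantized_forward_tracks_float_forward(self):
        params = self._trained_like_params()
        qnet = quantize_network(params, self.cfg, self.qc)
        X = np.random.default_rng(2).random((30, 3)) * 2
        a = forward(self.cfg, params, X)
        b = forward(self.cfg, qnet.to_float_params(), X)
        assert np.max(np.abs(a - b)) < 0.5  # coarse but close

    def test_diversification_distinguishes_identical_codes(self):
        """Same codebook indices + different (k, B) = different neurons."""
        codes = np.array([-1.0, 0.2, 1.0])
        n1 = NeuronAffine(codes, 1.0, 0.0)
        n2 = NeuronAffine(codes, 2.0, 0.5)
        x = np.array([0.3, 1.1, -0.7])
        assert affine_dot(x, n1) != pytest.approx(affine_dot(x, n2))

    def test_naive_quantization_rounds_in_place(self):
        params = self._trained_like_params()
        naive = naive_quantize(params, self.qc)
        g = quant_grid(4)
        for orig, rounded in zip(params["layers"], naive["layers"]):
            for k in orig:
                assert np.all(np.isin(np.round(rounded[k] * 15), np.arange(-15, 16)))
                np.testing.assert_allclose(
                    rounded[k],
                    hard_quantize(np.clip(orig[k], -1, 1), g).reshape(orig[k].shape),
                    atol=1e-12,
                )

    def test_quant_reg_grads_vanish_on_grid(self):
        """Rows whose normalized weights sit exactly on codebook levels
        (including the +-1 extremes, where sin carries a float residue)
        receive zero regularizer gradient."""
        params = init_params(NetworkConfig(2, 3, 1, use_bn_dropout=False), 0)
        for layer in params["layers"]:
            for k in layer:
                layer[k][...] = 0.0
            layer["W_r"][:, 0] = 1.0
            layer["W_r"][:, 1] = -1.0
            layer["U_r"][:, 0] = 1.0 / 15  # on-grid after normalization
        g = quant_reg_grads(params, self.qc)
        for layer in g["layers"]:
            for k in layer:
                np.testing.assert_allclose(layer[k], 0.0, atol=1e-8)
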