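"""Forward dynamics against brute-force per-equation oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deepconvlstm import (
    ModelSpec,
    build_model,
    count_parameters,
    load_model,
    model_forward,
    save_model,
)
from deepconvlstm.network import (
    ConvLayerParams,
    DenseLayerParams,
    LSTMLayerParams,
    LSTMState,
    _conv_preact,
    conv_layer_forward,
    dense_layer_forward,
    feature_map_length,
    lstm_layer_forward,
    lstm_step,
    softmax,
)

# ---------------------------------------------------------------------------
# brute-force oracles: plain python loops over the defining sums
# ---------------------------------------------------------------------------


def conv_oracle(x, kernels, bias):
    """Direct double-sum evaluation of the 1-D feature-map convolution."""
    f_out, f_in, P = kernels.shape
    _, d, s = x.shape
    out = np.zeros((f_out, d, s - P + 1))
    for j in range(f_out):
        for dd in range(d):
            for tau in range(s - P + 1):
                acc = bias[j]
                for f in range(f_in):
                    for p in range(P):
                        acc += kernels[j, f, p] * x[f, dd, tau + p]
                out[j, dd, tau] = max(acc, 0.0)
    return out


def lstm_step_oracle(a, h_prev, c_prev, p):
    """Scalar-calculator evaluation of one peephole-LSTM update."""

    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    i = sig(a @ p.W_ai + h_prev @ p.W_hi + p.w_ci * c_prev + p.b_i)
    f = sig(a @ p.W_af + h_prev @ p.W_hf + p.w_cf * c_prev + p.b_f)
    c = f * c_prev + i * np.tanh(a @ p.W_ac + h_prev @ p.W_hc + p.b_c)
    o = sig(a @ p.W_ao + h_prev @ p.W_ho + p.w_co * c + p.b_o)
    h = o * np.tanh(c)
    return h, c


def random_lstm_params(rng, n_in, n):
    mats = {
        k: rng.normal(scale=0.5, size=(n_in, n))
        for k in ("W_ai", "W_af", "W_ac", "W_ao")
    }
    mats.update(
        {k: rng.normal(scale=0.5, size=(n, n))
         for k in ("W_hi", "W_hf", "W_hc", "W_ho")}
    )
    mats.update(
        {k: rng.normal(scale=0.5, size=n)
         for k in ("w_ci", "w_cf", "w_co", "b_i", "b_f", "b_c", "b_o")}
    )
    return LSTMLayerParams(**mats)


# ---------------------------------------------------------------------------
# feature-map length
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("s, p, expected", [(24, 5, 20), (5, 5, 1), (10, 3, 8)])
def test_feature_map_length(s, p, expected):
    assert feature_map_length(s, p) == expected


def test_feature_map_length_through_four_layers():
    s = 24
    for _ in range(4):
        s = feature_map_length(s, 5)
    assert s == 8


def test_feature_map_length_rejects_short_input():
    with pytest.raises(ValueError, match="kernel longer than input"):
        feature_map_length(4, 5)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


class TestConvLayer:
    def test_zero_kernels_pass_bias_through_relu(self):
        p = ConvLayerParams(kernels=np.zeros((2, 1, 5)), bias=np.full(2, 0.3))
        out = conv_layer_forward(np.zeros((1, 3, 10)), p)
        np.testing.assert_allclose(out, 0.3)
        assert out.shape == (2, 3, 6)

    def test_delta_kernel_shifts_input(self, rng):
        x = rng.random((1, 2, 10))  # non-negative, ReLU inactive
        k = np.zeros((1, 1, 5))
        k[0, 0, 0] = 1.0
        p = ConvLayerParams(kernels=k, bias=np.zeros(1))
        out = conv_layer_forward(x, p)
        np.testing.assert_allclose(out[0], x[0, :, :6], atol=1e-15)

    def test_matches_double_sum_oracle(self, rng):
        x = rng.normal(size=(1, 3, 10))
        p = ConvLayerParams(
            kernels=rng.normal(size=(2, 1, 5)), bias=rng.normal(size=2)
        )
        out = conv_layer_forward(x, p)
        expected = conv_oracle(x, p.kernels, p.bias)
        np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-12)

    def test_multi_map_batched_matches_oracle(self, rng):
        x = rng.normal(size=(4, 3, 2, 12))
        p = ConvLayerParams(
            kernels=rng.normal(size=(5, 3, 5)), bias=rng.normal(size=5)
        )
        out = conv_layer_forward(x, p)
        for b in range(4):
            np.testing.assert_allclose(
                out[b], conv_oracle(x[b], p.kernels, p.bias),
                rtol=1e-10, atol=1e-12,
            )

    def test_preactivation_is_linear(self, rng):
        p = ConvLayerParams(
            kernels=rng.normal(size=(3, 2, 5)), bias=np.zeros(3)
        )
        x = rng.normal(size=(1, 2, 4, 15))
        y = rng.normal(size=(1, 2, 4, 15))
        a, b = 0.7, -1.3
        lhs = _conv_preact(a * x + b * y, p)
        rhs = a * _conv_preact(x, p) + b * _conv_preact(y, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_translation_equivariance_in_valid_region(self, rng):
        p = ConvLayerParams(
            kernels=rng.normal(size=(2, 1, 5)), bias=rng.normal(size=2)
        )
        motif = rng.normal(size=8)
        x = np.zeros((1, 1, 30))
        x[0, 0, 3 : 3 + 8] = motif
        y = np.zeros((1, 1, 30))
        y[0, 0, 10 : 10 + 8] = motif
        ox = conv_layer_forward(x, p)  # valid length 26
        oy = conv_layer_forward(y, p)
        # response to the motif shifted by 7 is the response shifted by 7
        np.testing.assert_allclose(ox[:, :, 0:19], oy[:, :, 7:26], atol=1e-12)

    def test_map_count_mismatch_raises(self, rng):
        p = ConvLayerParams(kernels=np.zeros((2, 3, 5)), bias=np.zeros(2))
        with pytest.raises(ValueError, match="mismatch"):
            conv_layer_forward(rng.random((1, 2, 10)), p)


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------


class TestLSTM:
    def test_zero_parameters_give_zero_state(self, rng):
        p = random_lstm_params(rng, 2, 3)
        for name, arr in p.arrays("x"):
            arr[...] = 0.0
        state = lstm_step(rng.normal(size=2), LSTMState.zeros(3), p)
        np.testing.assert_array_equal(state.h, 0.0)
        np.testing.assert_array_equal(state.c, 0.0)

    def test_saturated_forget_gate_preserves_cell(self, rng):
        p = random_lstm_params(rng, 2, 3)
        p.W_ac[...] = 0.0
        p.W_hc[...] = 0.0
        p.b_c[...] = 0.0  # candidate input path silenced
        p.b_f[...] = 100.0  # forget gate saturated open
        p.W_af[...] = 0.0
        p.W_hf[...] = 0.0
        p.w_cf[...] = 0.0
        c_prev = rng.normal(size=3)
        state = lstm_step(
            rng.normal(size=2), LSTMState(h=np.zeros(3), c=c_prev.copy()), p
        )
        np.testing.assert_allclose(state.c, c_prev, rtol=1e-12)

    def test_three_steps_match_scalar_oracle(self, rng):
        p = random_lstm_params(rng, 2, 1)
        h = np.zeros(1)
        c = np.zeros(1)
        state = LSTMState.zeros(1)
        for _ in range(3):
            a = rng.normal(size=2)
            h, c = lstm_step_oracle(a, h, c, p)
            state = lstm_step(a, state, p)
            np.testing.assert_allclose(state.h, h, rtol=1e-12)
            np.testing.assert_allclose(state.c, c, rtol=1e-12)

    def test_layer_forward_single_step_reduces_to_step(self, rng):
        p = random_lstm_params(rng, 3, 4)
        a = rng.normal(size=(1, 3))
        hs = lstm_layer_forward(a, p)
        step = lstm_step(a[0], LSTMState.zeros(4), p)
        np.testing.assert_allclose(hs[0], step.h, rtol=1e-12)

    def test_layer_forward_chains_steps(self, rng):
        p = random_lstm_params(rng, 3, 4)
        seq = rng.normal(size=(4, 3))
        hs = lstm_layer_forward(seq, p)
        state = LSTMState.zeros(4)
        for t in range(4):
            state = lstm_step(seq[t], state, p)
            np.testing.assert_allclose(hs[t], state.h, rtol=1e-12)

    def test_empty_sequence_raises(self, rng):
        p = random_lstm_params(rng, 3, 4)
        with pytest.raises(ValueError, match="empty"):
            lstm_layer_forward(np.zeros((0, 3)), p)

    def test_input_width_mismatch_raises(self, rng):
        p = random_lstm_params(rng, 3, 4)
        with pytest.raises(ValueError, match="width"):
            lstm_step(np.zeros(5), LSTMState.zeros(4), p)


# ---------------------------------------------------------------------------
# dense and softmax
# ---------------------------------------------------------------------------


class TestDenseSoftmax:
    def test_identity_weights_pass_nonnegative_input(self, rng):
        x = rng.random(4)
        p = DenseLayerParams(W=np.eye(4), b=np.zeros(4), activation="relu")
        np.testing.assert_allclose(dense_layer_forward(x, p), x)

    def test_zero_weights_broadcast_bias(self, rng):
        b = rng.normal(size=3)
        p = DenseLayerParams(W=np.zeros((5, 3)), b=b, activation="relu")
        np.testing.assert_allclose(
            dense_layer_forward(rng.normal(size=5), p), np.maximum(b, 0)
        )

    def test_matches_matvec_oracle(self, rng):
        W = rng.normal(size=(6, 4))
        b = rng.normal(size=4)
        x = rng.normal(size=6)
        p = DenseLayerParams(W=W, b=b, activation="relu")
        expected = np.array(
            [max(sum(W[i, j] * x[i] for i in range(6)) + b[j], 0.0)
             for j in range(4)]
        )
        np.testing.assert_allclose(dense_layer_forward(x, p), expected,
                                   rtol=1e-10)

    def test_softmax_uniform_for_equal_logits(self):
        np.testing.assert_allclose(softmax(np.full(5, 3.7)), 0.2)

    def test_softmax_closed_form(self):
        out = softmax(np.log([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [1 / 6, 2 / 6, 3 / 6], rtol=1e-12)

    @given(shift=st.floats(-500, 500))
    def test_softmax_shift_invariance(self, shift):
        z = np.array([0.3, -1.2, 2.5, 0.0])
        np.testing.assert_allclose(
            softmax(z + shift), softmax(z), rtol=1e-12, atol=1e-15
        )


# ---------------------------------------------------------------------------
# model assembly and full forward
# ---------------------------------------------------------------------------


class TestModelAssembly:
    def test_full_scale_layer_widths(self):
        lstm = ModelSpec(variant="lstm", n_channels=113, n_classes=18,
                         window_len=24)
        cnn = ModelSpec(variant="cnn", n_channels=113, n_classes=18,
                        window_len=24)
        assert lstm.recurrent_input_width == 7232
        assert cnn.flattened_width == 57856
        assert lstm.final_map_len == 8

    def test_too_short_window_raises(self):
        with pytest.raises(ValueError, match="window_len"):
            ModelSpec(window_len=16)  # needs >= 4*(5-1)+1 = 17

    def test_same_seed_builds_identical_parameters(self, tiny_lstm_spec):
        a = build_model(tiny_lstm_spec, seed=7)
        b = build_model(tiny_lstm_spec, seed=7)
        for (na, xa), (nb, xb) in zip(a.arrays(), b.arrays()):
            assert na == nb
            np.testing.assert_array_equal(xa, xb)

    @pytest.mark.parametrize("variant", ["lstm", "cnn"])
    def test_parameter_counts_match_closed_forms(self, variant):
        spec = ModelSpec(variant=variant, n_channels=9, n_classes=6,
                         window_len=30, n_maps=12, n_hidden=10)
        m = build_model(spec, 0)
        table = count_parameters(m)
        F, P, n, nc = 12, 5, 10, 6
        counts = [row["count"] for row in table["layers"]]
        assert counts[0] == F * P + F
        assert counts[1] == counts[2] == counts[3] == F * F * P + F
        s5 = 30 - 4 * (P - 1)
        if variant == "lstm":
            n_in = F * 9
            assert counts[4] == 4 * n * n_in + 4 * n * n + 4 * n + 3 * n
            assert counts[5] == 4 * n * n + 4 * n * n + 4 * n + 3 * n
        else:
            n_in = F * 9 * s5
            assert counts[4] == n_in * n + n
            assert counts[5] == n * n + n
        assert counts[6] == n * nc + nc
        assert table["total"] == sum(counts)

    @pytest.mark.parametrize("n_conv", [2, 3, 4, 5])
    def test_shape_conservation_through_stack(self, n_conv, rng):
        spec = ModelSpec(variant="lstm", n_channels=3, n_classes=2,
                         window_len=40, n_conv_layers=n_conv, n_maps=4,
                         n_hidden=5)
        m = build_model(spec, 0)
        x = rng.random((2, 1, 3, 40))
        s = 40
        for conv in m.conv_layers:
            x = conv_layer_forward(x, conv)
            s -= 4
            assert x.shape == (2, 4, 3, s)


class TestModelForward:
    @pytest.mark.parametrize("variant", ["lstm", "cnn"])
    def test_output_is_distribution(self, variant, rng):
        spec = ModelSpec(variant=variant, n_channels=2, n_classes=3,
                         window_len=17, n_maps=3, n_hidden=4)
        m = build_model(spec, 3)
        probs = model_forward(rng.random((5, 2, 17)), m)
        assert probs.shape == (5, 3)
        assert (probs > 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)

    def test_windows_are_independent(self, tiny_lstm_spec, rng):
        m = build_model(tiny_lstm_spec, 3)
        batch = rng.random((4, 2, 17))
        full = model_forward(batch, m)
        for i in range(4):
            np.testing.assert_allclose(
                model_forward(batch[i], m), full[i], rtol=1e-12
            )

    def test_recurrent_forward_matches_layer_oracles(self, rng):
        """Full model equals the per-layer composition with the final
        prediction read at the last time step."""
        spec = ModelSpec(variant="lstm", n_channels=2, n_classes=2,
                         window_len=17, n_maps=3, n_hidden=4)
        m = build_model(spec, 11)
        window = rng.random((2, 17))

        x = window[None, :, :]
        for conv in m.conv_layers:
            x = conv_oracle(x, conv.kernels, conv.bias)
        f, d, s5 = x.shape
        seq = x.transpose(2, 0, 1).reshape(s5, f * d)  # map-major flatten
        h = lstm_layer_forward(seq, m.hidden_layers[0])
        h = lstm_layer_forward(h, m.hidden_layers[1])
        expected = softmax(h[-1] @ m.output_layer.W + m.output_layer.b)

        np.testing.assert_allclose(
            model_forward(window, m), expected, rtol=1e-10
        )

    def test_baseline_forward_matches_layer_oracles(self, rng):
        spec = ModelSpec(variant="cnn", n_channels=2, n_classes=2,
                         window_len=17, n_maps=3, n_hidden=4)
        m = build_model(spec, 11)
        window = rng.random((2, 17))

        x = window[None, :, :]
        for conv in m.conv_layers:
            x = conv_oracle(x, conv.kernels, conv.bias)
        flat = x.ravel()  # map, channel, time order
        a = dense_layer_forward(flat, m.hidden_layers[0])
        a = dense_layer_forward(a, m.hidden_layers[1])
        expected = dense_layer_forward(a, m.output_layer)

        np.testing.assert_allclose(
            model_forward(window, m), expected, rtol=1e-10
        )

    def test_shape_mismatch_raises(self, tiny_lstm_spec, rng):
        m = build_model(tiny_lstm_spec, 0)
        with pytest.raises(ValueError, match="shape"):
            model_forward(rng.random((3, 16)), m)


def test_save_load_round_trip_bit_exact(tmp_path, tiny_lstm_spec, rng):
    m = build_model(tiny_lstm_spec, 5)
    for _, arr in m.arrays():
        arr += rng.normal(size=arr.shape)  # perturb away from init
    path = tmp_path / "model.npz"
    save_model(m, path)
    loaded = load_model(path)
    assert loaded.spec == m.spec
    for (na, xa), (nb, xb) in zip(m.arrays(), loaded.arrays()):
        assert na == nb
        np.testing.assert_array_equal(xa, xb)
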