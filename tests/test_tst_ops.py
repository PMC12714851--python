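"""Operator-level checks against brute-force oracles."""

import numpy as np
import pytest

from neuroedge.tst_model.ops import (
    ffn,
    multi_head_attention,
    positional_encoding,
    softmax,
    temporal_conv,
    temporal_shift,
)


# -- brute-force oracles -----------------------------------------------------


def conv_oracle(X, W, b):
    T, F = X.shape
    K = W.shape[0]
    Y = np.zeros((T, F))
    for t in range(T):
        for f in range(F):
            acc = 0.0
            for k in range(1, K + 1):
                if t - k >= 0:
                    acc += X[t - k, f] * W[k - 1, f]
            Y[t, f] = acc + (b[f] if np.ndim(b) else b)
    return Y


def attention_oracle(Q, K_in, V, params, h):
    d = Q.shape[-1]
    dk = d // h
    Qp, Kp, Vp = Q @ params["Wq"], K_in @ params["Wk"], V @ params["Wv"]
    heads = []
    for i in range(h):
        q = Qp[:, i * dk : (i + 1) * dk]
        k = Kp[:, i * dk : (i + 1) * dk]
        v = Vp[:, i * dk : (i + 1) * dk]
        s = q @ k.T / np.sqrt(dk)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        heads.append(a @ v)
    return np.concatenate(heads, axis=1) @ params["Wo"]


def ffn_oracle(x, params):
    z = x @ params["W1"] + params["b1"]
    return np.where(z > 0, z, 0.0) @ params["W2"] + params["b2"]


# -- temporal convolution ----------------------------------------------------


class TestTemporalConv:
    def test_k1_is_unit_delay(self):
        X = np.arange(1.0, 6.0)[:, None]
        Y = temporal_conv(X, np.array([[1.0]]), 0.0)
        np.testing.assert_array_equal(Y[:, 0], [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_bias_only(self):
        X = np.random.default_rng(0).normal(size=(7, 3))
        Y = temporal_conv(X, np.zeros((4, 3)), 0.5)
        np.testing.assert_allclose(Y, 0.5)

    def test_spec_example(self):
        X = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        Y = temporal_conv(X, np.array([1.0, -1.0]), 0.0)
        np.testing.assert_allclose(Y[:, 0], [0.0, 1.0, 1.0, 1.0])

    def test_feature_mismatch_raises(self):
        with pytest.raises(ValueError, match="feature"):
            temporal_conv(np.zeros((5, 3)), np.zeros((2, 4)))

    def test_100_random_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            T = int(rng.integers(2, 12))
            F = int(rng.integers(1, 5))
            K = int(rng.integers(1, 6))
            X = rng.normal(size=(T, F))
            W = rng.normal(size=(K, F))
            b = rng.normal(size=F)
            np.testing.assert_allclose(
                temporal_conv(X, W, b), conv_oracle(X, W, b), atol=1e-9
            )


# -- temporal shift ----------------------------------------------------------


class TestTemporalShift:
    def test_fraction_zero_identity(self, rng):
        X = rng.normal(size=(6, 8))
        np.testing.assert_array_equal(temporal_shift(X, 0.0), X)

    def test_shape_preserved(self, rng):
        for shape in [(3, 4), (10, 16), (2, 5, 8)]:
            X = rng.normal(size=shape)
            assert temporal_shift(X, 0.25).shape == shape

    def test_index_bookkeeping_4x4(self):
        X = np.arange(16.0).reshape(4, 4)
        Y = temporal_shift(X, 0.25)
        # column 0 delayed by one step
        np.testing.assert_array_equal(Y[:, 0], [0.0, X[0, 0], X[1, 0], X[2, 0]])
        # column 1 advanced by one step
        np.testing.assert_array_equal(Y[:, 1], [X[1, 1], X[2, 1], X[3, 1], 0.0])
        # columns 2-3 unchanged
        np.testing.assert_array_equal(Y[:, 2:], X[:, 2:])

    def test_interior_round_trip(self, rng):
        # delay then advance restores interior rows of the delayed block
        X = rng.normal(size=(10, 8))
        Y = temporal_shift(temporal_shift(X, 0.25), 0.25)
        m = 2
        # after two applications the delayed block is shifted twice
        np.testing.assert_allclose(Y[2:, :m], X[:-2, :m])

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            temporal_shift(np.zeros((4, 4)), 0.75)


# -- positional encoding -----------------------------------------------------


class TestPositionalEncoding:
    def test_row_zero(self):
        pe = positional_encoding(5, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_range(self):
        pe = positional_encoding(100, 16)
        assert pe.min() >= -1.0 and pe.max() <= 1.0

    def test_direct_evaluation(self):
        pe = positional_encoding(4, 4)
        assert pe[3, 0] == pytest.approx(np.sin(3.0), abs=1e-12)
        assert pe[3, 1] == pytest.approx(np.cos(3.0), abs=1e-12)
        assert pe[2, 2] == pytest.approx(np.sin(2.0 / 10000.0 ** (2.0 / 4.0)), abs=1e-12)

    def test_odd_d_raises(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding(4, 5)


# -- attention ---------------------------------------------------------------


def identity_params(d):
    eye = np.eye(d)
    return {"Wq": eye.copy(), "Wk": eye.copy(), "Wv": eye.copy(), "Wo": eye.copy()}


class TestAttention:
    def test_identical_keys_average_values(self, rng):
        d = 4
        Q = rng.normal(size=(5, d))
        K_in = np.tile(rng.normal(size=(1, d)), (5, 1))
        V = rng.normal(size=(5, d))
        out = multi_head_attention(Q, K_in, V, identity_params(d), h=1)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (5, 1)), atol=1e-9)

    def test_single_head_equals_plain_attention(self, rng):
        d = 4
        Q, K_in, V = (rng.normal(size=(3, d)) for _ in range(3))
        params = identity_params(d)
        out = multi_head_attention(Q, K_in, V, params, h=1)
        s = Q @ K_in.T / np.sqrt(d)
        np.testing.assert_allclose(out, softmax(s, axis=-1) @ V, atol=1e-12)

    def test_two_token_toy_matches_oracle(self):
        rng = np.random.default_rng(7)
        Q, K_in, V = (rng.normal(size=(2, 2)) for _ in range(3))
        params = {k: rng.normal(size=(2, 2)) for k in ("Wq", "Wk", "Wv", "Wo")}
        np.testing.assert_allclose(
            multi_head_attention(Q, K_in, V, params, h=1),
            attention_oracle(Q, K_in, V, params, 1),
            atol=1e-9,
        )

    def test_indivisible_width_raises(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            multi_head_attention(
                np.zeros((2, 6)), np.zeros((2, 6)), np.zeros((2, 6)), identity_params(6), h=4
            )

    def test_100_random_instances_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            h = int(rng.choice([1, 2, 4]))
            dk = int(rng.integers(1, 4))
            d = h * dk
            T = int(rng.integers(1, 6))
            Q, K_in, V = (rng.normal(size=(T, d)) for _ in range(3))
            params = {k: rng.normal(size=(d, d)) for k in ("Wq", "Wk", "Wv", "Wo")}
            np.testing.assert_allclose(
                multi_head_attention(Q, K_in, V, params, h),
                attention_oracle(Q, K_in, V, params, h),
                atol=1e-9,
            )


# -- FFN ---------------------------------------------------------------------


class TestFFN:
    def test_relu_kills_first_term(self):
        params = {
            "W1": np.eye(2),
            "b1": np.full(2, -100.0),
            "W2": np.ones((2, 2)),
            "b2": np.array([3.0, -1.0]),
        }
        x = np.random.default_rng(0).uniform(0, 1, size=(4, 2))
        out = ffn(x, params)
        np.testing.assert_allclose(out, np.tile(params["b2"], (4, 1)))

    def test_identity_composition(self, rng):
        x = np.abs(rng.normal(size=(3, 4)))
        params = {"W1": np.eye(4), "b1": np.zeros(4), "W2": np.eye(4), "b2": np.zeros(4)}
        np.testing.assert_allclose(ffn(x, params), x)

    def test_random_3x4_matches_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 4))
        params = {
            "W1": rng.normal(size=(4, 6)),
            "b1": rng.normal(size=6),
            "W2": rng.normal(size=(6, 4)),
            "b2": rng.normal(size=4),
        }
        np.testing.assert_allclose(ffn(x, params), ffn_oracle(x, params), atol=1e-9)

    def test_100_random_instances_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            T = int(rng.integers(1, 6))
            din = int(rng.integers(1, 5))
            dh = int(rng.integers(1, 7))
            x = rng.normal(size=(T, din))
            params = {
                "W1": rng.normal(size=(din, dh)),
                "b1": rng.normal(size=dh),
                "W2": rng.normal(size=(dh, din)),
                "b2": rng.normal(size=din),
            }
            np.testing.assert_allclose(ffn(x, params), ffn_oracle(x, params), atol=1e-9)
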