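"""Core sequence operators of the temporal-shift transformer.

These are plain functional forms over ``(time, features)`` arrays (leading
batch axes are accepted where noted) so each operator can be checked against
brute-force oracles independently of the assembled network.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "temporal_conv",
    "temporal_shift",
    "positional_encoding",
    "multi_head_attention",
    "ffn",
    "softmax",
]


def temporal_conv(X: np.ndarray, W: np.ndarray, b: np.ndarray | float = 0.0) -> np.ndarray:
    """Strictly causal depthwise temporal convolution.

    ``Y[t, f] = sum_{k=1..K} X[t - k, f] * W[k - 1, f] + b[f]`` — the current
    sample is excluded (the lag index starts at 1) and the left edge is
    zero-padded so the output length equals the input length.

    ``X`` is ``(..., time, features)``; ``W`` is ``(K, features)`` or ``(K,)``
    (broadcast over features).
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n_feat = X.shape[-1]
    if W.shape[1] not in (1, n_feat):
        raise ValueError(f"W has {W.shape[1]} feature columns but X has {n_feat}")
    K = W.shape[0]
    T = X.shape[-2]
    Y = np.zeros_like(X)
    for k in range(1, min(K, T - 1) + 1):
        Y[..., k:, :] += X[..., : T - k, :] * W[k - 1]
    return Y + np.asarray(b, dtype=float)


def temporal_shift(X: np.ndarray, shift_fraction: float) -> np.ndarray:
    """Shift feature blocks one step in time; vacated slots become zero.

    The first ``floor(fraction * n_features)`` columns are delayed by one
    step, the next block of the same size is advanced by one step, and the
    rest pass through unchanged.  Shape is preserved.
    """
    if not 0.0 <= shift_fraction <= 0.5:
        raise ValueError("shift_fraction must be in [0, 0.5]")
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[-1]
    m = int(shift_fraction * n_feat)
    Y = X.copy()
    if m == 0:
        return Y
    Y[..., 1:, :m] = X[..., :-1, :m]
    Y[..., 0, :m] = 0.0
    Y[..., :-1, m : 2 * m] = X[..., 1:, m : 2 * m]
    Y[..., -1, m : 2 * m] = 0.0
    return Y


def positional_encoding(length: int, d: int) -> np.ndarray:
    """Sinusoidal position table ``(length, d)``.

    Even columns hold ``sin(pos / 10000^(2i/d))``, odd columns the matching
    cosine.
    """
    if d % 2 != 0:
        raise ValueError("encoding dimensionality d must be even")
    pos = np.arange(length)[:, None].astype(float)
    i = np.arange(d // 2)[None, :].astype(float)
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.empty((length, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    """(..., T, d) -> (..., h, T, d//h)"""
    *lead, T, d = x.shape
    x = x.reshape(*lead, T, h, d // h)
    return np.moveaxis(x, -2, -3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    """(..., h, T, dk) -> (..., T, h*dk)"""
    x = np.moveaxis(x, -3, -2)
    *lead, T, h, dk = x.shape
    return x.reshape(*lead, T, h * dk)


def multi_head_attention(
    Q: np.ndarray,
    K_in: np.ndarray,
    V: np.ndarray,
    params: dict[str, np.ndarray],
    h: int,
) -> np.ndarray:
    """Scaled dot-product attention over ``h`` parallel heads.

    ``params`` holds the projection matrices ``Wq``, ``Wk``, ``Wv`` (model
    width -> model width) and the output projection ``Wo``.  Queries, keys,
    and values are projected, split into heads, attended with
    ``softmax(Q'K'^T / sqrt(d_k)) V'``, concatenated, and reprojected.
    """
    Q = np.asarray(Q, dtype=float)
    K_in = np.asarray(K_in, dtype=float)
    V = np.asarray(V, dtype=float)
    d = Q.shape[-1]
    if d % h != 0:
        raise ValueError(f"width {d} not divisible by {h} heads")
    q = _split_heads(Q @ params["Wq"], h)
    k = _split_heads(K_in @ params["Wk"], h)
    v = _split_heads(V @ params["Wv"], h)
    dk = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(dk)
    attn = softmax(scores, axis=-1)
    out = _merge_heads(attn @ v)
    return out @ params["Wo"]


def ffn(x: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """Position-wise two-layer ReLU network: ``max(0, x W1 + b1) W2 + b2``."""
    x = np.asarray(x, dtype=float)
    z = x @ params["W1"] + params["b1"]
    return np.maximum(z, 0.0) @ params["W2"] + params["b2"]
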