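"""Assembled temporal-shift transformer with hand-rolled reverse-mode math.

The forward graph per block uses pre-normalized residual sublayers::

    H += causal depthwise conv(shift(LayerNorm(H)))
    H += self-attention(LayerNorm(H))
    H += position-wise FFN(LayerNorm(H))

preceded by a linear channel embedding plus sinusoidal positional encoding
and followed by mean-pooling over time and a softmax classifier head.
Pre-normalization keeps signal amplitude in the residual stream, which the
rectifying FFN can convert into band-power features — the quantity that
separates mental-state classes in oscillatory data.
Gradients are computed analytically (no autograd dependency) so training is
deterministic and runs anywhere numpy does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .ops import positional_encoding, softmax, temporal_shift

__all__ = ["TSTConfig", "TSTModel"]


@dataclass
class TSTConfig:
    d_model: int = 16
    n_heads: int = 2
    kernel_K: int = 8
    shift_fraction: float = 0.25
    ffn_hidden: int = 32
    n_layers: int = 1
    n_classes: int = 2
    dropout: float = 0.0
    weight_decay: float = 0.0
    lr: float = 1e-3
    max_epochs: int = 50
    batch: int = 32
    seed: int = 0
    convergence_criterion: float = 0.95

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.shift_fraction <= 0.5:
            raise ValueError("shift_fraction must be in [0, 0.5]")
        if self.kernel_K < 1:
            raise ValueError("kernel_K must be >= 1")
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even (positional encoding)")


def _layer_norm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _shift_backward(dY: np.ndarray, m: int) -> np.ndarray:
    dX = dY.copy()
    if m == 0:
        return dX
    dX[..., :m] = 0.0
    dX[..., :-1, :m] = dY[..., 1:, :m]
    dX[..., m : 2 * m] = 0.0
    dX[..., 1:, m : 2 * m] = dY[..., :-1, m : 2 * m]
    return dX


class TSTModel:
    """Parameter container plus forward/backward passes.

    Parameters live in a flat name->array dict so checkpoints are a single
    JSON document and optimizers can iterate generically.
    """

    def __init__(self, cfg: TSTConfig, n_input_channels: int):
        self.cfg = cfg
        self.n_input_channels = n_input_channels
        self.params: dict[str, np.ndarray] = {}
        self._rng = np.random.default_rng(cfg.seed)
        self._init_params()
        self._train_mode = False

    # -- initialization ------------------------------------------------------

    def _glorot(self, shape):
        fan_in, fan_out = shape[0], shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self._rng.uniform(-limit, limit, size=shape)

    def _init_params(self) -> None:
        cfg = self.cfg
        d = cfg.d_model
        p = self.params
        p["We"] = self._glorot((self.n_input_channels, d))
        p["be"] = np.zeros(d)
        for l in range(cfg.n_layers):
            pre = f"L{l}."
            p[pre + "convW"] = self._rng.normal(0.0, 1.0 / np.sqrt(cfg.kernel_K), (cfg.kernel_K, d))
            p[pre + "convb"] = np.zeros(d)
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + nm] = self._glorot((d, d))
            p[pre + "W1"] = self._glorot((d, cfg.ffn_hidden))
            p[pre + "b1"] = np.zeros(cfg.ffn_hidden)
            p[pre + "W2"] = self._glorot((cfg.ffn_hidden, d))
            p[pre + "b2"] = np.zeros(d)
            for i in (1, 2, 3):
                p[pre + f"ln{i}g"] = np.ones(d)
                p[pre + f"ln{i}b"] = np.zeros(d)
        p["Wc"] = self._glorot((d, cfg.n_classes))
        p["bc"] = np.zeros(cfg.n_classes)

    # -- forward -------------------------------------------------------------

    def _dropout(self, x, cache_list):
        rate = self.cfg.dropout
        if not self._train_mode or rate <= 0.0:
            cache_list.append(None)
            return x
        mask = (self._rng.random(x.shape) >= rate) / (1.0 - rate)
        cache_list.append(mask)
        return x * mask

    def _forward(self, X: np.ndarray):
        """X: (B, T, C) -> (probs, cache)."""
        cfg, p = self.cfg, self.params
        B, T, C = X.shape
        if C != self.n_input_channels:
            raise ValueError(f"model expects {self.n_input_channels} channels, got {C}")
        cache: dict = {"X": X, "drop": []}
        # scale the embedding up so the positional table stays a perturbation
        scale = np.sqrt(cfg.d_model)
        H = (X @ p["We"] + p["be"]) * scale
        H = H + positional_encoding(T, cfg.d_model)[None]
        m = int(cfg.shift_fraction * cfg.d_model)
        cache["m"] = m
        cache["layers"] = []
        K = cfg.kernel_K
        for l in range(cfg.n_layers):
            pre = f"L{l}."
            lc: dict = {"Hin": H}
            # shift + causal conv sublayer
            U1, lc["ln1"] = _layer_norm_forward(H, p[pre + "ln1g"], p[pre + "ln1b"])
            S = temporal_shift(U1, cfg.shift_fraction)
            Cv = np.zeros_like(S)
            W = p[pre + "convW"]
            for k in range(1, K + 1):
                Cv[:, k:, :] += S[:, :-k, :] * W[k - 1]
            Cv += p[pre + "convb"]
            lc["S"] = S
            H1 = H + self._dropout(Cv, cache["drop"])
            lc["H1"] = H1
            # self-attention sublayer
            U2, lc["ln2"] = _layer_norm_forward(H1, p[pre + "ln2g"], p[pre + "ln2b"])
            lc["U2"] = U2
            h = cfg.n_heads
            dk = cfg.d_model // h
            q = (U2 @ p[pre + "Wq"]).reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            kk = (U2 @ p[pre + "Wk"]).reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            v = (U2 @ p[pre + "Wv"]).reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            scores = q @ kk.transpose(0, 1, 3, 2) / np.sqrt(dk)
            attn = softmax(scores, axis=-1)
            O = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            A = O @ p[pre + "Wo"]
            lc.update(q=q, k=kk, v=v, attn=attn, O=O)
            H2 = H1 + self._dropout(A, cache["drop"])
            lc["H2"] = H2
            # FFN sublayer
            U3, lc["ln3"] = _layer_norm_forward(H2, p[pre + "ln3g"], p[pre + "ln3b"])
            lc["U3"] = U3
            Z = U3 @ p[pre + "W1"] + p[pre + "b1"]
            R = np.maximum(Z, 0.0)
            F = R @ p[pre + "W2"] + p[pre + "b2"]
            lc["Z"] = Z
            lc["R"] = R
            H = H2 + self._dropout(F, cache["drop"])
            cache["layers"].append(lc)
        pooled = H.mean(axis=1)
        logits = pooled @ p["Wc"] + p["bc"]
        probs = softmax(logits, axis=-1)
        cache["pooled"] = pooled
        cache["T"] = T
        return probs, cache

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class probabilities for segments ``X`` of shape (n, C, T)."""
        self._train_mode = False
        X = np.asarray(X, dtype=float)
        Xt = np.transpose(X, (0, 2, 1))
        out = [self._forward(Xt[i : i + batch])[0] for i in range(0, len(Xt), batch)]
        return np.concatenate(out, axis=0)

    # -- backward ------------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and parameter gradients for a batch.

        ``X`` is (B, T, C); ``y`` integer class ids.
        """
        cfg, p = self.cfg, self.params
        probs, cache = self._forward(X)
        B = len(y)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(B), y] + eps))
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["Wc"] = cache["pooled"].T @ dlogits
        grads["bc"] = dlogits.sum(axis=0)
        dH = (dlogits @ p["Wc"].T)[:, None, :] / cache["T"] * np.ones((1, cache["T"], 1))

        drop_caches = cache["drop"]
        di = len(drop_caches)

        def undrop(dx):
            nonlocal di
            di -= 1
            mask = drop_caches[di]
            return dx if mask is None else dx * mask

        K = cfg.kernel_K
        m = cache["m"]
        for l in reversed(range(cfg.n_layers)):
            pre = f"L{l}."
            lc = cache["layers"][l]
            # FFN sublayer: H = H2 + drop(FFN(LN3(H2)))
            dF = undrop(dH)
            Bt = dF.shape[0] * dF.shape[1]
            R2d = lc["R"].reshape(Bt, -1)
            dF2d = dF.reshape(Bt, -1)
            grads[pre + "W2"] = R2d.T @ dF2d
            grads[pre + "b2"] = dF2d.sum(axis=0)
            dR = dF @ p[pre + "W2"].T
            dZ = dR * (lc["Z"] > 0)
            U32d = lc["U3"].reshape(Bt, -1)
            dZ2d = dZ.reshape(Bt, -1)
            grads[pre + "W1"] = U32d.T @ dZ2d
            grads[pre + "b1"] = dZ2d.sum(axis=0)
            dU3 = dZ @ p[pre + "W1"].T
            dln, dg, db = _layer_norm_backward(dU3, lc["ln3"])
            grads[pre + "ln3g"] = dg
            grads[pre + "ln3b"] = db
            dH2 = dH + dln
            # attention sublayer: H2 = H1 + drop(MHA(LN2(H1)))
            dA = undrop(dH2)
            Bs, T, d = dA.shape
            h = cfg.n_heads
            dk = d // h
            O2d = lc["O"].reshape(Bs * T, d)
            dA2d = dA.reshape(Bs * T, d)
            grads[pre + "Wo"] = O2d.T @ dA2d
            dO = (dA @ p[pre + "Wo"].T).reshape(Bs, T, h, dk).transpose(0, 2, 1, 3)
            attn, q, kk, v = lc["attn"], lc["q"], lc["k"], lc["v"]
            dattn = dO @ v.transpose(0, 1, 3, 2)
            dv = attn.transpose(0, 1, 3, 2) @ dO
            ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            ds /= np.sqrt(dk)
            dq = ds @ kk
            dkk = ds.transpose(0, 1, 3, 2) @ q
            dQp = dq.transpose(0, 2, 1, 3).reshape(Bs * T, d)
            dKp = dkk.transpose(0, 2, 1, 3).reshape(Bs * T, d)
            dVp = dv.transpose(0, 2, 1, 3).reshape(Bs * T, d)
            U22d = lc["U2"].reshape(Bs * T, d)
            grads[pre + "Wq"] = U22d.T @ dQp
            grads[pre + "Wk"] = U22d.T @ dKp
            grads[pre + "Wv"] = U22d.T @ dVp
            dU2 = (
                dQp @ p[pre + "Wq"].T + dKp @ p[pre + "Wk"].T + dVp @ p[pre + "Wv"].T
            ).reshape(Bs, T, d)
            dln, dg, db = _layer_norm_backward(dU2, lc["ln2"])
            grads[pre + "ln2g"] = dg
            grads[pre + "ln2b"] = db
            dH1 = dH2 + dln
            # shift + conv sublayer: H1 = H + drop(conv(shift(LN1(H))))
            dCv = undrop(dH1)
            grads[pre + "convb"] = dCv.sum(axis=(0, 1))
            S = lc["S"]
            W = p[pre + "convW"]
            dS = np.zeros_like(S)
            dW = np.zeros_like(W)
            for k in range(1, K + 1):
                dW[k - 1] = (S[:, :-k, :] * dCv[:, k:, :]).sum(axis=(0, 1))
                dS[:, :-k, :] += dCv[:, k:, :] * W[k - 1]
            grads[pre + "convW"] = dW
            dU1 = _shift_backward(dS, m)
            dln, dg, db = _layer_norm_backward(dU1, lc["ln1"])
            grads[pre + "ln1g"] = dg
            grads[pre + "ln1b"] = db
            dH = dH1 + dln
        # embedding
        dH0 = dH * np.sqrt(cfg.d_model)
        X2d = cache["X"].reshape(-1, self.n_input_channels)
        grads["We"] = X2d.T @ dH0.reshape(-1, cfg.d_model)
        grads["be"] = dH0.sum(axis=(0, 1))
        return loss, grads

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "config": asdict(self.cfg),
            "n_input_channels": self.n_input_channels,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TSTModel":
        doc = json.loads(Path(path).read_text())
        model = cls(TSTConfig(**doc["config"]), doc["n_input_channels"])
        for k, v in doc["params"].items():
            model.params[k] = np.asarray(v, dtype=float)
        return model
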