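"""Reverse-mode gradients for the classifier, derived and coded by hand.

The network is small enough (about 12k scalars) that explicit backward
passes in numpy are both simple and fast; each layer's forward stores the
intermediates its backward needs. Gradients are returned as a dict with the
same keys and shapes as the weights. Correctness is pinned down in the test
suite by central finite differences over every tensor and by an analytic
summed-gradient oracle for accumulation.

All math uses float64. The loss gradient is taken with respect to the head
logit (pre-sigmoid), which keeps the weighted cross-entropy numerically
stable for extreme probabilities.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .model import ModelConfig, Weights, _head_logit


# ---------------------------------------------------------------------------
# Layer primitives: forward with cache / backward
# ---------------------------------------------------------------------------

def _ln_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv)


def _ln_backward(dy: np.ndarray, cache, gamma: np.ndarray):
    """Backward of layer norm with biased variance, per row."""
    xhat, inv = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def _conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    # im2col: one (L, C_in*k) x (C_in*k, C_out) product instead of k shifts
    L, c_in = x.shape
    c_out, _, k = weight.shape
    pad_l = (k - 1) // 2
    xp = np.zeros((L + k - 1, c_in))
    xp[pad_l : pad_l + L] = x
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=0)  # (L, C_in, k)
    cols = win.reshape(L, c_in * k)
    y = cols @ weight.reshape(c_out, c_in * k).T + bias
    return y, cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, weight: np.ndarray):
    L = dy.shape[0]
    c_out, c_in, k = weight.shape
    pad_l = (k - 1) // 2
    dw = (dy.T @ cols).reshape(c_out, c_in, k)
    db = dy.sum(axis=0)
    dcols = (dy @ weight.reshape(c_out, c_in * k)).reshape(L, c_in, k)
    dxp = np.zeros((L + k - 1, c_in))
    for j in range(k):
        dxp[j : j + L] += dcols[:, :, j]
    return dw, db, dxp[pad_l : pad_l + L]


def _block_forward(x, W: Mapping[str, np.ndarray], b: int, cfg: ModelConfig):
    y, xp = _conv_forward(x, W[f"conv{b}.weight"], W[f"conv{b}.bias"])
    z, ln_cache = _ln_forward(
        y, W[f"conv{b}.ln_gamma"], W[f"conv{b}.ln_beta"], cfg.layer_norm_eps
    )
    r = np.maximum(z, 0.0)
    pk = cfg.pool_kernel
    n_out = r.shape[0] // pk
    out = r[: n_out * pk].reshape(n_out, pk, -1).mean(axis=1)
    return out, (xp, ln_cache, z, r.shape[0], n_out)


def _block_backward(dout, cache, W: Mapping[str, np.ndarray], b: int, cfg: ModelConfig):
    xp, ln_cache, z, L, n_out = cache
    pk = cfg.pool_kernel
    dr = np.zeros((L, dout.shape[1]))
    # each pooled row spreads its gradient equally; the floor-dropped tail gets none
    dr[: n_out * pk] = np.repeat(dout / pk, pk, axis=0)
    dz = dr * (z > 0)
    dy, dgamma, dbeta = _ln_backward(dz, ln_cache, W[f"conv{b}.ln_gamma"])
    dw, db, dx = _conv_backward(dy, xp, W[f"conv{b}.weight"])
    grads = {
        f"conv{b}.weight": dw,
        f"conv{b}.bias": db,
        f"conv{b}.ln_gamma": dgamma,
        f"conv{b}.ln_beta": dbeta,
    }
    return dx, grads


def _encoder_forward(Z, W: Mapping[str, np.ndarray], cfg: ModelConfig):
    h, dk = cfg.n_heads, cfg.d_head
    l = Z.shape[0]
    # heads batched through stacked matmul: (h, l, dk)
    Zb = Z[None]
    Q, K, V = Zb @ W["attn.wq"], Zb @ W["attn.wk"], Zb @ W["attn.wv"]
    S = Q @ K.transpose(0, 2, 1) / np.sqrt(dk)
    S -= S.max(axis=2, keepdims=True)
    A = np.exp(S)
    A /= A.sum(axis=2, keepdims=True)
    attn_cache = (Q, K, V, A)
    H = (A @ V).transpose(1, 0, 2).reshape(l, h * dk)
    M0 = H @ W["attn.wo"]
    R1 = Z + M0
    mid, ln1_cache = _ln_forward(
        R1, W["enc.ln1_gamma"], W["enc.ln1_beta"], cfg.layer_norm_eps
    )
    U = mid @ W["ffn.w1"] + W["ffn.b1"]
    Ur = np.maximum(U, 0.0)
    F = Ur @ W["ffn.w2"] + W["ffn.b2"]
    out, ln2_cache = _ln_forward(
        mid + F, W["enc.ln2_gamma"], W["enc.ln2_beta"], cfg.layer_norm_eps
    )
    return out, (Z, attn_cache, H, ln1_cache, mid, U, Ur, ln2_cache)


def _encoder_backward(dout, cache, W: Mapping[str, np.ndarray], cfg: ModelConfig):
    Z, attn_cache, H, ln1_cache, mid, U, Ur, ln2_cache = cache
    h, dk = cfg.n_heads, cfg.d_head
    grads: Weights = {}

    dR2, grads["enc.ln2_gamma"], grads["enc.ln2_beta"] = _ln_backward(
        dout, ln2_cache, W["enc.ln2_gamma"]
    )
    dmid = dR2.copy()
    dF = dR2
    grads["ffn.w2"] = Ur.T @ dF
    grads["ffn.b2"] = dF.sum(axis=0)
    dU = (dF @ W["ffn.w2"].T) * (U > 0)
    grads["ffn.w1"] = mid.T @ dU
    grads["ffn.b1"] = dU.sum(axis=0)
    dmid += dU @ W["ffn.w1"].T

    dR1, grads["enc.ln1_gamma"], grads["enc.ln1_beta"] = _ln_backward(
        dmid, ln1_cache, W["enc.ln1_gamma"]
    )
    dZ = dR1.copy()
    dM0 = dR1
    grads["attn.wo"] = H.T @ dM0
    dH = dM0 @ W["attn.wo"].T

    Q, K, V, A = attn_cache
    l = Z.shape[0]
    dHh = dH.reshape(l, h, dk).transpose(1, 0, 2)  # (h, l, dk)
    dA = dHh @ V.transpose(0, 2, 1)
    dV = A.transpose(0, 2, 1) @ dHh
    dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))  # softmax rows per head
    dQ = dS @ K / np.sqrt(dk)
    dK = dS.transpose(0, 2, 1) @ Q / np.sqrt(dk)
    Zt = Z.T[None]
    grads["attn.wq"] = Zt @ dQ
    grads["attn.wk"] = Zt @ dK
    grads["attn.wv"] = Zt @ dV
    dZ += (
        dQ @ W["attn.wq"].transpose(0, 2, 1)
        + dK @ W["attn.wk"].transpose(0, 2, 1)
        + dV @ W["attn.wv"].transpose(0, 2, 1)
    ).sum(axis=0)
    return dZ, grads


# ---------------------------------------------------------------------------
# Whole-model forward/backward
# ---------------------------------------------------------------------------

def forward_logit(
    x: np.ndarray,
    weights: Mapping[str, np.ndarray],
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Run the model up to the pre-sigmoid logit, caching intermediates.

    Returns ``(logit, cache)``; pass the cache to :func:`backward_from_logit`.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < config.min_length:
        raise ValueError(
            f"profile length {x.shape[0]} is below the minimum {config.min_length}"
        )
    block_caches = []
    for b in range(config.conv_blocks):
        x, c = _block_forward(x, weights, b, config)
        block_caches.append(c)
    enc_cache = None
    if config.use_transformer:
        x, enc_cache = _encoder_forward(x, weights, config)
    L_pooled = x.shape[0]
    v = x.mean(axis=0)
    head_cache: dict = {}
    z = _head_logit(v, weights, config, training, rng, cache=head_cache)
    return z, (block_caches, enc_cache, L_pooled, head_cache)


def backward_from_logit(
    dz: float,
    cache,
    weights: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> Weights:
    """Backpropagate d(loss)/d(logit) through the whole network."""
    block_caches, enc_cache, L_pooled, head_cache = cache
    grads: Weights = {}

    v = head_cache["head_v"]
    if config.fc_hidden > 0:
        hdrop, mask, a = (
            head_cache["head_hdrop"],
            head_cache["head_mask"],
            head_cache["head_a"],
        )
        grads["fc2.weight"] = (hdrop * dz)[:, None]
        grads["fc2.bias"] = np.array([dz])
        dh = weights["fc2.weight"][:, 0] * dz
        da = dh * mask * (a > 0)
        grads["fc1.weight"] = np.outer(v, da)
        grads["fc1.bias"] = da
        dv = weights["fc1.weight"] @ da
    else:
        grads["fc2.weight"] = (v * dz)[:, None]
        grads["fc2.bias"] = np.array([dz])
        dv = weights["fc2.weight"][:, 0] * dz

    dx = np.tile(dv / L_pooled, (L_pooled, 1))  # global average pool
    if config.use_transformer:
        dx, enc_grads = _encoder_backward(dx, enc_cache, weights, config)
        grads.update(enc_grads)
    for b in reversed(range(config.conv_blocks)):
        dx, block_grads = _block_backward(dx, block_caches[b], weights, b, config)
        grads.update(block_grads)
    return grads


def sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


def loss_and_grads(
    x: np.ndarray,
    y: int,
    weights: Mapping[str, np.ndarray],
    config: ModelConfig,
    class_weights: tuple[float, float],
    training: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, Weights, float]:
    """Weighted BCE loss, its gradients, and the predicted probability.

    The loss is L = -[w_pos*y*log p + w_neg*(1-y)*log(1-p)] with p the
    sigmoid of the logit z; both the loss and dL/dz are evaluated from z
    directly (log1p/exp form), so saturated probabilities cannot produce
    infinities.
    """
    w_pos, w_neg = class_weights
    z, cache = forward_logit(x, weights, config, training, rng)
    p = sigmoid(z)
    # log p = -softplus(-z); log(1-p) = -softplus(z)
    loss = w_pos * y * np.logaddexp(0.0, -z) + w_neg * (1 - y) * np.logaddexp(0.0, z)
    dz = -w_pos * y * (1.0 - p) + w_neg * (1 - y) * p
    grads = backward_from_logit(dz, cache, weights, config)
    return float(loss), grads, p
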