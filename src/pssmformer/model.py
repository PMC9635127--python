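"""Forward computation of the lightweight PSSM transformer classifier.

The network maps one variable-length N x 20 PSSM profile (batch size 1 by
construction) to an adaptor-protein probability:

    three conv blocks (1D conv -> layer norm -> ReLU -> avg-pool /2)
    -> one post-norm transformer encoder layer (d=20, h=5, d_ff=128)
    -> global average pooling over positions
    -> FC(20 -> 64) -> ReLU -> dropout(0.5) -> FC(64 -> 1) -> sigmoid

Everything is plain numpy, float64. Weights live in an ordered dict keyed by
the names produced by :func:`weight_shapes`; the trainable-parameter count is
a pure function of :class:`ModelConfig`. Model sizes are reported in the
truncated "12.1k" convention.

There is no positional encoding, so the encoder is permutation-equivariant;
the model's notion of order comes entirely from the convolutional front end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .profiles import PSSMProfile

Weights = dict[str, np.ndarray]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults reproduce the 12.1k model."""

    in_channels: int = 20
    conv_blocks: int = 3
    conv_channels: int = 20
    conv_kernel: int = 3
    pool_kernel: int = 2
    d_model: int = 20
    n_heads: int = 5
    d_ff: int = 128
    fc_hidden: int = 64  # 0 collapses the head to a single affine map
    dropout: float = 0.5
    use_transformer: bool = True
    layer_norm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        for name in ("in_channels", "conv_channels", "conv_kernel", "pool_kernel",
                     "d_model", "n_heads", "d_ff"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.conv_blocks < 0 or self.fc_hidden < 0:
            raise ValueError("conv_blocks and fc_hidden must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        feat = self.conv_channels if self.conv_blocks > 0 else self.in_channels
        if feat != self.d_model:
            raise ValueError(
                f"features entering the encoder have width {feat}, "
                f"but d_model is {self.d_model}"
            )

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    @property
    def min_length(self) -> int:
        """Shortest profile the conv/pool stack can reduce without vanishing."""
        return self.pool_kernel**self.conv_blocks


def weight_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Every trainable tensor's shape, in the fixed enumeration order.

    Convention (chosen to reproduce all published model sizes): Q/K/V and
    output projections are bias-free; conv, FFN and FC layers carry biases;
    every layer norm has per-element gain and bias.
    """
    shapes: dict[str, tuple[int, ...]] = {}
    c_in = config.in_channels
    for b in range(config.conv_blocks):
        shapes[f"conv{b}.weight"] = (config.conv_channels, c_in, config.conv_kernel)
        shapes[f"conv{b}.bias"] = (config.conv_channels,)
        shapes[f"conv{b}.ln_gamma"] = (config.conv_channels,)
        shapes[f"conv{b}.ln_beta"] = (config.conv_channels,)
        c_in = config.conv_channels
    if config.use_transformer:
        d, h, dk = config.d_model, config.n_heads, config.d_head
        shapes["attn.wq"] = (h, d, dk)
        shapes["attn.wk"] = (h, d, dk)
        shapes["attn.wv"] = (h, d, dk)
        shapes["attn.wo"] = (d, d)
        shapes["enc.ln1_gamma"] = (d,)
        shapes["enc.ln1_beta"] = (d,)
        shapes["ffn.w1"] = (d, config.d_ff)
        shapes["ffn.b1"] = (config.d_ff,)
        shapes["ffn.w2"] = (config.d_ff, d)
        shapes["ffn.b2"] = (d,)
        shapes["enc.ln2_gamma"] = (d,)
        shapes["enc.ln2_beta"] = (d,)
    if config.fc_hidden > 0:
        shapes["fc1.weight"] = (config.d_model, config.fc_hidden)
        shapes["fc1.bias"] = (config.fc_hidden,)
        shapes["fc2.weight"] = (config.fc_hidden, 1)
    else:
        shapes["fc2.weight"] = (config.d_model, 1)
    shapes["fc2.bias"] = (1,)
    return shapes


def count_parameters(config: ModelConfig) -> int:
    """Number of trainable scalars implied by the config."""
    return sum(int(np.prod(s)) for s in weight_shapes(config).values())


def format_param_count(n: int) -> str:
    """Report a parameter count in thousands, truncated to one decimal.

    Truncation (not rounding) is the convention used for published sizes,
    e.g. 15,089 -> "15.0k" and 12,137 -> "12.1k".
    """
    return f"{int(n / 100) / 10:.1f}k"


def init_weights(config: ModelConfig, rng: np.random.Generator) -> Weights:
    """Kaiming-uniform fan-in initialisation (PyTorch's default scheme).

    Conv/linear weights ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in)), likewise their
    biases; layer-norm gains start at 1, biases at 0. Draw order follows the
    fixed key order of :func:`weight_shapes`, so a given seed yields the same
    tensors on every platform.
    """
    shapes = weight_shapes(config)
    weights: Weights = {}
    for name, shape in shapes.items():
        if name.endswith(("ln_gamma", "ln1_gamma", "ln2_gamma")):
            weights[name] = np.ones(shape)
        elif name.endswith(("ln_beta", "ln1_beta", "ln2_beta")):
            weights[name] = np.zeros(shape)
        else:
            bound = 1.0 / np.sqrt(_fan_in(name, shape, shapes))
            weights[name] = rng.uniform(-bound, bound, size=shape)
    return weights


def _fan_in(
    name: str, shape: tuple[int, ...], shapes: Mapping[str, tuple[int, ...]]
) -> int:
    if name.endswith(".bias"):  # bias bound follows the paired weight's fan-in
        w = shapes[name.replace(".bias", ".weight")]
        return w[1] * w[2] if len(w) == 3 else w[0]
    if name.startswith("conv"):
        return shape[1] * shape[2]
    if name == "ffn.b1":
        return shapes["ffn.w1"][0]
    if name == "ffn.b2":
        return shapes["ffn.w2"][0]
    return shape[-2]


# ---------------------------------------------------------------------------
# Forward operations
# ---------------------------------------------------------------------------

def layer_norm(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5
) -> np.ndarray:
    """Normalise each position's channel vector to zero mean / unit variance.

    Uses the population (biased) variance over the channel axis, then applies
    the learned per-element affine: y = (x - E[x]) / sqrt(Var[x] + eps) * g + b.
    Accepts a single channel vector or an (L, C) feature map.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)  # biased
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def conv1d_same(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """1-D convolution along the position axis, stride 1, zero same-padding.

    x: (L, C_in); weight: (C_out, C_in, k); returns (L, C_out). Implemented
    as k shifted matrix products, which is exact and fast for small k.
    """
    L = x.shape[0]
    k = weight.shape[2]
    pad_l = (k - 1) // 2
    pad_r = k - 1 - pad_l
    xp = np.pad(x, ((pad_l, pad_r), (0, 0)))
    out = np.zeros((L, weight.shape[0]))
    for j in range(k):
        out += xp[j : j + L] @ weight[:, :, j].T
    return out + bias


def conv_block_forward(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    pool_kernel: int = 2,
    eps: float = 1e-5,
) -> np.ndarray:
    """One conv block: conv -> layer norm -> ReLU -> average pool.

    Pooling is non-overlapping (stride = kernel) with floor length division;
    an input shorter than the pool kernel is an error.
    """
    L = x.shape[0]
    if L < pool_kernel:
        raise ValueError(f"feature map length {L} shorter than pool kernel {pool_kernel}")
    y = conv1d_same(x, weight, bias)
    y = layer_norm(y, gamma, beta, eps)
    y = np.maximum(y, 0.0)
    n_out = L // pool_kernel
    return y[: n_out * pool_kernel].reshape(n_out, pool_kernel, -1).mean(axis=1)


def scaled_dot_product_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V with the per-head width as the scale."""
    d_k = Q.shape[1]
    scores = Q @ K.T / np.sqrt(d_k)
    scores -= scores.max(axis=1, keepdims=True)  # stable softmax
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ V


def multi_head_attention(Z: np.ndarray, weights: Mapping[str, np.ndarray]) -> np.ndarray:
    """h parallel attention heads on learned projections, concatenated.

    Per head i: Q_i = Z W_i^Q, K_i = Z W_i^K, V_i = Z W_i^V (no biases);
    the concatenated heads are reprojected by W^O (no bias).
    """
    wq, wk, wv = weights["attn.wq"], weights["attn.wk"], weights["attn.wv"]
    heads = [
        scaled_dot_product_attention(Z @ wq[i], Z @ wk[i], Z @ wv[i])
        for i in range(wq.shape[0])
    ]
    return np.concatenate(heads, axis=1) @ weights["attn.wo"]


def transformer_encoder(
    Z: np.ndarray, weights: Mapping[str, np.ndarray], eps: float = 1e-5
) -> np.ndarray:
    """One post-norm encoder layer: LN(Z + MHA), then LN(Mid + FFN)."""
    mid = layer_norm(
        Z + multi_head_attention(Z, weights),
        weights["enc.ln1_gamma"], weights["enc.ln1_beta"], eps,
    )
    ffn = np.maximum(mid @ weights["ffn.w1"] + weights["ffn.b1"], 0.0) @ weights[
        "ffn.w2"
    ] + weights["ffn.b2"]
    return layer_norm(mid + ffn, weights["enc.ln2_gamma"], weights["enc.ln2_beta"], eps)


def global_average_pool(features: np.ndarray) -> np.ndarray:
    """Column-wise mean: any (L, d) map becomes one d-vector."""
    return np.asarray(features, dtype=float).mean(axis=0)


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


def classifier_head(
    v: np.ndarray,
    weights: Mapping[str, np.ndarray],
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """FC -> ReLU -> dropout -> FC -> sigmoid. Dropout only when training.

    Inverted dropout: kept units are scaled by 1/(1-rate) at train time so
    evaluation applies the weights unchanged.
    """
    z = _head_logit(v, weights, config, training, rng)
    return float(_sigmoid(z))


def _head_logit(v, weights, config, training=False, rng=None, cache=None):
    if config.fc_hidden > 0:
        a = v @ weights["fc1.weight"] + weights["fc1.bias"]
        r = np.maximum(a, 0.0)
        if training and config.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            mask = (rng.random(r.shape) >= config.dropout) / (1.0 - config.dropout)
        else:
            mask = np.ones_like(r)
        hdrop = r * mask
        z = float((hdrop @ weights["fc2.weight"])[0] + weights["fc2.bias"][0])
        if cache is not None:
            cache.update(head_a=a, head_mask=mask, head_hdrop=hdrop, head_v=v)
    else:
        z = float((v @ weights["fc2.weight"])[0] + weights["fc2.bias"][0])
        if cache is not None:
            cache.update(head_v=v)
    return z


def model_forward(
    profile: PSSMProfile | np.ndarray,
    config: ModelConfig,
    weights: Mapping[str, np.ndarray],
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Full forward pass: one profile in, one adaptor probability out."""
    x = profile.scores if isinstance(profile, PSSMProfile) else np.asarray(profile, float)
    if x.shape[0] < config.min_length:
        raise ValueError(
            f"profile length {x.shape[0]} is below the minimum {config.min_length} "
            f"required by {config.conv_blocks} pooling stages of kernel "
            f"{config.pool_kernel}"
        )
    for b in range(config.conv_blocks):
        x = conv_block_forward(
            x,
            weights[f"conv{b}.weight"],
            weights[f"conv{b}.bias"],
            weights[f"conv{b}.ln_gamma"],
            weights[f"conv{b}.ln_beta"],
            config.pool_kernel,
            config.layer_norm_eps,
        )
    if config.use_transformer:
        x = transformer_encoder(x, weights, config.layer_norm_eps)
    v = global_average_pool(x)
    return classifier_head(v, weights, config, training, rng)
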