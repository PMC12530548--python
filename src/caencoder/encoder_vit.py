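"""The encoder E: x → z.

A stack of transformer blocks — multi-head self-attention, Switch
Normalization (a trainable α·BN + β·LN blend) and a small MLP, with residual
additions — followed by mean-pooling over tokens and a three-layer reduction
head down to the latent space.  No CLS token is used: the goal is a reduced
latent vector, not a classification token.

Tokenisation of a concatenated omics vector is not canonical; two schemes are
supported.  ``per_modality`` (default) projects each modality to the embedding
dimension, giving one token per modality, so self-attention acts across
modalities.  ``chunked`` slices the concatenated vector into a fixed number of
equal-width chunks and projects each.

Parameters are nested dicts of numpy arrays; every forward function is pure so
the whole encoder is differentiable with autograd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.tracer import isbox as isbox_input

from ._nn import (as_float_array, gaussian_init, leaky_relu, linear,
                  linear_params, softmax)


@dataclass
class EncoderConfig:
    n_blocks: int = 8
    n_heads: int = 8
    embed_dim: int = 1024
    latent_dim: int = 256
    head_dims: tuple[int, ...] | None = None   # output dims of the 3 head layers
    leaky_slope: float = 0.2
    token_scheme: str = "per_modality"         # or "chunked"
    n_tokens: int = 8                          # chunked scheme only
    mlp_ratio: int = 2
    bn_momentum: float = 0.1
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.head_dims is None:
            mid = int(round(math.sqrt(self.embed_dim * self.latent_dim)))
            self.head_dims = (self.embed_dim, mid, self.latent_dim)
        self.head_dims = tuple(self.head_dims)
        if self.head_dims[-1] != self.latent_dim:
            raise ValueError("last head dim must equal latent_dim")
        if any(a <= b for a, b in zip(self.head_dims, self.head_dims[1:])):
            raise ValueError("head_dims must be strictly decreasing")
        if self.token_scheme not in ("per_modality", "chunked"):
            raise ValueError(f"unknown token scheme {self.token_scheme!r}")


@dataclass
class SwitchNormState:
    """Trainable BN/LN mixing coefficients plus BN running statistics."""

    alpha: float = 0.5
    beta: float = 0.5
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None
    epsilon: float = 1e-5


@dataclass
class EncoderState:
    """Config + parameters + BN running statistics for a fitted input layout."""

    config: EncoderConfig
    modality_dims: list[int]
    params: dict
    bn_state: list[dict] = field(default_factory=list)

    @property
    def n_x(self) -> int:
        return int(sum(self.modality_dims))


# ---------------------------------------------------------------------------
# construction


def _token_layout(config: EncoderConfig, modality_dims: list[int]) -> list[int]:
    """Input width of each token's projection."""
    if config.token_scheme == "per_modality":
        return list(modality_dims)
    n_x = sum(modality_dims)
    width = -(-n_x // config.n_tokens)  # ceil
    return [width] * config.n_tokens


def init_encoder(config: EncoderConfig, modality_dims: list[int],
                 rng: np.random.Generator) -> EncoderState:
    D = config.embed_dim
    params: dict = {
        "in_proj": [linear_params(rng, w, D) for w in _token_layout(config, modality_dims)],
        "blocks": [],
        "head": [],
    }
    hidden = D * config.mlp_ratio
    bn_state: list[dict] = []
    for _ in range(config.n_blocks):
        params["blocks"].append({
            "attn": {
                "Wq": gaussian_init(rng, (D, D)),
                "Wk": gaussian_init(rng, (D, D)),
                "Wv": gaussian_init(rng, (D, D)),
                "Wo": gaussian_init(rng, (D, D)),
                "bo": np.zeros(D),
            },
            "sn1": {"alpha": np.array(0.5), "beta": np.array(0.5)},
            "mlp": {"W0": gaussian_init(rng, (D, hidden)),
                    "W1": gaussian_init(rng, (hidden, D)),
                    "b0": np.zeros(hidden), "b1": np.zeros(D)},
            "sn2": {"alpha": np.array(0.5), "beta": np.array(0.5)},
        })
        bn_state.append({
            "sn1": {"mean": np.zeros(D), "var": np.ones(D)},
            "sn2": {"mean": np.zeros(D), "var": np.ones(D)},
        })
    dims = (D,) + config.head_dims
    params["head"] = [linear_params(rng, dims[i], dims[i + 1]) for i in range(3)]
    return EncoderState(config=config, modality_dims=list(modality_dims),
                        params=params, bn_state=bn_state)


# ---------------------------------------------------------------------------
# primitive operations (exposed for testing and reuse)


def attention_head(X, W_Q, W_K, W_V):
    """One self-attention head on a (T × d) token matrix.

    Returns (O_i, alpha): alpha[j, k] = softmax_k(Q_j·K_k / √d_k), each row a
    probability vector; O_i = alpha @ V.
    """
    X = as_float_array(X)
    if not isbox_input(X) and not np.all(np.isfinite(np.asarray(X))):
        raise FloatingPointError("non-finite attention input")
    Q = anp.dot(X, W_Q)
    K = anp.dot(X, W_K)
    V = anp.dot(X, W_V)
    d_k = Q.shape[-1]
    alpha = softmax(anp.dot(Q, K.T) / anp.sqrt(float(d_k)), axis=-1)
    return anp.dot(alpha, V), alpha


def switch_norm(x, state: SwitchNormState, training: bool = True):
    """SN(x) = α·BN(x) + β·LN(x) on a (B × D) or (B × T × D) batch.

    Training mode normalises with batch statistics; inference uses the stored
    running statistics.  A batch with a single normalisation sample falls back
    to running statistics to avoid a zero-variance degeneracy.
    """
    x = as_float_array(x)
    axes = tuple(range(x.ndim - 1))
    count = int(np.prod(x.shape[:-1]))
    use_batch = training and count > 1
    if use_batch:
        mean = anp.mean(x, axis=axes)
        var = anp.var(x, axis=axes)
    else:
        if state.running_mean is None:
            raise ValueError("inference-mode switch_norm requires running statistics")
        mean, var = state.running_mean, state.running_var
    bn = (x - mean) / anp.sqrt(var + state.epsilon)
    ln_mean = anp.mean(x, axis=-1, keepdims=True)
    ln_var = anp.var(x, axis=-1, keepdims=True)
    ln = (x - ln_mean) / anp.sqrt(ln_var + state.epsilon)
    return state.alpha * bn + state.beta * ln


def reduction_head(O, head_params, slope: float = 0.2):
    """Three affine layers; Leaky ReLU after the first two, final layer linear."""
    h = leaky_relu(linear(O, head_params[0]["W"], head_params[0]["b"]), slope)
    h = leaky_relu(linear(h, head_params[1]["W"], head_params[1]["b"]), slope)
    return linear(h, head_params[2]["W"], head_params[2]["b"])


# ---------------------------------------------------------------------------
# full forward pass


def _split_tokens(X, config: EncoderConfig, modality_dims: list[int]) -> list:
    n_x = int(sum(modality_dims))
    if X.shape[-1] != n_x:
        raise ValueError(
            f"input length {X.shape[-1]} does not match fitted modality dims "
            f"{list(modality_dims)} (total {n_x})"
        )
    if config.token_scheme == "per_modality":
        bounds = np.cumsum([0] + list(modality_dims))
        return [X[:, bounds[m]:bounds[m + 1]] for m in range(len(modality_dims))]
    width = -(-n_x // config.n_tokens)
    pad = width * config.n_tokens - n_x
    if pad:
        X = anp.concatenate([X, anp.zeros((X.shape[0], pad))], axis=1)
    return [X[:, t * width:(t + 1) * width] for t in range(config.n_tokens)]


def mha_attention_weights(attn: dict, X, n_heads: int) -> np.ndarray:
    """Per-head attention weight tensor (B, heads, T, T) for a token batch.

    Exposes the softmax rows of multi-head self-attention so their
    probability-vector invariant can be inspected directly.
    """
    X = as_float_array(X)
    B, T, D = X.shape
    d_k = D // n_heads
    Q = anp.dot(X, attn["Wq"]).reshape((B, T, n_heads, d_k))
    K = anp.dot(X, attn["Wk"]).reshape((B, T, n_heads, d_k))
    scores = anp.einsum("bihd,bjhd->bhij", Q, K) / anp.sqrt(float(d_k))
    return np.asarray(softmax(scores, axis=-1))


def _mha(attn, X, n_heads: int):
    """Multi-head attention on (B, T, D); returns the projected concat of heads."""
    B, T, D = X.shape
    d_k = D // n_heads
    Q = anp.dot(X, attn["Wq"]).reshape((B, T, n_heads, d_k))
    K = anp.dot(X, attn["Wk"]).reshape((B, T, n_heads, d_k))
    V = anp.dot(X, attn["Wv"]).reshape((B, T, n_heads, d_k))
    scores = anp.einsum("bihd,bjhd->bhij", Q, K) / anp.sqrt(float(d_k))
    alpha = softmax(scores, axis=-1)
    out = anp.einsum("bhij,bjhd->bihd", alpha, V).reshape((B, T, D))
    return anp.dot(out, attn["Wo"]) + attn["bo"]


def _cval(v):
    """Concrete ndarray view of a possibly autograd-boxed array."""
    while hasattr(v, "_value"):
        v = v._value
    return np.asarray(v)


def _sn(x, sn_params, running, eps: float, training: bool, collect: list | None):
    count = int(np.prod(x.shape[:-1]))
    use_batch = training and count > 1
    if use_batch:
        mean = anp.mean(x, axis=tuple(range(x.ndim - 1)))
        var = anp.var(x, axis=tuple(range(x.ndim - 1)))
        if collect is not None:
            collect.append((_cval(mean), _cval(var)))
    else:
        mean, var = running["mean"], running["var"]
        if collect is not None:
            collect.append((running["mean"], running["var"]))
    bn = (x - mean) / anp.sqrt(var + eps)
    ln = (x - anp.mean(x, axis=-1, keepdims=True)) / anp.sqrt(
        anp.var(x, axis=-1, keepdims=True) + eps)
    return sn_params["alpha"] * bn + sn_params["beta"] * ln


def encoder_forward(params: dict, X, config: EncoderConfig, modality_dims: list[int],
                    bn_state: list[dict], training: bool,
                    collect: list | None = None):
    """Map a (B × n_x) batch to (B × n_z) latents.

    ``collect``, when given, receives the per-SN-layer batch statistics so the
    caller can update running BN state after an optimisation step.
    """
    X = as_float_array(X)
    parts = _split_tokens(X, config, modality_dims)
    tokens = anp.stack(
        [linear(p, proj["W"], proj["b"]) for p, proj in zip(parts, params["in_proj"])],
        axis=1)  # (B, T, D)
    h = tokens
    for blk, running in zip(params["blocks"], bn_state):
        h = h + _mha(blk["attn"], h, config.n_heads)
        h = _sn(h, blk["sn1"], running["sn1"], config.epsilon, training, collect)
        m = leaky_relu(linear(h, blk["mlp"]["W0"], blk["mlp"]["b0"]), config.leaky_slope)
        h = h + linear(m, blk["mlp"]["W1"], blk["mlp"]["b1"])
        h = _sn(h, blk["sn2"], running["sn2"], config.epsilon, training, collect)
    pooled = anp.mean(h, axis=1)  # (B, D)
    return reduction_head(pooled, params["head"], config.leaky_slope)


def apply_bn_update(state: EncoderState, collected: list) -> None:
    """Fold batch statistics gathered during a training forward pass into the
    running BN state (exponential moving average)."""
    it = iter(collected)
    mom = state.config.bn_momentum
    for running in state.bn_state:
        for key in ("sn1", "sn2"):
            mean, var = next(it)
            running[key]["mean"] = (1 - mom) * running[key]["mean"] + mom * mean
            running[key]["var"] = (1 - mom) * running[key]["var"] + mom * var


def update_bn_state(state: EncoderState, X: np.ndarray) -> None:
    """Refresh BN running statistics from one training-mode forward pass."""
    collected: list = []
    encoder_forward(state.params, np.atleast_2d(X), state.config, state.modality_dims,
                    state.bn_state, training=True, collect=collected)
    apply_bn_update(state, collected)


def encode(X, state: EncoderState, training: bool = False) -> np.ndarray:
    """Public encoding entry point; inference mode is deterministic and
    batch-independent (BN uses frozen running statistics)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Z = encoder_forward(state.params, np.atleast_2d(X), state.config,
                        state.modality_dims, state.bn_state, training=training)
    Z = np.asarray(Z)
    return Z[0] if single else Z
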