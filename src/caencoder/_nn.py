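"""Shared numerical building blocks for the autograd-based networks.

All model code in this package is written functionally: parameters are nested
dicts/lists of plain numpy arrays and every forward pass is a pure function of
them, so ``autograd`` can differentiate end to end.  Nothing here mutates its
inputs.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.tracer import isbox


def as_float_array(x):
    """np.asarray for concrete inputs; identity for autograd-boxed ones
    (asarray has no VJP and would break the trace)."""
    return x if isbox(x) else np.asarray(x, dtype=float)


def ensure_2d(x):
    """Promote a vector to a single-row matrix without leaving the trace."""
    x = as_float_array(x)
    return x.reshape((1, -1)) if x.ndim == 1 else x


def leaky_relu(x, slope: float = 0.2):
    return anp.where(x > 0, x, slope * x)


def linear(x, W, b):
    return anp.dot(x, W) + b


def softmax(x, axis: int = -1):
    shifted = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=axis, keepdims=True)


def conv1d(x, w, b: float = 0.0):
    """Bare valid-mode 1D cross-correlation: y_i = Σ_j w_j·x_{i+j} + b.

    Output length is len(x) − k + 1; padding is the caller's business.
    """
    x = as_float_array(x)
    w = as_float_array(w)
    k = w.shape[0]
    n = x.shape[0]
    if k > n:
        raise ValueError(f"kernel size {k} exceeds input length {n}")
    windows = anp.stack([x[j:n - k + 1 + j] for j in range(k)], axis=0)  # (k, n-k+1)
    return anp.dot(w, windows) + b


def conv1d_same_multichannel(x, w, b):
    """Multi-channel 1D conv with zero same-padding.

    x: (B, C_in, L); w: (C_out, C_in, k) with k odd; b: (C_out,).
    Returns (B, C_out, L).
    """
    k = w.shape[2]
    pad = (k - 1) // 2
    B, C, L = x.shape
    zeros = anp.zeros((B, C, pad))
    xp = anp.concatenate([zeros, x, zeros], axis=2)
    # sum of k shifted channel-mixing products; cheaper to differentiate than
    # materialising a (B, C, k, L) window tensor
    out = anp.einsum("oi,bil->bol", w[:, :, 0], xp[:, :, 0:L])
    for j in range(1, k):
        out = out + anp.einsum("oi,bil->bol", w[:, :, j], xp[:, :, j:j + L])
    return out + b[None, :, None]


def gaussian_init(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int | None = None) -> np.ndarray:
    """Scaled-Gaussian initialisation, std = 1/sqrt(fan_in)."""
    if fan_in is None:
        fan_in = shape[0]
    return rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), size=shape)


def linear_params(rng: np.random.Generator, n_in: int, n_out: int) -> dict:
    return {"W": gaussian_init(rng, (n_in, n_out), fan_in=n_in),
            "b": np.zeros(n_out)}


def check_finite(name: str, *arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(np.asarray(a, dtype=float))):
            raise FloatingPointError(f"non-finite values in {name}")
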