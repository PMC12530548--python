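"""1D CycleGAN: generators G1 (latent → data) and G2 (data → latent) and
discriminators D1 (data space) and D2 (latent space).

Each network maps a flat feature vector through an input linear layer onto a
(channels × length) grid, a stack of same-padded 1D convolutions with Leaky
ReLU, and an output linear layer.  Discriminators end in a single linear
score with no squashing nonlinearity — hinge-loss semantics require raw,
unbounded scores (trained toward ≥ +1 on real and ≤ −1 on generated input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (conv1d_same_multichannel, ensure_2d, gaussian_init,
                  leaky_relu, linear)

# re-export the bare 1D convolution primitive (valid mode, exactly
# y_i = Σ_j w_j x_{i+j} + b) alongside the networks built from it
from ._nn import conv1d  # noqa: F401


@dataclass
class GeneratorConfig:
    direction: str                       # "latent_to_data" or "data_to_latent"
    hidden_channels: tuple[int, ...] = (16, 32, 32, 16)  # grid + per-conv output channels
    kernel_size: int = 3
    grid_length: int = 32
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.direction not in ("latent_to_data", "data_to_latent"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def n_conv_layers(self) -> int:
        return len(self.hidden_channels) - 1


@dataclass
class DiscriminatorConfig:
    input_dim: int
    hidden_channels: tuple[int, ...] = (16, 32, 16)
    kernel_size: int = 3
    grid_length: int = 32
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


@dataclass
class CycleGanState:
    """Parameters and configs of all four networks for fixed (n_x, n_z)."""

    n_x: int
    n_z: int
    params: dict                          # {"G1","G2","D1","D2"}
    g1_config: GeneratorConfig = field(default=None)  # type: ignore[assignment]
    g2_config: GeneratorConfig = field(default=None)  # type: ignore[assignment]
    d1_config: DiscriminatorConfig = field(default=None)  # type: ignore[assignment]
    d2_config: DiscriminatorConfig = field(default=None)  # type: ignore[assignment]


def _net_params(rng: np.random.Generator, in_dim: int, out_dim: int,
                channels: tuple[int, ...], k: int, L: int) -> dict:
    p = {
        "lin_in": {"W": gaussian_init(rng, (in_dim, channels[0] * L), fan_in=in_dim),
                   "b": np.zeros(channels[0] * L)},
        "convs": [],
        "lin_out": {"W": gaussian_init(rng, (channels[-1] * L, out_dim),
                                       fan_in=channels[-1] * L),
                    "b": np.zeros(out_dim)},
    }
    for c_in, c_out in zip(channels, channels[1:]):
        p["convs"].append({"w": gaussian_init(rng, (c_out, c_in, k), fan_in=c_in * k),
                           "b": np.zeros(c_out)})
    return p


def init_cyclegan(n_x: int, n_z: int, rng: np.random.Generator,
                  g1_config: GeneratorConfig | None = None,
                  g2_config: GeneratorConfig | None = None,
                  d1_config: DiscriminatorConfig | None = None,
                  d2_config: DiscriminatorConfig | None = None) -> CycleGanState:
    g1 = g1_config or GeneratorConfig("latent_to_data")
    g2 = g2_config or GeneratorConfig("data_to_latent")
    d1 = d1_config or DiscriminatorConfig(input_dim=n_x)
    d2 = d2_config or DiscriminatorConfig(input_dim=n_z)
    params = {
        "G1": _net_params(rng, n_z, n_x, g1.hidden_channels, g1.kernel_size, g1.grid_length),
        "G2": _net_params(rng, n_x, n_z, g2.hidden_channels, g2.kernel_size, g2.grid_length),
        "D1": _net_params(rng, n_x, 1, d1.hidden_channels, d1.kernel_size, d1.grid_length),
        "D2": _net_params(rng, n_z, 1, d2.hidden_channels, d2.kernel_size, d2.grid_length),
    }
    return CycleGanState(n_x=n_x, n_z=n_z, params=params, g1_config=g1,
                         g2_config=g2, d1_config=d1, d2_config=d2)


def _net_forward(p: dict, x, channels: tuple[int, ...], L: int, slope: float):
    """linear → (channels × L) grid → same-padded convs (Leaky ReLU) → linear."""
    x = ensure_2d(x)
    B = x.shape[0]
    h = linear(x, p["lin_in"]["W"], p["lin_in"]["b"]).reshape((B, channels[0], L))
    for conv in p["convs"]:
        h = leaky_relu(conv1d_same_multichannel(h, conv["w"], conv["b"]), slope)
    h = h.reshape((B, -1))
    return linear(h, p["lin_out"]["W"], p["lin_out"]["b"])


def generator_forward(p: dict, x, config: GeneratorConfig):
    return _net_forward(p, x, config.hidden_channels, config.grid_length,
                        config.leaky_slope)


def discriminator_forward(p: dict, x, config: DiscriminatorConfig):
    """Raw scalar scores, shape (B,); the final layer is linear on purpose."""
    return _net_forward(p, x, config.hidden_channels, config.grid_length,
                        config.leaky_slope)[:, 0]


def _check_dim(v: np.ndarray, dim: int, what: str) -> None:
    if np.atleast_2d(np.asarray(v)).shape[1] != dim:
        raise ValueError(f"{what}: expected dimension {dim}, "
                         f"got {np.atleast_2d(np.asarray(v)).shape[1]}")


def generate_data(z, state: CycleGanState) -> np.ndarray:
    """G1: latent z → synthetic multi-omics vector x̄ of length n_x."""
    _check_dim(z, state.n_z, "generate_data")
    out = np.asarray(generator_forward(state.params["G1"], z, state.g1_config))
    return out[0] if np.asarray(z).ndim == 1 else out


def generate_latent(x, state: CycleGanState) -> np.ndarray:
    """G2: data vector x → reconstructed latent z̄ of length n_z."""
    _check_dim(x, state.n_x, "generate_latent")
    out = np.asarray(generator_forward(state.params["G2"], x, state.g2_config))
    return out[0] if np.asarray(x).ndim == 1 else out


def discriminate(v, which: str, state: CycleGanState) -> np.ndarray:
    """Raw score(s) from D1 (data space) or D2 (latent space)."""
    if which == "D1":
        _check_dim(v, state.n_x, "discriminate D1")
        cfg = state.d1_config
    elif which == "D2":
        _check_dim(v, state.n_z, "discriminate D2")
        cfg = state.d2_config
    else:
        raise ValueError(f"unknown discriminator {which!r}")
    out = np.asarray(discriminator_forward(state.params[which], v, cfg))
    return float(out[0]) if np.asarray(v).ndim == 1 else out
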