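"""Synthetic multi-omics generator with known class structure.

A linear-Gaussian factor model: each sample owns a shared latent factor drawn
around its class mean, and each modality observes a mix of that shared factor
(through fixed random loadings) and a modality-private factor, plus Gaussian
noise.  The ``shared_signal_fraction`` dial moves modalities between fully
redundant (1.0) and conditionally independent given the class (0.0) — the
latter is the regime where integrating modalities genuinely beats any single
one.  A fraction of columns is discretised into three levels by per-column
tertiles, mimicking CNV-style loss/neutral/gain coding, so categorical
preprocessing is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .omics_data import MultiOmicsDataset, OmicsModality

TERTILE_LEVELS = ("gain", "loss", "neutral")  # assigned by code, listed sorted


@dataclass
class SyntheticSpec:
    n_classes: int = 3
    samples_per_class: tuple[int, ...] = (60, 60, 60)
    modality_dims: tuple[int, ...] = (120, 90, 60)
    latent_factor_dim: int = 8
    class_separation: float = 4.0
    shared_signal_fraction: float = 0.5
    noise_sd: float = 1.0
    categorical_fraction: float = 0.1
    seed: int = 0
    modality_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_classes < 1 or len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must list one count per class")
        if any(s < 1 for s in self.samples_per_class):
            raise ValueError("samples_per_class entries must be >= 1")
        if any(d < 1 for d in self.modality_dims) or self.latent_factor_dim < 1:
            raise ValueError("all dimensions must be >= 1")
        if not (0.0 <= self.shared_signal_fraction <= 1.0):
            raise ValueError("shared_signal_fraction must lie in [0, 1]")
        if not (0.0 <= self.categorical_fraction <= 1.0):
            raise ValueError("categorical_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.class_separation <= 0:
            raise ValueError("noise_sd must be >= 0 and class_separation > 0")
        if self.latent_factor_dim < self.n_classes:
            raise ValueError("latent_factor_dim must be >= n_classes "
                             "(class means occupy orthogonal axes)")
        if not self.modality_names:
            self.modality_names = tuple(f"mod{m+1}" for m in range(len(self.modality_dims)))


def _class_means(spec: SyntheticSpec) -> np.ndarray:
    """Class means on orthogonal axes, pairwise distance exactly class_separation."""
    mu = np.zeros((spec.n_classes, spec.latent_factor_dim))
    for c in range(spec.n_classes):
        mu[c, c] = spec.class_separation / np.sqrt(2.0)
    return mu


def generate(spec: SyntheticSpec) -> MultiOmicsDataset:
    """Draw a full MultiOmicsDataset; identical seeds give identical datasets."""
    rng = np.random.default_rng(spec.seed)
    d_f = spec.latent_factor_dim
    mu = _class_means(spec)
    labels = np.concatenate([np.full(n, f"class{c+1}")
                             for c, n in enumerate(spec.samples_per_class)])
    n_total = len(labels)
    class_idx = np.concatenate([np.full(n, c) for c, n in enumerate(spec.samples_per_class)])
    shared = mu[class_idx] + rng.normal(size=(n_total, d_f))

    s = spec.shared_signal_fraction
    modalities = []
    for m, (dim, name) in enumerate(zip(spec.modality_dims, spec.modality_names)):
        A = rng.normal(0.0, 1.0 / np.sqrt(d_f), size=(d_f, dim))
        B = rng.normal(0.0, 1.0 / np.sqrt(d_f), size=(d_f, dim))
        private = rng.normal(size=(n_total, d_f))
        X = s * (shared @ A) + (1.0 - s) * (private @ B)
        if spec.noise_sd > 0:
            X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)

        n_cat = int(np.ceil(spec.categorical_fraction * dim)) if spec.categorical_fraction else 0
        if n_cat:
            cat_cols = rng.choice(dim, size=n_cat, replace=False)
            values = X.astype(object)
            level_by_code = ("loss", "neutral", "gain")  # tertile order low→high
            for j in cat_cols:
                cuts = np.quantile(X[:, j].astype(float), [1 / 3, 2 / 3])
                codes = np.digitize(X[:, j].astype(float), cuts)
                values[:, j] = np.array([level_by_code[c] for c in codes], dtype=object)
        else:
            values = X
        modalities.append(OmicsModality(
            name=name,
            values=values,
            feature_names=[f"{name}_f{j}" for j in range(dim)],
            sample_ids=[f"S{i:04d}" for i in range(n_total)],
        ))
    return MultiOmicsDataset(modalities=modalities, labels=labels)


def generate_easy_benchmark(seed: int = 0) -> MultiOmicsDataset:
    """The fixed benchmark recipe used throughout the test harness.

    3 balanced classes of 60, three modalities of 120/90/60 features, an
    8-dimensional shared factor with class-mean separation 4.0, half of each
    modality's signal shared, unit noise, and 10% tertile-categorical columns.
    """
    return generate(SyntheticSpec(
        n_classes=3,
        samples_per_class=(60, 60, 60),
        modality_dims=(120, 90, 60),
        latent_factor_dim=8,
        class_separation=4.0,
        shared_signal_fraction=0.5,
        noise_sd=1.0,
        categorical_fraction=0.1,
        seed=seed,
    ))
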