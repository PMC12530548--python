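"""The frozen desk-scale benchmark: a reduced encoder on the synthetic fixture.

This module pins one complete recipe — fixture, model size, optimisation
schedule, loss weights — so that the end-to-end properties of the method
(latent classification quality, ablation ordering, modality synergy) are
measured under identical conditions everywhere: in the test suite, in the
acceptance script, and in any ad-hoc exploration.

The recipe, chosen once on a development split and then frozen:

* fixture: :func:`caencoder.synthetic_data.generate_easy_benchmark`
  (180 samples, 3 classes, modalities of 120/90/60 features);
* encoder: 2 transformer blocks, 2 heads, 64-dim embedding, 16-dim latent;
* schedule: 30 epochs, batch 32, Adam lr 1e-3, 4 triplet draws per anchor
  per epoch — the package-default lr of 1e-4 suits a schedule an order of
  magnitude longer; at ~600 total steps it barely moves the parameters;
* triplets: negatives swap 2 of 3 modalities to a foreign class — with only
  three modalities a single-swap negative shares two thirds of its content
  with the anchor and provides too weak a repulsive signal;
* loss weights: margin 1.0, α_cycle 3e-4, β_adv 0.1 — the printed loss forms
  are batch sums (cycle terms additionally sum over all n_x features), so
  commensurate gradient contributions require α ≪ 1 here, unlike the mean
  -reduced convention behind the usual CycleGAN α = 10;
* compact CycleGAN nets: channels (8, 16, 8) on a length-16 grid;
* evaluation: Random Forest with 15 trees on the held-out fifth of a
  stratified split.
"""

from __future__ import annotations

import numpy as np

from .cyclegan_1d import DiscriminatorConfig, GeneratorConfig
from .encoder_vit import EncoderConfig
from .evaluation import classify_latent
from .losses import LossWeights
from .omics_data import MultiOmicsDataset, make_folds
from .synthetic_data import generate_easy_benchmark
from .training import TrainConfig, TrainState, encode_fold, train

BENCHMARK_SEEDS = (0, 1, 2)


def reduced_encoder_config() -> EncoderConfig:
    return EncoderConfig(n_blocks=2, n_heads=2, embed_dim=64, latent_dim=16)


def reduced_train_config(seed: int, variant: str = "full") -> TrainConfig:
    return TrainConfig(epochs=30, batch_size=32, learning_rate=1e-3,
                       triplets_per_anchor=4, n_swap=2, seed=seed,
                       variant=variant)


def reduced_loss_weights() -> LossWeights:
    return LossWeights(margin=1.0, alpha_cycle=3e-4, beta_adv=0.1)


def reduced_gan_configs(n_x: int, n_z: int) -> dict:
    return {
        "g1_config": GeneratorConfig("latent_to_data", hidden_channels=(8, 16, 8),
                                     grid_length=16),
        "g2_config": GeneratorConfig("data_to_latent", hidden_channels=(8, 16, 8),
                                     grid_length=16),
        "d1_config": DiscriminatorConfig(input_dim=n_x, hidden_channels=(8, 16, 8),
                                         grid_length=16),
        "d2_config": DiscriminatorConfig(input_dim=n_z, hidden_channels=(8, 16, 8),
                                         grid_length=16),
    }


def run_reduced_benchmark(seed: int, variant: str = "full",
                          dataset: MultiOmicsDataset | None = None,
                          modality_subset: list[str] | None = None) -> dict:
    """Train the reduced model on the fixture and score held-out RF latents.

    One stratified 80/20 split per seed; the same split serves every variant
    and modality subset at that seed, so comparisons are paired.
    """
    ds = dataset if dataset is not None else generate_easy_benchmark(seed)
    if modality_subset is not None:
        ds = ds.subset_modalities(modality_subset)
    fold = make_folds(ds, k=5, repeats=1, seed=seed)[0]
    enc_cfg = reduced_encoder_config()
    config = reduced_train_config(seed, variant)
    nets = {} if variant == "RC" else reduced_gan_configs(
        ds.n_features_total, enc_cfg.latent_dim)
    state: TrainState = train(ds, fold, config, reduced_loss_weights(),
                              enc_cfg, **nets)
    z_train = encode_fold(state, fold.train_indices)
    z_test = encode_fold(state, fold.test_indices)
    report = classify_latent(z_train, ds.labels[fold.train_indices],
                             z_test, ds.labels[fold.test_indices],
                             classifier="RF", seed=seed)
    return {"seed": int(seed), "variant": variant,
            "modalities": ds.modality_names(),
            "accuracy": report.accuracy, "macro_f1": report.macro_f1,
            "state": state, "fold": fold, "dataset": ds}
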