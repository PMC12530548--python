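"""End-to-end optimisation of the encoder + 1D CycleGAN.

Each step alternates two phases: a discriminator phase (update D1 and D2 on
their hinge objective, encoder and generators frozen) and a generator phase
(update the encoder and both generators on the weighted total loss,
discriminators frozen).  Both phases use Adam with global-norm gradient
clipping and classic L2 weight decay.  Ablation variants: ``notCL`` zeroes the
contrastive coefficient (CycleGAN feedback only), ``RC`` drops the CycleGAN
entirely (contrastive loss only).

Cross-validation repeats a stratified k-fold partition under different seeds;
normalisation and categorical encodings are fitted on each training fold only,
and a provenance audit records every sample index that supplied any modality
of any training triplet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from .cyclegan_1d import (CycleGanState, DiscriminatorConfig, GeneratorConfig,
                          discriminator_forward, generator_forward, init_cyclegan)
from .encoder_vit import (EncoderConfig, EncoderState, apply_bn_update, encode,
                          encoder_forward, init_encoder)
from .losses import (LossReport, LossWeights, contrastive_loss, cycle_loss,
                     disc_loss, gen_adv_loss)
from .omics_data import FoldSplit, MultiOmicsDataset, make_folds, preprocess_fold
from .triplet_sampling import TripletBatch, audit_sources, epoch_batches

VARIANTS = ("full", "notCL", "RC")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    clip_norm: float = 1.0
    weight_decay: float = 1e-5
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    variant: str = "full"
    n_swap: int = 1                 # foreign-class modalities per negative
    disc_steps: int = 1             # discriminator updates per generator update
    triplets_per_anchor: int = 1    # triplet draws per anchor per epoch

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.clip_norm <= 0 or self.epochs < 1:
            raise ValueError("learning_rate, clip_norm must be > 0 and epochs >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def clip_gradients(grads, clip_norm: float):
    """Scale a gradient tree so its global L2 norm is at most clip_norm."""
    flat, unflatten = flatten(grads)
    norm = float(np.linalg.norm(flat))
    if norm > clip_norm:
        flat = flat * (clip_norm / norm)
    return unflatten(flat), norm


class Adam:
    """Adam over a flattened parameter tree, with L2 weight decay folded into
    the gradient before global-norm clipping."""

    def __init__(self, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = self.v = None
        self.t = 0

    def step(self, params, grads, clip_norm: float):
        gflat, _ = flatten(grads)
        pflat, unflatten = flatten(params)
        g = gflat + self.wd * pflat
        norm = float(np.linalg.norm(g))
        if norm > clip_norm:
            g = g * (clip_norm / norm)
        if self.m is None:
            self.m = np.zeros_like(pflat)
            self.v = np.zeros_like(pflat)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        m_hat = self.m / (1 - self.b1 ** self.t)
        v_hat = self.v / (1 - self.b2 ** self.t)
        return unflatten(pflat - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


@dataclass
class TrainState:
    encoder: EncoderState
    cyclegan: CycleGanState | None
    config: TrainConfig
    weights: LossWeights
    opt_g: Adam
    opt_d: Adam | None
    epoch: int = 0
    history: list[LossReport] = field(default_factory=list)
    epoch_means: list[dict] = field(default_factory=list)
    train_sources: set = field(default_factory=set)   # provenance audit (original indices)


def init_train_state(modality_dims: list[int], config: TrainConfig,
                     weights: LossWeights, encoder_config: EncoderConfig | None = None,
                     g1_config: GeneratorConfig | None = None,
                     g2_config: GeneratorConfig | None = None,
                     d1_config: DiscriminatorConfig | None = None,
                     d2_config: DiscriminatorConfig | None = None) -> TrainState:
    rng = np.random.default_rng(config.seed)
    enc_cfg = encoder_config or EncoderConfig()
    encoder = init_encoder(enc_cfg, list(modality_dims), rng)
    n_x = int(sum(modality_dims))
    if config.variant == "RC":
        cyclegan, opt_d = None, None
    else:
        cyclegan = init_cyclegan(n_x, enc_cfg.latent_dim, rng, g1_config, g2_config,
                                 d1_config, d2_config)
        opt_d = Adam(config.learning_rate, config.weight_decay)
    opt_g = Adam(config.learning_rate, config.weight_decay)
    return TrainState(encoder=encoder, cyclegan=cyclegan, config=config,
                      weights=weights, opt_g=opt_g, opt_d=opt_d)


def _encode_train(enc_params, X, state: TrainState, collect=None):
    e = state.encoder
    return encoder_forward(enc_params, X, e.config, e.modality_dims, e.bn_state,
                           training=True, collect=collect)


def _concrete(v) -> float:
    """Pull the numeric value out of a possibly autograd-boxed scalar."""
    while hasattr(v, "_value"):
        v = v._value
    return float(v)


def _split_roles(arr, n: int) -> tuple:
    return arr[:n], arr[n:2 * n], arr[2 * n:]


def train_step(batch: TripletBatch, state: TrainState) -> LossReport:
    """One optimisation step: discriminator phase then encoder/generator phase.

    The three triplet roles are stacked into a single (3N × ·) batch per
    network call; role-wise loss terms are taken on slices, which is exact
    because the roles share the batch size.
    """
    cfg, w = state.config, state.weights
    n = len(batch)
    X_all = np.vstack([batch.anchors, batch.positives, batch.negatives])
    report = LossReport()
    gan = state.cyclegan

    if gan is not None:
        # ---- discriminator phase: E, G1, G2 frozen ----
        Z_all = np.asarray(_encode_train(state.encoder.params, X_all, state))
        x_fake = np.asarray(generator_forward(gan.params["G1"], Z_all, gan.g1_config))
        z_fake = np.asarray(generator_forward(gan.params["G2"], X_all, gan.g2_config))

        def d_objective(d_params):
            s_real_x = discriminator_forward(d_params["D1"], X_all, gan.d1_config)
            s_fake_x = discriminator_forward(d_params["D1"], x_fake, gan.d1_config)
            s_real_z = discriminator_forward(d_params["D2"], Z_all, gan.d2_config)
            s_fake_z = discriminator_forward(d_params["D2"], z_fake, gan.d2_config)
            l_d1 = disc_loss(_split_roles(s_real_x, n), _split_roles(s_fake_x, n))
            l_d2 = disc_loss(_split_roles(s_real_z, n), _split_roles(s_fake_z, n))
            report.l_d1, report.l_d2 = _concrete(l_d1), _concrete(l_d2)
            return l_d1 + l_d2

        for _ in range(cfg.disc_steps):
            d_params = {"D1": gan.params["D1"], "D2": gan.params["D2"]}
            _, d_grads = value_and_grad(d_objective)(d_params)
            new_d = state.opt_d.step(d_params, d_grads, cfg.clip_norm)
            gan.params["D1"], gan.params["D2"] = new_d["D1"], new_d["D2"]

    # ---- generator phase: D1, D2 frozen ----
    con_coef = 0.0 if cfg.variant == "notCL" else 1.0
    bn_batch_stats: list = []

    def g_objective(tree):
        bn_batch_stats.clear()
        Z_all = _encode_train(tree["E"], X_all, state, collect=bn_batch_stats)
        l_con = contrastive_loss(*_split_roles(Z_all, n), margin=w.margin)
        report.l_con = _concrete(l_con)
        if gan is None:
            total = con_coef * l_con
            report.l_total = _concrete(total)
            return total
        x_bar = generator_forward(tree["G1"], Z_all, gan.g1_config)
        z_bar = generator_forward(tree["G2"], X_all, gan.g2_config)
        l_g1_adv = gen_adv_loss(*_split_roles(
            discriminator_forward(gan.params["D1"], x_bar, gan.d1_config), n))
        l_g2_adv = gen_adv_loss(*_split_roles(
            discriminator_forward(gan.params["D2"], z_bar, gan.d2_config), n))
        z_cycle = generator_forward(tree["G2"], x_bar, gan.g2_config)
        x_cycle = generator_forward(tree["G1"], z_bar, gan.g1_config)
        l_g1_cyc = cycle_loss(_split_roles(Z_all, n), _split_roles(z_cycle, n))
        l_g2_cyc = cycle_loss(_split_roles(X_all, n), _split_roles(x_cycle, n))
        total = (con_coef * l_con + w.alpha_cycle * (l_g1_cyc + l_g2_cyc)
                 + w.beta_adv * (l_g1_adv + l_g2_adv))
        report.l_g1_adv, report.l_g2_adv = _concrete(l_g1_adv), _concrete(l_g2_adv)
        report.l_g1_cycle, report.l_g2_cycle = _concrete(l_g1_cyc), _concrete(l_g2_cyc)
        report.l_total = _concrete(total)
        return total

    tree = {"E": state.encoder.params}
    if gan is not None:
        tree["G1"], tree["G2"] = gan.params["G1"], gan.params["G2"]
    _, g_grads = value_and_grad(g_objective)(tree)
    if not np.isfinite(report.l_total):
        bad = [k for k, v in report.as_dict().items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite loss component(s): {bad}")
    new_tree = state.opt_g.step(tree, g_grads, cfg.clip_norm)
    state.encoder.params = new_tree["E"]
    if gan is not None:
        gan.params["G1"], gan.params["G2"] = new_tree["G1"], new_tree["G2"]

    apply_bn_update(state.encoder, bn_batch_stats)
    state.history.append(report)
    return report


def train(dataset: MultiOmicsDataset, fold: FoldSplit, config: TrainConfig,
          weights: LossWeights, encoder_config: EncoderConfig | None = None,
          preprocess: bool = True, **net_configs) -> TrainState:
    """Train on the fold's training samples only; returns the fitted state.

    The returned state carries the fold, the fold-preprocessed dataset (train
    statistics applied to all rows, so held-out rows can be encoded), and the
    provenance audit of every training-triplet source.
    """
    if preprocess:
        processed, _, _ = preprocess_fold(dataset, fold)
    else:
        processed = dataset
    train_ds = processed.subset_rows(fold.train_indices)
    state = init_train_state(train_ds.modality_dims, config, weights,
                             encoder_config, **net_configs)
    rng = np.random.default_rng(config.seed)
    orig_index = np.asarray(fold.train_indices)
    for _ in range(config.epochs):
        for _pass in range(config.triplets_per_anchor):
            for batch in epoch_batches(train_ds, config.batch_size, rng,
                                       n_swap=config.n_swap):
                train_step(batch, state)
                state.train_sources.update(
                    int(orig_index[i]) for i in audit_sources([batch]))
        n_batches = config.triplets_per_anchor * \
            -(-train_ds.n_samples // config.batch_size)
        recent = state.history[-n_batches:]
        state.epoch_means.append({
            k: float(np.mean([r.as_dict()[k] for r in recent]))
            for k in recent[0].as_dict()})
        state.epoch += 1
    state.processed_dataset = processed
    state.fold = fold
    return state


def encode_fold(state: TrainState, indices) -> np.ndarray:
    """Inference-mode latents for rows of the fold-preprocessed dataset."""
    ds = state.processed_dataset.subset_rows(indices)
    X = np.column_stack([np.asarray(m.values, dtype=float) for m in ds.modalities])
    return np.asarray(encode(X, state.encoder, training=False))


def run_cv(dataset: MultiOmicsDataset, config: TrainConfig, weights: LossWeights,
           k: int = 5, repeats: int = 5,
           encoder_config: EncoderConfig | None = None,
           classifier: str = "RF", **net_configs):
    """k-fold CV repeated under different seeds; returns a per-fold metrics table.

    Each repeat r uses its own stratified partition seeded by config.seed+r;
    all k×repeats fold results are pooled (see :func:`summarize_cv`).
    """
    import pandas as pd

    from .evaluation import classify_latent

    folds = make_folds(dataset, k=k, repeats=repeats, seed=config.seed)
    rows = []
    for fold in folds:
        fold_seed = (fold.seed * k + fold.fold_id) % (2 ** 31)
        fold_config = TrainConfig(**{**asdict(config), "seed": fold_seed})
        state = train(dataset, fold, fold_config, weights, encoder_config,
                      **net_configs)
        z_train = encode_fold(state, fold.train_indices)
        z_test = encode_fold(state, fold.test_indices)
        row = classify_latent(z_train, dataset.labels[fold.train_indices],
                              z_test, dataset.labels[fold.test_indices],
                              classifier=classifier, seed=fold_seed)
        rows.append({"repeat_seed": fold.seed, "fold": fold.fold_id,
                     "accuracy": row.accuracy, "macro_f1": row.macro_f1})
    return pd.DataFrame(rows)


def summarize_cv(table) -> dict:
    """Pooled mean ± sd of ACC and macro-F1 over all folds × repeats."""
    return {
        "acc_mean": float(table["accuracy"].mean()),
        "acc_sd": float(table["accuracy"].std(ddof=1)) if len(table) > 1 else 0.0,
        "f1_mean": float(table["macro_f1"].mean()),
        "f1_sd": float(table["macro_f1"].std(ddof=1)) if len(table) > 1 else 0.0,
        "n_folds": int(len(table)),
    }


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(state: TrainState, path: str) -> None:
    """Single-container checkpoint: all network parameters + configs + BN stats."""
    payload = {
        "encoder_params": state.encoder.params,
        "bn_state": state.encoder.bn_state,
        "modality_dims": state.encoder.modality_dims,
    }
    if state.cyclegan is not None:
        payload["gan_params"] = state.cyclegan.params
        payload["gan_dims"] = (state.cyclegan.n_x, state.cyclegan.n_z)
    meta = {
        "encoder_config": asdict(state.encoder.config),
        "train_config": asdict(state.config),
        "loss_weights": asdict(state.weights),
        "epoch": state.epoch,
    }
    np.savez(path, payload=np.array([payload], dtype=object),
             meta=json.dumps(meta))


def load_checkpoint(path: str) -> TrainState:
    with np.load(path, allow_pickle=True) as f:
        payload = f["payload"][0]
        meta = json.loads(str(f["meta"]))
    enc_cfg = EncoderConfig(**{**meta["encoder_config"],
                               "head_dims": tuple(meta["encoder_config"]["head_dims"])})
    config = TrainConfig(**meta["train_config"])
    weights = LossWeights(**meta["loss_weights"])
    encoder = EncoderState(config=enc_cfg, modality_dims=list(payload["modality_dims"]),
                           params=payload["encoder_params"],
                           bn_state=payload["bn_state"])
    cyclegan = None
    if "gan_params" in payload:
        n_x, n_z = payload["gan_dims"]
        rng = np.random.default_rng(0)
        cyclegan = init_cyclegan(int(n_x), int(n_z), rng)
        cyclegan.params = payload["gan_params"]
    state = TrainState(encoder=encoder, cyclegan=cyclegan, config=config,
                       weights=weights, opt_g=Adam(config.learning_rate),
                       opt_d=None if cyclegan is None else Adam(config.learning_rate))
    state.epoch = int(meta["epoch"])
    return state
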