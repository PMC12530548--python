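"""Objective terms for contrastive-adversarial training.

Three families of losses act on a triplet batch (anchor / positive / negative
roles, batch size N):

* triplet-margin contrastive loss on latents, summed over the batch:
  Σ_i ‖z_a−z_p‖² + max(0, m − ‖z_a−z_n‖²);
* hinge adversarial losses — generators are penalised when the discriminator
  scores their output below +1, discriminators when real scores fall below +1
  or fake scores above −1;
* L1 cycle-consistency losses through G2∘G1 (latent cycle) and G1∘G2 (data
  cycle).

The total objective for the encoder/generator phase is
L_total = L_con + α(L_G1cyc + L_G2cyc) + β(L_G1adv + L_G2adv); the
discriminator losses are the discriminators' separate objective and are never
part of L_total.  All functions are autograd-differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import autograd.numpy as anp
import numpy as np

from ._nn import as_float_array, ensure_2d


@dataclass(frozen=True)
class LossWeights:
    """margin m of the triplet loss; α weights the cycle terms, β the adversarial."""

    margin: float = 1.0
    alpha_cycle: float = 10.0
    beta_adv: float = 1.0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.alpha_cycle < 0 or self.beta_adv < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossReport:
    """Per-step component losses; discriminator terms reported alongside."""

    l_con: float = 0.0
    l_g1_adv: float = 0.0
    l_g2_adv: float = 0.0
    l_d1: float = 0.0
    l_d2: float = 0.0
    l_g1_cycle: float = 0.0
    l_g2_cycle: float = 0.0
    l_total: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


def _check_shapes(*batches) -> None:
    shapes = {as_float_array(b).shape for b in batches}
    if len(shapes) != 1:
        raise ValueError(f"role batches have mismatched shapes: {sorted(shapes)}")


def contrastive_loss(z_a, z_p, z_n, margin: float = 1.0, reduction: str = "sum"):
    """Triplet-margin loss on latent batches (N × n_z), summed over the batch.

    ``reduction="mean"`` divides by N; the printed form (sum) is the default
    and couples with the learning rate, so the choice is logged in configs.
    """
    z_a, z_p, z_n = (as_float_array(z) for z in (z_a, z_p, z_n))
    _check_shapes(z_a, z_p, z_n)
    d_pos = anp.sum((z_a - z_p) ** 2, axis=-1)
    d_neg = anp.sum((z_a - z_n) ** 2, axis=-1)
    per_item = d_pos + anp.maximum(0.0, margin - d_neg)
    if reduction == "mean":
        return anp.mean(per_item)
    return anp.sum(per_item)


def gen_adv_loss(scores_anchor, scores_positive, scores_negative):
    """Hinge generator loss: −(1/3) Σ_roles mean[min(0, −1 + D(G(·)))].

    Zero once the discriminator scores generated samples at or above +1;
    equals 2 when every fake scores −1.
    """
    roles = [as_float_array(s) for s in
             (scores_anchor, scores_positive, scores_negative)]
    if any(r.size == 0 for r in roles):
        raise ValueError("empty score batch")
    return -(1.0 / 3.0) * sum(anp.mean(anp.minimum(0.0, -1.0 + r)) for r in roles)


def disc_loss(scores_real: tuple, scores_fake: tuple):
    """Hinge discriminator loss over the three roles:
    (1/6) Σ [mean max(0, 1 − D(real)) + mean max(0, 1 + D(fake))]."""
    if len(scores_real) != 3 or len(scores_fake) != 3:
        raise ValueError("expected three real and three fake score batches")
    real = [as_float_array(s) for s in scores_real]
    fake = [as_float_array(s) for s in scores_fake]
    if any(r.size == 0 for r in real + fake):
        raise ValueError("empty score batch")
    total = sum(anp.mean(anp.maximum(0.0, 1.0 - r)) for r in real)
    total = total + sum(anp.mean(anp.maximum(0.0, 1.0 + f)) for f in fake)
    return total / 6.0


def cycle_loss(originals: tuple, reconstructions: tuple):
    """L1 cycle-consistency: (1/3) Σ_roles Σ_i ‖recon_i − orig_i‖₁."""
    if len(originals) != 3 or len(reconstructions) != 3:
        raise ValueError("expected three original and three reconstructed batches")
    total = 0.0
    for orig, rec in zip(originals, reconstructions):
        orig = ensure_2d(orig)
        rec = ensure_2d(rec)
        _check_shapes(orig, rec)
        total = total + anp.sum(anp.abs(rec - orig))
    return total / 3.0


def total_loss(l_con, l_g1_cycle, l_g2_cycle, l_g1_adv, l_g2_adv,
               weights: LossWeights):
    """L_total = L_con + α(L_G1cyc + L_G2cyc) + β(L_G1adv + L_G2adv)."""
    for name, v in (("l_con", l_con), ("l_g1_cycle", l_g1_cycle),
                    ("l_g2_cycle", l_g2_cycle), ("l_g1_adv", l_g1_adv),
                    ("l_g2_adv", l_g2_adv)):
        # boxed values appear while autograd traces; only concrete ones are checked
        concrete = getattr(v, "_value", v)
        if isinstance(concrete, (int, float, np.floating, np.ndarray)) and \
                not np.all(np.isfinite(concrete)):
            raise FloatingPointError(f"non-finite loss component {name}")
    return (l_con + weights.alpha_cycle * (l_g1_cycle + l_g2_cycle)
            + weights.beta_adv * (l_g1_adv + l_g2_adv))
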