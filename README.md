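# caencoder

Contrastive adversarial encoder for multi-omics data integration.

Cancer subtyping from molecular data works best when several measurement
layers — copy-number variation, mRNA expression, protein arrays, methylation,
miRNA — are analysed jointly, but the concatenated feature vector is far too
wide for the sample counts available. `caencoder` learns a compact latent
representation of multi-omics profiles in which an ordinary classifier (a
Random Forest by default) separates disease subtypes.

## The model

An encoder **E: x → z** maps the concatenated multi-omics vector
x ∈ ℝⁿˣ to a latent vector z ∈ ℝⁿᶻ (n_z ≪ n_x). E is a stack of transformer
blocks — multi-head self-attention with Switch Normalization
SN(x) = α·BN(x) + β·LN(x) and residual additions — followed by a three-layer
reduction head (Leaky ReLU on the first two layers, linear last). No CLS
token is used.

Training couples three objectives on anchor/positive/negative triplets built
across patients and modalities:

* **Triplet margin loss** — an anchor combines all modalities of one
  patient; a positive combines modalities of other patients of the same
  subtype; a negative swaps at least one modality in from a different
  subtype:

  L_con = Σᵢ ‖E(xᵢᵃ)−E(xᵢᵖ)‖² + max(0, m − ‖E(xᵢᵃ)−E(xᵢⁿ)‖²)

* **Hinge adversarial losses** of a 1D CycleGAN: generators G₁: z → x̄ and
  G₂: x → z̄ (linear layers + 1D convolutions) against discriminators D₁
  (data space) and D₂ (latent space), trained toward scores ≥ +1 on real and
  ≤ −1 on generated input.

* **L1 cycle-consistency losses** through G₂∘G₁ (latent cycle) and G₁∘G₂
  (data cycle).

The encoder/generator phase minimises
L_total = L_con + α(L_G1cyc + L_G2cyc) + β(L_G1adv + L_G2adv); the
discriminators minimise their own hinge objectives in an alternating phase.
Because both generators consume z = E(x), adversarial and cycle gradients
flow back into the encoder — the CycleGAN acts as a feedback regulariser on
the latent geometry. At inference only E is used; classification happens in
the latent space.

All networks are implemented functionally on numpy and differentiated with
`autograd`; optimisation is Adam with global-norm gradient clipping and L2
weight decay.

## Worked example

```python
import numpy as np
from caencoder import (generate_easy_benchmark, make_folds, classify_latent,
                       run_reduced_benchmark, pca_baseline)

# synthetic fixture: 180 samples, 3 subtypes, modalities of 120/90/60 features
result = run_reduced_benchmark(seed=0, variant="full")
print(f"latent RF accuracy {result['accuracy']:.4f}  "
      f"macro-F1 {result['macro_f1']:.4f}")

ds = result["dataset"]
fold = result["fold"]
base = pca_baseline(ds, fold, variance_threshold=0.95, seed=0)
print(f"{base.classifier} baseline accuracy {base.accuracy:.4f}")
```

Output on one machine:

```
latent RF accuracy 0.9167  macro-F1 0.9167
PCA(104)+RF baseline accuracy 0.6389
```

The first line is the held-out accuracy of a 15-tree Random Forest reading
the 16-dimensional latents of a reduced encoder (2 blocks, 2 heads, 64-dim
embedding) trained for 30 epochs on one stratified 80/20 split of the
fixture. The second line is the classical arm on the same split: PCA keeping
95% of the variance (104 components here) followed by the same Random
Forest. The gap illustrates what the learned integration adds; averaged over
seeds 0–2 the full model reaches ≈0.93 while the PCA baseline stays
near 0.64.

A command-line interface mirrors the library:

```bash
caencoder simulate --out data/ --seed 0
caencoder train --modality cnv=data/mod1.csv --modality mrna=data/mod2.csv \
    --modality rppa=data/mod3.csv --labels data/labels.csv --out runs/full
caencoder encode --modality ... --labels data/labels.csv \
    --checkpoint runs/full/checkpoint.npz --out latents.csv
```

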