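# Methods

## Model

The encoder E maps a concatenated multi-omics vector x ∈ ℝⁿˣ to a latent
vector z ∈ ℝⁿᶻ. Its default architecture is 8 transformer blocks with 8
attention heads on a 1024-dimensional embedding, followed by a reduction head
of three fully connected layers with output widths 1024 → 512 → 256 (Leaky
ReLU after the first two, linear last), so n_z = 256 by default. Each block
is post-norm residual: h ← SN(h + MHA(h)); h ← SN(h + MLP(h)), where the
per-block MLP is a two-layer expansion (ratio 2) and SN is Switch
Normalization, SN(x) = α·BN(x) + β·LN(x) with trainable scalars α, β
initialised at 0.5 and left unconstrained, per block. BN uses batch
statistics during training (falling back to running statistics when the
normalisation count is 1) and exponential-moving-average running statistics
(momentum 0.1) at inference, which makes inference deterministic and
batch-independent. No CLS token and no positional embeddings are used: the
input has no sequential order, and the goal is a reduced latent vector, not
a classification token.

**Tokenisation.** Self-attention needs a token axis, and a flat omics vector
does not define one canonically. The default `per_modality` scheme projects
each modality through its own linear map to the embedding dimension, giving
T = M tokens, so attention is literally inter-modality attention; tokens are
mean-pooled after the blocks. A `chunked` alternative (fixed number of
equal-width slices of the concatenated vector, zero-padded) is provided; it
performed clearly worse on the synthetic benchmark and is kept for
experimentation only.

**CycleGAN.** Generators G₁: z → x̄ and G₂: x → z̄ and discriminators D₁, D₂
share one layer recipe: input linear map onto a (channels × length) grid,
a stack of same-padded 1D convolutions (kernel 3, Leaky ReLU 0.2), and an
output linear map — a scalar for the discriminators, with no squashing
nonlinearity, as hinge losses require raw scores. The bare `conv1d`
primitive is valid-mode cross-correlation, y_i = Σ_j w_j·x_{i+j} + b;
same-padding is applied inside layers. Package defaults are channels
(16, 32, 32, 16) on a length-32 grid; the desk-scale benchmark uses
(8, 16, 8) on length 16 (see below).

## Objectives

With anchor/positive/negative latent batches (size N):

* contrastive (triplet-margin), summed over the batch as a sum — not a
  mean — which couples its magnitude to the batch size:
  L_con = Σᵢ ‖zᵢᵃ−zᵢᵖ‖² + max(0, m − ‖zᵢᵃ−zᵢⁿ‖²), m > 0;
* generator hinge: −(1/3) Σ_roles mean[min(0, −1 + D(G(·)))] — clipped at
  zero once fakes score above +1, so the generator is not rewarded past the
  margin;
* discriminator hinge: (1/6) Σ over the six role-terms of
  mean[max(0, 1 − D(real))] and mean[max(0, 1 + D(fake))];
* cycle consistency: (1/3) Σ_roles Σᵢ ‖recon − orig‖₁, again a batch sum
  that additionally sums over all feature dimensions;
* total (encoder/generator phase):
  L_total = L_con + α(L_G1cyc + L_G2cyc) + β(L_G1adv + L_G2adv). The
  discriminator losses are the discriminators' separate objective and never
  enter L_total.

Package defaults are m = 1, α = 10, β = 1. Because the cycle terms are sums
over both the batch and all n_x features, α = 10 only makes sense when the
losses are mean-reduced per feature (the convention behind the usual
CycleGAN cycle weight); with the sum forms used here the weighted cycle term
is then 2–3 orders of magnitude larger than L_con and, after global-norm
gradient clipping, monopolises the update direction. Recipes should scale α
by roughly 1/n_x; the benchmark recipe does (α = 3e-4 at n_x = 270).

## Triplet construction

For anchor patient i, the anchor concatenates all M modalities of i. A
positive draws each modality independently and uniformly (with replacement)
from patients sharing i's class — deliberately mixing patients, which acts
as strong augmentation and makes positives hard. A negative takes `n_swap`
modalities from patients of a different class and the rest from patient i.
The package default is n_swap = 1 (the minimal foreign contamination); the
benchmark recipe uses n_swap = 2 because with M = 3 a single-swap negative
shares two thirds of its content with the anchor and the repulsive signal is
too dilute to shape the latent space in a short schedule. Anchors iterate
over the training samples in shuffled order, `triplets_per_anchor` times per
epoch. Batches record full per-role provenance (modality, source index),
which drives both the negative-validity invariant and the cross-validation
hygiene audit.

Anchor classes in randomly sampled batches follow the empirical class
proportions, so imbalanced cohorts are seen in proportion to their
prevalence rather than re-balanced.

## Training

Each step runs a discriminator phase (D₁, D₂ updated on their hinge loss
with encoder and generators frozen) and then an encoder/generator phase
(E, G₁, G₂ updated on L_total with discriminators frozen), one Adam
optimiser per phase. Gradients are clipped to global L2 norm 1.0 after
adding classic L2 weight decay (default 1e-5); learning rate 1e-4, 100
epochs, batch 64 by default. The three triplet roles are stacked into one
(3N × ·) batch per network call; role-wise loss terms are taken on slices,
which is exact because the roles share a batch size. The ablation variants
are `notCL` (contrastive coefficient zero — CycleGAN feedback only; L_con is
still logged) and `RC` (no CycleGAN — pure contrastive training).

Cross-validation uses stratified k-folds (classes are imbalanced in the
intended cohorts); "repeated with different seeds" is implemented as seeds
seed+0 … seed+r−1, each with its own partition, and all k×r fold results
pooled into mean ± sd. Categorical encodings (sorted-level ordinal) and
z-scoring (population sd; zero-variance features map to zeros, keeping n_x
stable) are fitted on each training fold only and applied to the held-out
fold.

## Implementation

All networks are pure functions of nested dicts of numpy arrays,
differentiated end-to-end with `autograd`; Adam, clipping and the two-phase
schedule are implemented in `training.py`. This keeps every forward path
replayable and bitwise deterministic given a seed: identical seed, config
and data reproduce identical loss histories and metrics tables. All
randomness flows through explicitly injected `numpy.random.Generator`
streams; there is no global RNG state.

## Synthetic data

The generator is a linear-Gaussian factor model. Each class c has a factor
mean μ_c on its own orthogonal axis with pairwise distance exactly
`class_separation`; each sample draws a shared factor f ~ N(μ_c, I) in
`latent_factor_dim` dimensions. Modality m observes
x_m = s·(f·A_m) + (1−s)·(g_m·B_m) + ε, with fixed random loadings A_m, B_m
(entries N(0, 1/d_f)), a modality-private factor g_m ~ N(0, I),
s = `shared_signal_fraction`, and ε ~ N(0, noise_sd²). s = 1 makes
modalities redundant; s = 0 makes them conditionally independent given the
class — the regime in which integration genuinely beats any single layer. A
`categorical_fraction` of columns is discretised into loss/neutral/gain by
per-column tertiles, mimicking CNV-style coding and exercising the
categorical-encoding path.

The fixed benchmark (`generate_easy_benchmark`) uses 3 balanced classes of
60, modalities of 120/90/60 features, d_f = 8, separation 4.0, s = 0.5,
noise 1.0, 10% categorical columns. At these settings the problem is
demanding but solvable: logistic regression on the raw concatenated features
reaches ≈0.92 held-out accuracy, a 15-tree Random Forest on raw features
≈0.78, and PCA(95%)+RF ≈0.64 — so good latent-space scores require genuine
signal concentration, not merely preserved separability. What this fixture
does **not** emulate: real TCGA marginal distributions (heavy tails,
zero-inflation), batch effects, missingness, or nonlinear class boundaries;
passing results show the machinery learns and generalises the structure it
was built for, not clinical performance.

## Desk-scale benchmark recipe

The reduced configuration used by the test suite and the acceptance script
(frozen after calibration on a single development split, seed 0, and then
validated on seeds 0–2): encoder 2 blocks / 2 heads / embed 64 / latent 16;
30 epochs, batch 32; Adam lr 1e-3; triplets_per_anchor 4; n_swap 2;
m = 1, α = 3e-4, β = 0.1; GAN channels (8, 16, 8), grid 16; RF with 15
trees on one stratified 80/20 split per seed (the test suite runs every
variant and every modality subset at three seeds; the acceptance script runs
the single-modality arm at one seed to stay within a desk-scale runtime).
Three choices depart from the
package defaults, each for a reason stated above: lr (the default 1e-4 is
matched to a schedule several times longer — at ~600 steps it moves
parameters by about one percent and the encoder stays near its
initialisation), α (sum-form cycle loss scaling), and n_swap (M = 3
dilution).

## Numerical choices and degenerate inputs

* Attention uses max-shifted softmax; weights are checked to sum to 1 within
  1e-6 in the test suite.
* Switch Normalization adds ε = 1e-5 inside every square root.
* Batch-of-one training batches fall back to BN running statistics.
* Zero-variance features z-score to zeros (sd recorded as 0) rather than
  being dropped.
* Unseen categorical levels at transform time raise, naming column and
  level.
* A non-finite loss component aborts training with the component named.
* Checkpoints store all four networks, configs and BN running statistics in
  one container; loading restores bit-identical encodings.

## Known limitations

* The adversarial/cycle feedback helps modestly at desk scale (≈ +0.03
  accuracy over the pure contrastive ablation on the benchmark); its value
  on real cohorts is not established by this package.
* `autograd` on one CPU limits practical model sizes; the default
  (8 × 1024) encoder is functional but slow to train at realistic n_x.
* Hinge-GAN training is stabilised only by gradient clipping and the
  two-phase schedule; no spectral normalisation or gradient penalties.
* The F1 reported is macro-averaged; classes absent from both truth and
  prediction in a fold contribute 0, a conservative convention.
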