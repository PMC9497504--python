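# Methods

## Model and procedure

`asymcl` studies supervised contrastive representation learning under
class imbalance. A batch of samples is mapped to l2-normalized embeddings
z₁,…,zₙ; the pair probability p_ij (softmax over cosine similarities at
temperature τ, excluding self-similarity) estimates whether anchor i and
sample j share a class. The implemented loss family is

    L = −Σᵢ (Lᵢ⁺ + η Lᵢ⁻),
    Lᵢ⁺ = (1/|Pᵢ|) Σ_{j∈Pᵢ} (1 − p_ij)^γ log p_ij,
    Lᵢ⁻ = (1/|Nᵢ|) Σ_{j∈Nᵢ} log(1 − p_ij),

with CL (η=0, γ=0), FCL (η=0, γ=1) and ACL (γ=0) as special cases sharing
one code path, so the algebraic reductions hold exactly in floating
point. The rationale for the asymmetric negative term: under heavy
imbalance a minority anchor frequently has an empty positive set Pᵢ and
contributes nothing to CL; the η-weighted negative term restores its
influence by pushing it away from majority samples. The focusing exponent
is applied to the positive term only — p_ij is of order 1/(n−1) in large
batches, so a (p_ij)^γ factor on the negative term would extinguish it;
for the same reason useful η values are large (order 10–300 at batch
size 128).

Training is two-stage: (1) encoder + two-layer projection head minimise
the contrastive loss on l2-normalized projections; (2) the encoder is
frozen (verified bit-identical via a SHA-256 parameter hash), the
projection head is discarded, and a single affine map to two softmax
logits is fitted with cross-entropy or focal loss
(−y(1−p)^γ log p − (1−y)p^γ log(1−p)). Decisions are argmax over logits.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| τ | softmax temperature on cosine similarities | 0.07 | standard default for supervised contrastive training |
| η | weight of the negative-pair term | 0 (CL-like) | canonical grid {0, 60, 120, 180, 240, 300} |
| γ (contrastive) | focusing exponent on positives | 0 | canonical grid {0, 1, 2, 4, 7, 10} |
| γ (classifier FL) | focusing exponent, fine-tuning | 2 | typical focal-loss setting |
| learning rate / batch | Adam step, mini-batch size | 1e-2 / 128 | the reference training protocol |
| epochs stage 1 / 2 | representation / classifier epochs | 20 / 10 | protocol for a small encoder; tests and desk-scale runs use 10 / 5 |
| reduction | `mean` over anchors vs literal `sum` | `mean` | decouples learning rate from batch size; oracle tests use `sum` |

Encoders are pluggable behind a forward/backward contract; the built-ins
are a tiny MLP (input→32→32 features) and a tiny CNN (3×3 conv, 8 maps,
mean-pool, linear) written in NumPy. Projection presets (512, 128) and
(2048, 128) mirror the shapes used with deep residual encoders; the desk
default is (32, 16).

## Synthetic data

The generator emulates imbalance scenarios 50:50 … 98:2 with an explicit
Bayes-error knob rather than mimicking any real image corpus. Feature
mode: two isotropic Gaussians in `dims` dimensions, centers `signal`
apart along a seeded random direction (signal 2.0 → d′=2, per-class Bayes
error ≈ 16%, so minority recall is genuinely hard at 95:5). Image mode:
class-specific Gaussian blobs in opposite quadrants plus pixel noise of
s.d. 1/signal, clipped to [0, 1]; optional random flip/rotation
augmentation. Splits are 70/30 and stratified — unstratified splitting at
98:2 can leave no minority test sample, making UWA undefined.

What passing tests show, and don't: the generators expose imbalance with
controllable separability, but they are unimodal, noise-isotropic and
free of label noise, intra-class structure and domain shift. Results here
demonstrate the losses' mechanics and their directional effect on UWA
under imbalance, not performance on natural images.

## Numerical choices

- p_ij via max-shifted exponents; log p_ij taken from the log-softmax
  directly, never log of a stored probability.
- log(1 − p_ij) as log1p(−p) with p clamped at 1 − 1e-12; the clamp is the
  defined contract at the singular point (e.g. an n=2 negative pair, where
  p = 1 exactly).
- Self-similarities masked to −∞ *before* the max shift, so the diagonal
  has exactly zero probability mass.
- (1 − p)^γ uses the convention 0⁰ = 1, so AFCL(γ=0) is exactly ACL.
- Empty Pᵢ: the anchor's positive term is 0 (for CL/FCL this means the
  anchor is skipped; an all-singleton batch yields loss 0 with a runtime
  warning); its negative term is still computed in ACL/AFCL. Empty Nᵢ
  (single-class batch): negative term 0.
- Gradients are analytic (softmax Jacobian row-wise, then symmetrised
  through zᵢ·z_j), including backprop through the l2 normalization; all
  are tested against central finite differences at 1e-4 relative
  tolerance.
- Training-loop normalization clamps the projection norm at 1e-12: a
  sample whose ReLU units are all inactive projects to the exact origin,
  and the clamp lets such transient rows pass through with zero gradient
  instead of aborting the fit. The public `l2_normalize`/`FeatureBatch`
  API remains strict (zero rows are errors). Dense biases get a small
  random init to make dead projections rare.
- Classifier probabilities are clamped to [1e-12, 1 − 1e-12] before logs,
  so maximally wrong predictions give large finite losses.
- Determinism: every source of randomness (init, shuffling, data) derives
  from `numpy.random.default_rng(seed)`; fixed seeds reproduce loss
  trajectories exactly on a given platform. Sweep cells use the documented
  derivation `seed = (base·1000003 + cell·8191 + run·131 + 17) mod 2³¹`
  so individual cells can be re-run.

## Design choices

- The classification head is a single affine map to 2 logits with bias
  and no hidden activation; binary probabilities come from the 2-way
  softmax.
- Stage 2 re-uses the stated learning rate 1e-2 (no separate rate is
  defined for fine-tuning). Because encoder features are not normalized,
  stage-2 convergence depends on the number of Adam steps; the defaults
  (10 epochs) are comfortable, very short schedules on very small
  datasets may underfit the head.
- Image augmentations are resampled fresh every epoch when enabled.
- Mean-over-anchors is the default loss reduction for training; all
  oracle comparisons use the literal anchor sum.
- Desk-scale problem sizes throughout (n ≈ 10²–10³ samples, 16-d features,
  ≤ 10+5 epochs, 5 repeated seeds) keep every experiment reproducible on
  one CPU in seconds while preserving the imbalance phenomena of
  interest.

## Limitations

- Binary classification only; no multi-class heads.
- NumPy encoders are intentionally tiny; deep residual encoders can be
  plugged in behind the same contract but are out of scope here.
- The 95:5 directional experiment is stochastic: AFCL's UWA advantage
  over CL is asserted as a ≥-within-one-standard-error trend over seeds,
  not per-run dominance — mirroring the run-averaged character of the
  underlying claim.
- UWA is undefined on single-class test sets and raised as an error, by
  design.
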