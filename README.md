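# asymcl — asymmetric contrastive losses for imbalanced classification

`asymcl` is a library and CLI for studying how supervised contrastive
losses behave on class-imbalanced binary datasets (the motivating setting
is medical image classification, e.g. rare skin-lesion categories, where a
model that never predicts the minority class still scores high accuracy).

## The losses

Given a mini-batch of samples embedded as l2-normalized vectors
z₁,…,zₙ with class labels y₁,…,yₙ, the probability that anchor i and
sample j share a class is a temperature-scaled softmax over cosine
similarities:

    p_ij = exp(zᵢ·z_j / τ) / Σ_{k≠i} exp(zᵢ·z_k / τ)

With Pᵢ = same-class partners of anchor i and Nᵢ the rest, the package
implements one two-parameter family

    L = −Σᵢ ( Lᵢ⁺ + η·Lᵢ⁻ )
    Lᵢ⁺ = (1/|Pᵢ|) Σ_{j∈Pᵢ} (1 − p_ij)^γ log p_ij
    Lᵢ⁻ = (1/|Nᵢ|) Σ_{j∈Nᵢ} log(1 − p_ij)

whose special cases are the supervised **contrastive loss** (CL: η=0, γ=0),
the **focal contrastive loss** (FCL: η=0, γ=1), the **asymmetric
contrastive loss** (ACL: γ=0) and the **asymmetric focal contrastive loss**
(AFCL: the full family). The negative term is what lets a minority-class
anchor with *no* positive partner in the batch still shape the
representation; the focusing exponent γ down-weights easy positive pairs.

Training follows a two-stage recipe: (1) fit an encoder + projection head
with one of these losses; (2) freeze the encoder, drop the projection
head, and fit a one-layer softmax classifier with cross-entropy or focal
loss. Evaluation reports plain accuracy and **unweighted accuracy** (UWA,
the mean of per-class recalls): a majority-only predictor on a 90:10 test
set gets accuracy 0.90 but UWA 0.50, so the pair of metrics exposes
majority bias. All losses, gradients and the tiny MLP/CNN encoders are
implemented in NumPy with analytic backpropagation, verified against
finite differences.

## Worked example

Train AFCL (η=300, γ=7) on a synthetic 95:5 two-class Gaussian dataset
(n=1000, 16-d, class centers 2σ apart, 70/30 stratified split):

```python
from asymcl import (ScenarioSpec, generate, TwoStageClassifier,
                    TwoStageConfig, ContrastiveConfig)

ds = generate(ScenarioSpec(n_total=1000, majority_fraction=0.95,
                           seed=0, signal=2.0, dims=16))
cfg = TwoStageConfig(contrastive=ContrastiveConfig("afcl", eta=300.0, gamma=7.0),
                     epochs_stage1=10, epochs_stage2=5, seed=0)
res = TwoStageClassifier(ds, cfg).fit()
print(res.summary())
```

prints

```
Two-stage contrastive classifier
========================================
contrastive loss      AFCL  (tau=0.07, eta=300.0, gamma=7.0)
classifier loss       CE
encoder               mlp -> 32-d features
projection head       (32, 16)
epochs (stage 1 / 2)  10 / 5
stage-1 loss          7.0668 -> 4.8124
stage-2 loss          0.2906 -> 0.1182
----------------------------------------
test confusion        TP=4 TN=280 FP=5 FN=11
test accuracy         94.67%
test UWA              62.46%
```

The stage losses fall across epochs; accuracy is dominated by the 285
majority test samples while UWA shows how much minority recall the
representation actually supports (4 of 15 minority samples recovered here
— well above the 50% UWA of a majority-only predictor).

The same experiment from the shell:

```sh
asymcl generate --scenario 95:5 --n-total 1000 --out clouds.csv
asymcl train --data clouds.csv --loss afcl --eta 300 --gamma 7 \
             --epochs-stage1 10 --epochs-stage2 5 --seed 0
asymcl sweep --scenario 90:10 --vary eta --runs 4 --outdir sweep_out
```

`sweep` reproduces the protocol shape of the reference experiments:
per-cell repeated runs over an η grid {0, 60, 120, 180, 240, 300} (or a γ
grid {0, 1, 2, 4, 7, 10}) with deterministically derived seeds, reported
as mean accuracy / UWA in percent.

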