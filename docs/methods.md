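# Methods

## Model

A network with weight matrices `W_i` (biases folded in as a last row with a
fixed input of one) is given the Bernoulli variational posterior
`W_i = Θ_i ⊙ Z_i`, `Z_i ~ Bernoulli(p_i)` elementwise. Minimising the
negative evidence lower bound under this family reduces, with the KL term
approximated by an L2 penalty, to ordinary DropConnect training:

```
L(Θ) = (1/N) Σ_n CE(y_n, ŷ(x_n, Θ⊙Z_n)) + λ Σ_i ‖Θ_i‖²
```

optimised here by minibatch SGD with momentum 0.9 and one fresh mask
configuration per step (the single-sample Monte Carlo estimate of the
expected log likelihood). At test time the masks stay active; `T`
stochastic softmax passes are averaged into the posterior predictive, whose
argmax is the prediction. Unit-level masking (Dropout) is retained as the
baseline arm: identical architectures, masks on output units instead of
weights.

Per item the package reports predictive entropy (total), mutual information
between prediction and weights (epistemic: `Ĥ` minus mean per-sample
entropy, clamped at 0), and `I_norm`, the min–max normalisation of MI over
the evaluation set. MI — not entropy — drives all downstream decisions: a
sample on which every posterior draw agrees on a flat distribution is noisy
but *known* to be noisy (aleatoric), and flagging it would not catch model
failure. Natural log is used throughout; `I_norm` and therefore all
threshold metrics are invariant to the log base.

## Key parameters

| parameter | default | rationale |
| --- | --- | --- |
| keep probability `p` | 0.5 | the standard rate for both DropConnect and Dropout arms; applied to every weight layer of the classifiers |
| MC passes `T` | 100 | model-averaging budget at which the predictive mean and MI have stabilised (the convergence analysis typically shows the MC error beating the deterministic test within a few tens of passes) |
| weight decay `λ` | 1e-4 | the KL-derived L2 strength; small because the miniatures are far from overparameterised |
| threshold grid | 101 points on [0,1] | AUC changes by <0.5% against a 1001-point grid |
| referral baseline | 20 random samplings | matches the reported mean ± std convention |
| convergence repetitions | 10 | matches the reported averaging convention |

### Inverse-p scaling

With `scale_by_inverse_p=True` (default) kept weights are multiplied by
`1/p`, so the all-ones deterministic pass equals the expected stochastic
activation — the reparametrisation `Θ' = Θ/p` of the literal model. With it
off, the deterministic pass uses the raw trained weights ("keep everything
in place"). Both are supported; the choice moves the deterministic baseline
but not the Bayesian machinery.

### Boundary and tie conventions

* `i_norm == I_T` counts as **uncertain** (the defining inequalities are
  strict; ties go to the safe side).
* 0/0 ratios are stored as NaN. For AUC integration the undefined head of
  `R_cc` and tail of `R_iu` are filled with 1 — vacuous regions contain no
  incorrect-certain cases — and the fill is recorded in curve metadata.
* Argmax ties break to the lowest class index; percentile and referral cuts
  use stable sorts (lowest index first); retained counts are `⌈f·N⌉`.
* Threshold selection returns the midpoint of the first plateau of
  grid-maximal objective values.
* Probabilities are clamped at 1e-12 inside logarithms; the training loss
  uses log-softmax directly so loss and gradient stay consistent even for
  saturated logits.
* The min–max normaliser can be frozen on a validation set and applied to
  test data (values clipped to [0,1]) for the referral workflow.

## Synthetic study conditions

**Classification.** Three unit-variance Gaussian classes with means on
orthogonal axes of an 8-dimensional space at pairwise distance 2.8; 2,000
samples (1,000 train / 1,000 test), balanced to ±1. The Bayes error, known
by construction and checked by Monte Carlo integration of the true
densities, is ≈14%, so misclassifications are guaranteed. The ambient
dimension matters: in a low-dimensional, densely sampled task nearly all
residual error is aleatoric — every posterior draw agrees on the flat
regions — and MI would have (correctly) almost nothing to say about errors.
Out-of-distribution probes sit on a sphere at twice the in-distribution
extent; each probe is farther from every class mean than the 99th
percentile of in-distribution points. Classifier: MLP 8→64→64→3, all
layers masked at p=0.5, 80 epochs of SGD (lr 0.01, batch 64, momentum 0.9).

**Segmentation.** 24×24 scenes with background, a disk, a rectangle and a
3×3 rare object (<2% of pixels by construction) at stepped intensities,
pixel noise σ=0.25 and ±1 px boundary jitter applied to the shape
parameters before rendering (so images and masks stay consistent); 24
training and 8 test scenes. Segmenter: a small encoder–decoder
(conv–conv–pool–conv–upsample–conv–conv). Masking every layer of so small
a network at p=0.5 regularises it into predicting the dominant background
class everywhere, so the default placement masks the central
bottleneck/decoder convolutions only — the placement used for Bayesian
encoder–decoder segmenters, where the drop layers occupy the same central
part of the network in both the DropConnect and Dropout arms.
`stochastic="all"` is available. Evaluation uses T=50.

All randomness descends from one root seed split into named streams (data,
init, training masks, MC masks, shuffling); reruns are bit-identical.

## What the synthetic tasks do and do not show

They emulate: class overlap producing genuine misclassifications, a known
Bayes floor, out-of-distribution inputs, class-frequency imbalance with a
rare class, ambiguous object boundaries. They do not emulate: natural-image
texture, label noise, realistic covariate shift, or anything about scale.
Passing behavioural tests therefore demonstrates that the machinery orders
its own uncertainties correctly under controlled conditions — higher MI on
errors, on OOD probes and on rare classes; accuracy gains from referral —
not that any particular clinical model would behave the same way.

Behavioural properties are asserted as seeded majorities (≥18 of 20 seeds)
because each is a stochastic event per run; the MC variance-scaling check
asserts `var(T=64) ≤ var(T=4)/4` against an expected ratio of 1/16,
leaving a factor-4 margin for estimation noise in a 30-repetition variance.

## Numerical and degenerate cases

`keep_prob=1` is exactly deterministic (masks all ones, scale 1) and is the
reference point for the determinism tests. Zero-covariance blob classes
(point masses) are valid — the noiseless limit used in learnability checks —
while non-symmetric or indefinite covariances are rejected. An empty
retained set in referral, an all-ignored segmentation batch, and 0/0 ratio
denominators are surfaced as NaN markers or typed errors, never silently
filled. Training aborts with the loss trace attached if the objective goes
non-finite.

## Known limitations

* The miniatures are NumPy networks built for clarity and reproducibility,
  not speed; they are deliberately three orders of magnitude smaller than
  production segmentation models.
* MI estimated from T samples is biased upward at small T; comparisons
  always use a common T.
* The segmenter's central-mask placement means its first/last convolutions
  carry no posterior spread; epistemic uncertainty is accordingly attributed
  to the bottleneck features.
* Per-dataset normalisation makes `I_norm` relative: thresholds tuned on one
  set transfer only through the frozen-normaliser mode.
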