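# Methods

This note documents the models, numerical choices and limitations of
`retikan`.  It is the package's own account; every empirical number quoted
here is produced by the test suite or `scripts/acceptance.py`.

## Synthetic fundus images

The generator emulates the visual vocabulary a retinopathy grader uses, not
photorealism.  Each image is a dark circular retinal field with a radial
vignette over a black camera surround, one bright optic disc (radius
6.2–6.7% of the side), 3–8 curvilinear vessel strokes radiating from the
disc, and grade-dependent lesions:

| lesion | appearance | expected count at grade g |
|---|---|---|
| microaneurysm | small dark-red dot, r 1.5–3 px | Poisson(3·g) |
| hemorrhage | irregular red blotch, r 4–8 px | Poisson(2·max(0, g−1)) |
| exudate | yellow-white deposit, r 4.5–8.5 px | Poisson(2·max(0, g−1)) |
| neovascular tuft | fine vessel curls near the disc | Poisson(3) at grade 4 only |

Rates are zero at grade 0 and non-decreasing in grade, giving a monotone
severity signal; radii are stated at the 224-pixel reference size and scale
linearly.  Exudate size was chosen so that a one-dimensional threshold on
bright-lesion area separates grade 0 from grade 4 with >95% accuracy — the
design requirement that guarantees the downstream task is learnable.
Residual overlap comes from the Poisson low tail (a grade-4 eye drawing 0–1
exudates), which is also clinically the hard case.

Class composition can reproduce the EyePACS-style screening imbalance
(≈73/7/15/2.5/2% for grades 0–4) by largest-remainder apportionment of any
total.  What the generator does **not** model: camera optics and
vignetting variation between devices, media opacity, inter-grader label
noise, and lesion co-location statistics.  Passing tests therefore show the
pipeline can extract and rank a monotone lesion signal under class
imbalance — not clinical performance.

## Preprocessing

CLAHE is applied to the BT.601 luminance only, with chroma rescaled
multiplicatively, so hue (the lesion color cue) is preserved.  The
`clip_limit` follows the common convention (2.0 default, 8×8 tiles) and is
mapped internally to the histogram-fraction convention of
scikit-image (`clip/100`).  A constant-luminance image is returned
unchanged: equalizing a single-spike histogram is defined as the identity.
Pixels are then rescaled x ↦ 2x − 1 into [−1, 1]; a guard refuses to
normalize twice.  Augmentation (rotation ±15°, flips with probability 0.5,
scale 0.9–1.1, translation ±5%, brightness ±0.1, contrast and saturation
0.9–1.1) fills exposed borders with the darkest corner value, mimicking the
black surround, and never touches the grade label.

## Feature extractor and the frozen-weights regime

The backbone is a toy-scale ShuffleNet-V2-style stack — stride-2 stem, three
stages of shuffle units with repeats 2/4/2 (stage channels 32/64/128 scaled
by the width multiplier), total stride 16 — followed by one LeViT-style
attention block (LayerNorm → multi-head self-attention → residual →
feed-forward → residual) on the 14×14 token grid and a linear projection
fixing 256 output channels for every width.

The package trains only the cKAN head; backbone weights stay at a seeded He
initialization.  This random-feature regime is what makes a full
hyperparameter search affordable on one CPU, and it preserves the search
problem's structure (width, kernel, embedding and dropout all change the
candidate's features and FLOPs).  One numerical choice matters a great
deal here: activations are **RMS-normalized** per channel (division by the
spatial root-mean-square, no mean subtraction).  Mean-subtracting instance
normalization would zero every channel's spatial mean, so the global
average pool of the output would be identically zero and no "how much
lesion" statistic could survive the stack; RMS scaling keeps depth-wise
stability while letting pooled first moments through.

Parameter and FLOP counts are analytic, computed from the same layer plan
that builds the weights (convolution: `2·Hout·Wout·Cout·K²·Cin/groups`;
attention: QKV/output projections plus the two N×N matmuls; 1 MAC = 2
FLOPs; normalizations and activations are not counted).

## cKAN head

Stage 2's function bank is a clamped cubic B-spline per channel: 8 uniform
breakpoints on [−2, 2], clamped knot vector, 10 basis functions, evaluated
by a vectorized Cox–de Boor triangular recursion (an independent scalar
recursion and scipy's design matrix serve as test oracles).  Inputs are
batch-normalized before the spline so activations live inside the knot
span; outside it the spline extrapolates by its boundary value, with zero
gradient through the clamp.  Coefficients initialize to the Greville
abscissae (the identity function), the depthwise kernel to a centre delta
with small noise — the untrained head is a benign near-linear map.

Training minimizes cross-entropy plus `λ(μ₁·mean|φ| + μ₂·S(φ))`, with S the
Shannon entropy of each bank's normalized absolute coefficients (0·log 0 = 0)
averaged over banks — the standard KAN sparsity penalty.  Defaults:
λ = 1e−4, μ₁ = μ₂ = 1, dropout 0.3 on the pooled descriptor, Adam at 1e−3,
batch 16, early stopping on validation loss (patience restores the best
epoch).  All gradients are hand-derived; the test suite checks every
parameter group against central finite differences at 1e−4 relative
tolerance on a float64 micro-instance.  The head's 70,021 parameters
compare with 250,885 for a flatten-plus-linear head on the same
14×14×256 input.

## Improved Whale Optimization

Positions live in a box; categorical menus are relaxed to `[0, |menu|)` and
decoded by floor, log-scaled dimensions move in log10 units.  The improved
update keeps the three vanilla moves and adds: tent-map chaotic
initialization (split point 0.7, fixed points perturbed), the nonlinear
convergence factor `a(t) = 2 − 2(e^{(t/tmax)^m} − 1)/(e − 1)`, the cosine
inertia weight `|cos(l·t·π/tmax)|` multiplying the move's base vector, a
Cauchy mutant of the best position recombined coordinate-wise
(binomial crossover with one forced index; step = `scale·(ub−lb)·Cauchy`),
and an optimal-based feedback blend applied to the worst 20% of whales.

Ambiguities resolved as follows: the spiral branch fires at p ≥ 0.5 (the
printed condition would make it dead code); the |A| branch test uses the
mean of the coefficient vector's absolute values; when mutation is disabled
the move's base vector is the branch's own target, which makes the update
*exactly* vanilla WOA — verified step-for-step against an independently
coded reference on a shared random stream.  The exploration/exploitation
semantics follow standard WOA (|A| ≥ 1 moves toward a random whale).

Defaults were fixed by benchmarking convergence on the sphere and Rastrigin
test functions during design: `m = 0.5` (early decay of a, longer
exploitation), `l_cycle = 1`, `b = 1`, `cauchy_scale = 0.1` (the scale the
mutation literature uses), `crossover_rate = 0.1`, feedback threshold 0.5
on the worst 20%.  With population 20 and 50 iterations the median final
sphere-10D objective over 20 seeds is ~2e−4.  On 2-D Rastrigin both IWO and
vanilla WOA reach ≈1e−2 of the optimum at this budget; the vanilla spiral
alone is already sufficient there, so the improved variant's advantage is
not uniform — the suite logs both medians and asserts agreement within a
small absolute slack.  A run costs exactly `P·(tmax+1)` objective
evaluations; a NaN objective is treated as +∞ with a warning.

## Search, fitness and problem sizes

Candidate fitness is `α(1 − ValAccuracy) + β·ValLoss + γ·FLOPs/FLOPs_max`
with accuracy-dominant defaults α = 0.6, β = 0.3, γ = 0.1 and `FLOPs_max`
the analytic count of the largest configuration in the space.  Top-1
validation accuracy is used (switchable to any metric by wrapping the
objective).  The batch-size menu is {16, 32}.

Problem sizes are deliberate scale reductions chosen so the whole study
runs on one CPU: candidate evaluation trains the head for 2 epochs on 120
balanced 64-pixel images (the backbone grid is then 4×4; the head is
grid-agnostic), the toy search uses population 6 × 10 iterations (66
evaluations), and the headline cross-validation uses 500 images at 224
pixels with the screening-cohort imbalance, 3-epoch head training and one
augmented copy per training image.  These sizes are also what
`scripts/acceptance.py` reports.

## Evaluation protocol

Stratified five-fold assignment deals each class's shuffled members
round-robin to folds (rotating starting fold per class), which guarantees
every fold holds ⌊n_c/5⌋ or ⌈n_c/5⌉ test samples of class c.  Within each
fold iteration the non-test samples are split 90/10 per class into train
and validation.  Augmentation applies to training folds only; the harness
raises if a test-fold id ever reaches an augmented batch.

Metrics follow the standard confusion-matrix formulas with one-vs-rest
reduction per grade and unweighted macro averaging; per-class "accuracy" is
one-vs-rest binary accuracy.  Multiclass kappa uses the full 5×5 matrix
with marginal-product expected agreement.  Zero denominators yield 0
(precision, recall, MCC) — a safe convention that only degenerate folds
exercise.  AUROC is the Mann–Whitney statistic with ties counted ½; AUPRC
is step-wise precision–recall integration; a class absent from the test
labels is reported as NaN and flagged, never as 0.  Fold summaries are
mean, sample SD (n−1) and the Student-t 95% CI half-width
`t₀.₉₇₅,k−₁·SD/√k`.

## Reproducibility

A single global seed fans out to per-stage child seeds through
`SeedSequence(entropy=seed, spawn_key=(stage,))`, all below 2³¹, so any
stage can be rerun in isolation.  Dataset manifests record each image's
child seed.  Backbone forward passes, head training, augmentation and the
optimizer are bit-reproducible given their seeds; dropout draws come from
the training generator only, so inference is deterministic.

## Known limitations

- The backbone is never trained end-to-end; reported accuracies reflect the
  random-feature regime, a deliberate desk-scale choice.
- The synthetic task is far easier than real fundus grading; adjacent-grade
  confusion (1 vs 2, 2 vs 3) dominates the residual error, as the lesion
  rates differ only by Poisson means.
- Rare grades (13 and 10 images of grades 3 and 4 in the 500-image study)
  make per-fold minority recall noisy; kappa and macro-F1 carry most of the
  information about minority performance.
- FLOP counts omit normalizations, activations and softmax (<1% of the
  total under the stated convention).
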