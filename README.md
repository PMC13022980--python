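# retikan

Desk-scale toolkit for diabetic-retinopathy (DR) severity grading:
a whale-optimized hybrid CNN/attention feature extractor feeding a
**convolutional Kolmogorov–Arnold (cKAN) classification head**, exercised
end-to-end on synthetically generated graded fundus images.  Everything runs
on one CPU with no downloads; the synthetic generator stands in for a real
screening cohort so that every stage — preprocessing, feature extraction,
hyperparameter search, training, and evaluation — is fully testable.

## Who this is for

Researchers and engineers who want a small, inspectable, pure-numpy
implementation of the cKAN grading pipeline: the spline function bank and
its analytic gradients, the Improved Whale Optimization (IWO) metaheuristic
with chaotic initialization and Cauchy mutation, the FLOPs-aware composite
search fitness, and the stratified five-fold evaluation protocol with the
full metric battery (accuracy, precision, recall, F1, MCC, Cohen's kappa,
AUROC/AUPRC).

## The model

**Preprocessing.** CLAHE on the luminance channel (hue-preserving), then a
linear rescale of pixels to [−1, 1].  Training folds receive label-preserving
augmentation (rotations within ±15°, flips, scaling, translation, photometric
jitter); validation and test folds are never augmented.

**Feature extractor.** A ShuffleNet-V2-style stack (stride-2 stem, shuffle
units with repeats 2/4/2, total stride 16) followed by one LeViT-style
multi-head self-attention block over the 14×14 token grid and a projection to
256 channels: `Z ∈ ℝ^{B×14×14×256}`.  Weights are frozen at a seeded He
initialization (random-feature regime); only the head is trained.

**cKAN head.** Five stages:

| stage | operation | tensor |
|---|---|---|
| 1 | channel condenser (1×1 conv) | B×14×14×128 |
| 2 | depthwise conv + per-channel cubic B-spline (order 3, 8 knots) | B×14×14×128 |
| 3 | superposition mixer (1×1 conv) | B×14×14×256 |
| 4 | global average pooling | B×256 |
| 5 | linear + softmax | B×5 |

Training minimizes `CE + λ(μ₁·L1(φ) + μ₂·S(φ))`, where `φ` are the spline
coefficients and `S` the entropy of their normalized magnitudes, with Adam,
dropout 0.3 and early stopping.  All gradients are analytic numpy.

**IWO search.**  Candidates (learning rate, weight decay, batch size, width
multiplier, depthwise kernel, embedding dim, heads, attention dropout) are
scored by

```
F = α(1 − ValAccuracy) + β·ValLoss + γ·FLOPs/FLOPs_max
```

and minimized by whale optimization improved with a tent-map chaotic
population, the nonlinear convergence factor
`a(t) = 2 − 2(e^{(t/tmax)^m} − 1)/(e − 1)`, a cosine inertia weight
`|cos(l t π/tmax)|`, Cauchy mutation of the best position, and an
optimal-based feedback move.

## Worked example

```python
import numpy as np
from retikan.pipeline import RunConfig, run_end_to_end
from retikan.synthetic import DatasetSpec, scaled_class_counts

cfg = RunConfig(
    dataset=DatasetSpec(n_images=500, class_counts=scaled_class_counts(500)),
    seed=1, out_dir="runs/demo")
report = run_end_to_end(cfg)
for name, s in report.summary.items():
    print(f"{name}: {s['mean']:.3f} +/- {s['ci95_half_width']:.3f}")
```

Output from this exact run:

```
overall_accuracy: 0.758 +/- 0.052
macro_accuracy: 0.903 +/- 0.021
macro_f1: 0.293 +/- 0.093
kappa: 0.325 +/- 0.093
```

`overall_accuracy` is plain top-1 accuracy over the five grades on the held-out
test folds (majority class alone would give 0.734 under the cohort's
imbalance); `macro_accuracy` averages the five one-vs-rest binary accuracies;
`kappa` is the chance-corrected multiclass agreement — values well above 0
show the grader has learned severity signal beyond the class prior.  The same
pipeline is scriptable from the shell:

```bash
retikan run-all --seed 1 --out runs/demo
retikan search --seed 0 --out runs/search     # toy IWO search
```

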