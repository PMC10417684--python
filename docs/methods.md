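# Methods

This note records the model, the choices that were genuinely open, the
numerical conventions, and what the synthetic fixture does and does not show.

## Dung beetle optimizer

The optimizer minimizes a black-box objective over a box. The population is
partitioned once, at startup, into four fixed roles — by default 6 rollers,
6 brood balls, 7 foragers and 11 thieves for a population of 30 (scaled by
largest-remainder apportionment for other sizes). Update rules per iteration
*t* (of *Tmax*), with *R = 1 − t/Tmax*:

* **Roller** (obstacle-free): `x' = x + α·k·x_prev + b·|x − x_worst|`, with
  flexure coefficient `k ∈ (0, 0.2]` (default 0.1), `b = 0.3`, and `α`
  resampled each iteration as ±1 with equal probability. With probability
  0.1 the roller instead meets an obstacle and dances:
  `x' = x + tan(θ)·|x − x_prev|`, `θ ~ U[0, π]`; at θ exactly 0, π/2 or π the
  position is unchanged.
* **Brood ball**: confined to the spawning region
  `[max(g·(1−R), L), min(g·(1+R), U)]` anchored at the global best `g`;
  update `B' = g + b₁∘(B − L*) + b₂∘(B − U*)` with `b₁, b₂ ~ U[0,1]^D`,
  clipped into the region.
* **Forager**: same shrinking construction anchored at the current
  population best; `x' = x + C₁·(x − L*) + C₂∘(x − U*)` with scalar
  `C₁ ~ N(0,1)` and `C₂ ~ U[0,1]^D`.
* **Thief**: `x' = x_lbest + S·g∘(|x − x_gbest| + |x − x_lbest|)`,
  `g ~ N(0,1)^D`, `S = 0.5`.

Open choices and how they were resolved:

* The thief rule is printed ambiguously in common descriptions (grouping and
  absolute-value bars); the form above follows the original optimizer's
  formulation and is the one implemented.
* When the anchor has negative components the naive shrinking interval can
  invert (lower > upper); the two endpoints are swapped and clipped into the
  global box, preserving a valid interval without discarding the shrinkage.
* Selection is unconditional replacement with best-ever tracking, so the
  best-so-far trace is monotone by construction. `x_lbest` is the best
  position of the population at the start of the iteration; `x_gbest` is the
  best ever observed.
* Positions are clipped (not reflected) to bounds after every update;
  `x_prev` is initialized equal to the initial positions so the `k·x_prev`
  term is defined at the first step.
* Randomness flows from one seed through five named substreams
  (initialization + one per role), so results are bit-reproducible and
  stable under role-count changes.
* A non-finite objective value marks the candidate with +∞ fitness and a log
  warning rather than aborting the run.

On the 5-D sphere (population 30, 200 iterations) the median best fitness
over 20 seeds is far below 1e-4 and the optimizer beats uniform random search
at an equal evaluation budget on essentially every seed; the test suite and
acceptance script recompute both.

## Feature extraction and entropy fusion

Backbone features are always the globally average-pooled activations before
any classification head. The default extractor, `surrogate_tiny`, is a
two-conv-block network (3×3 conv with 8 channels → ReLU → 2×2 max-pool → 3×3
conv with `feature_dim` channels → ReLU → global average pool) whose weights
are drawn once from a seeded generator and never trained: a deterministic
random projection of local image structure, fast enough for unit tests on one
CPU. Three differently seeded surrogates stand in for ResNet18, DenseNet201
and Inception-ResNet-v2; the real backbones are available through an optional
torch extra and are never required. Images are resized to the backbone's
input size (224 for ResNet18/DenseNet201, 299 for Inception-ResNet-v2, 64 for
the surrogate — all configurable) and rescaled to [0, 1]; grayscale input is
tiled to three channels. Backbone weights are frozen; fine-tuning is an
extension point, not part of the contract.

"Entropy-based fusion" admits several readings; the one implemented is the
simplest testable, symmetric one: pool each backbone's absolute activations
over samples (column means), normalize to a probability vector over feature
channels, score by Shannon entropy normalized by log(dim), set weights
proportional to the scores, and multiply each backbone's block by its scalar
weight before concatenation. Consequences worth knowing: weights are
invariant to any global positive rescaling of a backbone's features; an
all-zero matrix gets the uniform-entropy score 1 with a warning; weighting
multiplies rather than gates, so no channel is discarded. Weights are learned
on the training images only and reused for the test images.

## Peephole LSTM

The recurrence is the classical peephole formulation with diagonal peephole
terms: the input and forget gates see `c_{t−1}`, the output gate sees `c_t`.
The cell-input squashing is `g(x) = 4σ(x) − 2` with range (−2, 2). For the
cell-output squashing the literal printed form `2/(1+x) − 1` is non-monotone
and singular at x = −1; the default is the scaled sigmoid
`h(x) = 2σ(x) − 1 = tanh(x/2)`, matching the form of `g`, while the literal
variant is kept behind `output_activation="printed"` for fidelity
experiments. With the default, `h(x) = g(x)/2` exactly.

A fused feature vector is not a time series; it is split into `chunk_count`
timesteps (default 4, so the recurrence is actually exercised), zero-padded
on the right. Padding changes the output — it is part of the model, applied
identically at fit and predict time. A forecast-horizon concept plays no role
in classification and is unused.

Training is plain mini-batch SGD on the softmax cross-entropy of the final
hidden state, with analytic BPTT gradients (verified against central finite
differences to ~1e-7 per-array norm relative error), a global gradient-norm
clip at 5 as a divergence safeguard, optional feature standardization from
training statistics (on by default), Gaussian fan-in-scaled initialization,
and a forget-gate bias starting at 1. A non-finite loss aborts with a
diagnostic; the tuner converts that abort into +∞ fitness. Models serialize
to a single `.npz` archive with named arrays and a format-version field; the
round trip is bit-exact.

## Evaluation

Per-class metrics are one-vs-rest. Per-class "accuracy" is (TP + TN)/N — the
only reading consistent with the benchmark's per-class accuracy differing
across rows. Macro averages are unweighted means; a class with no predicted
positives has undefined precision (NaN, flagged, excluded from the macro with
a warning). Internally everything is full precision; display rounds half-up
to two decimals, and tests compare at tolerance 0.005. The micro error
percentage, 100 × misclassified / total, is the tuner's fitness.

The benchmark worked example: the published per-class percentages fix every
confusion-matrix cell (precision and sensitivity give the column and row
sums), so the four matrices in `dbofuse.benchmarks` are reconstructions, and
the evaluation stack reproduces all sixty printed values exactly — the
strongest available end-to-end check of the metric definitions.

## Synthetic fixture

The generator emulates the benchmark's scale and structure, not radiology: no
DICOM, no Hounsfield units, no anatomical priors. 100 grayscale images in
[0, 1] at 64 px (35/32/33 per class): normal is a smooth low-intensity field;
benign adds one isotropic bright Gaussian blob (σ between size/10 and
size/6, amplitude 0.5); malignant adds 4–7 small anisotropic rotated blobs
(amplitude 0.6) on a brighter base. Per-class base intensity offsets are
(0, 0.12, 0.24). Every between-class difference scales with a single
`separability` knob (default 1), so separability 0 yields one shared
distribution — the chance-level null used in tests. Pixel noise is Gaussian
with σ = 0.05. These defaults were chosen once so that a nearest-centroid
rule on raw pixels clears 70% test accuracy — a fixed baseline oracle —
while separability 0 is indistinguishable.

Splits are stratified per class with half-up rounding of the training count;
"table-matching" mode instead reproduces the test-set class counts implied by
the benchmark tables ((8, 5, 7) at 80:20, (13, 9, 8) at 70:30) so worked
examples share the benchmark's denominators. Whether the original study
stratified its split is unknown; both modes are provided without any fidelity
claim.

What passing tests on this fixture shows: the plumbing, determinism, metric
definitions, optimizer behaviour and classifier training are correct, and the
pipeline can exploit real class structure. What it does not show: performance
on real CT images. The published headline accuracies were obtained on an
external image collection with ImageNet-pretrained backbones and stochastic
GPU-scale training; reproducing them is explicitly out of scope here, and the
synthetic classes are far more separable than real nodule taxonomy.

## Pipeline and problem sizes

The end-to-end run extracts features on the training split, fits fusion
weights there, tunes on an inner stratified validation fraction (0.2) of the
training split, refits the best configuration on the full training split, and
only then touches the test split. One seed drives data generation, splitting,
tuning and training through named substreams; reruns are bit-identical, which
is why wall-clock times appear in logs but never in report files.

Default problem sizes, chosen as comfortable desk-scale settings: 100 images,
three 32-dimensional surrogate backbones (96 fused features), DBO budget
population 6 × 5 iterations (36 trained candidates), hyperparameter box:
learning rate 1e-4…1e-1 (log), hidden 8…128, batch 4…32, chunks 1…8, epochs
20…200. A full run takes about a minute on one CPU. The tuner re-tunes per
split rather than reusing one configuration across splits.

## Known limitations

* The surrogate backbones are untrained projections; entropy weights among
  them are nearly uniform, so fusion mainly concatenates at desk scale.
* The thief/brood updates concentrate strongly near the incumbent best as
  R → 0; on multimodal objectives the optimizer can converge prematurely —
  only box constraints and no restart mechanism are provided.
* The printed-form output activation is kept for fidelity but diverges for
  cell states near −1; it is not usable for serious training.
* One-vs-rest per-class accuracy is reported because the benchmark tables use
  it; it is systematically higher than micro accuracy and should not be
  compared against micro numbers from other studies.
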