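# Methods

## Model

`a3som` implements a semi-supervised classifier that couples a
self-organizing map to a dense classification head and trains both jointly.

**SOM layer.** The map is a fixed rectangular lattice of `height × width`
units, indexed row-major with 0-based integer coordinates `(row, col)` from
the top-left corner; map-space distance is Euclidean on those coordinates.
Each unit `u` holds a prototype `w_u` in input space. For a sample `x` the
layer outputs the vector of Euclidean distances `a_u = d(x, w_u)` — a
distance profile, not a similarity — and the best-matching unit (BMU) is
`argmin_u a_u`, with exact ties resolved to the lowest unit index so that
every computation is deterministic.

**Dense block and heads.** The distance profile feeds `B` fully-connected
ReLU layers (default one layer of width 32) and an output layer with one
neuron per class. Two heads are supported and must be chosen *before*
training: `softmax` for standard, mutually-exclusive classification, and
`sigmoid` for the abstained task, where each class probability is
independent and a sample far from every class can score low everywhere.
Rows of softmax output sum to 1; sigmoid rows need not.

**Loss.** The training objective is

    L = CE + gamma * D + eta * ||w||^2

- `CE`: cross-entropy **summed** (not averaged) over the labeled samples.
  Averaging would merely rescale the meaning of `gamma`; the summed form is
  the convention used throughout this package and its logs. With the
  softmax head this is the categorical cross-entropy `-sum y ln p`. With
  the sigmoid head it is the one-vs-all binary cross-entropy
  `-sum [y ln p + (1-y) ln(1-p)]`: keeping only the positive term would
  leave wrong-class outputs without gradient, let output biases grow
  unboundedly and drive every probability to 1, making confidence-based
  abstention impossible. Probabilities are clipped to `[1e-7, 1 - 1e-7]`
  before logs. If a batch (or dataset) contains no labeled samples the term
  is 0 and training is distortion-only (a warning is emitted).
- `D`: SOM distortion, the neighborhood-weighted mean squared distance
  between each sample and *all* prototypes, over **every** sample, labeled
  or not. This is the only place unlabeled data enters, and it is enough:
  prototypes (and hence the features the head sees) follow the full data
  distribution.
- `||w||^2`: squared L2 norm of the dense-block weight matrices (biases and
  prototypes excluded).

**Training.** Mini-batch gradient descent (plain SGD by default; Adam
optional) with analytic gradients. Within a step the BMU assignment and the
neighborhood radius are held fixed — no gradient flows through the argmin —
and gradients reach the prototypes through both the distortion term and the
cross-entropy (via the distance activation). The neighborhood radius decays
exponentially per optimizer step from `max(height, width)/2` to `0.5`,
ordering the map globally before refining locally. An alternative
`analytic_batch` mode trains only the dense block by gradient and refreshes
the prototypes after each epoch with the classic batch-SOM update
(neighborhood-weighted means of the assigned samples); units whose
neighborhood-weighted assignment mass is numerically zero keep their
previous prototype. Prototypes are initialized deterministically on the
plane of the first two principal components (grid spanning ±2 SD); dense
weights use He-normal initialization from the run's seed. Every source of
randomness (initialization, shuffling, masking) derives from explicit
seeds, and two runs with the same seed are bit-identical. A non-finite loss
aborts with a diagnostic rather than silently continuing.

**Defaults and reference configurations.** `gamma = 1`, `eta = 1e-4`,
learning rate `1e-3`, 100 epochs, batch 32 are the generic defaults; all
are exposed on `TrainingConfig`, and suitable values are dataset-dependent.
Two named configurations are used by the experiments and the acceptance
script:

- `reference_training_config`: Adam at 3e-3 for 50 epochs. On unit-scaled
  inputs and small maps Adam converges far faster than SGD, and all loss
  terms plateau well before 50 epochs on the bundled datasets.
- `reference_abstained_config`: the same but `eta = 0.1`, used whenever the
  head is sigmoid. Under weak regularization a sigmoid head saturates: in
  regions of the map that no labeled sample constrains, the dense block
  extrapolates to probabilities near 1, so the mean-calibrated thresholds
  sit at ≈0.99 and the distance rule loses its meaning. A strong L2 penalty
  keeps outputs soft exactly where labels are absent; with it, the SOM's
  separation of an unseen class translates into low output probabilities
  and reliable distance abstention. (This was diagnosed on the expression
  stand-in, where the map isolated the hidden Basal-like class perfectly
  while the unregularized head still reported 99% confidence.)

## Abstention

Abstention is applied after training to sigmoid-head probabilities. For
each sample with top class `c*`, top probability `p*` and runner-up `p**`:

- **distance rule**: abstain iff `p* < beta_dist[c*]` (strict; equality
  accepts);
- **ambiguity rule**: abstain iff `p* - p** < beta_amb[c*]` (strict).

When both fire, the recorded reason is `distance` — the rule that
identifies new-class clusters on the map; the reason is kept per sample for
explainability. Thresholds live in `[0, 1]` per class; a "global"
threshold is the degenerate case with all classes equal.

**Calibration.** Per-class thresholds are set from the *training-set*
predictions of the fitted model (test labels are unavailable by
construction): `beta_dist[c]` is the mean top probability over samples
whose argmax class is `c`, and `beta_amb[c]` the mean top-two margin over
the same samples. A class to which no sample is assigned gets threshold 0
and can never trigger abstention.

**Metrics.** With G/E the partition of evaluated samples by argmax
correctness and A/R the partition by the abstention decision: accepted
accuracy `AA = |G∩A|/|A|` and rejected error `RE = |E∩R|/|E|`. Vacuous
denominators are defined as `AA = 1` when nothing is accepted and `RE = 1`
when there are no errors; with zero rejections AA reduces to the plain
accuracy and (when errors exist) RE to 0.

**Threshold sweeps.** The global sweep traces (rejection rate, AA, RE) for
one shared threshold over a uniform grid on `[0, 1]` (101 points by
default). The local sweep explores the per-class hypercube by seeded
uniform random search (2000 draws by default) *plus* the shared-threshold
diagonal: the global configurations are a subset of the local space, so
any sensible search should include that known baseline, and seeding with it
guarantees the local Pareto front starts at the global one. Exhaustive
per-class grids would grow exponentially with the class count and are not
attempted; consequently the local front is a lower bound on what local
thresholds can achieve.

## Synthetic data

**Artificial 2-D benchmark** (`generate_artificial`): 3000 points, 2
features, 6 balanced classes (500 each), min-max normalized to [0, 1].
Classes 0–2 are isotropic Gaussians, classes 3–5 axis-aligned uniform
boxes, laid out to produce a graded ambiguity structure:

| component | definition (pre-normalization) | role |
|---|---|---|
| class 0 | N((0.15, 0.82), 0.04²I) | close to box 3 but separable (≥95% mass disjoint) |
| class 1 | N((0.92, 0.92), 0.03²I) | far from everything (≥6 pooled SD); the natural hidden class |
| class 2 | N((0.73, 0.21), 0.05²I) | its upper tail reaches into box 5 |
| class 3 | box [0.05, 0.33] × [0.38, 0.62] | overlaps box 4 in a 0.045-wide strip |
| class 4 | box [0.285, 0.565] × [0.36, 0.60] | overlaps boxes 3 and 5 |
| class 5 | box [0.545, 0.825] × [0.30, 0.56] | overlaps box 4; intersects class 2's high-density region |

Inside an overlap strip the two uniform densities are equal, so those
regions are irreducibly ambiguous. The 3–4 strip is wide enough that a
linear classifier cannot separate the pair above ≈0.93; the 4–5 strip and
the box-5/Gaussian-2 intersection are narrower, keeping the 6-class Bayes
accuracy near 0.96 — the regime in which the benchmark experiments operate.
All parameters are fields of `ArtificialSpec`.

**PAM50-like expression stand-in** (`generate_expression`): a synthetic
surrogate for a curated breast-cancer bulk-expression cohort — 150 samples
per subtype (LumA, LumB, Her2, Basal), 50 features: four named marker roles
plus 46 background features. Marker means encode the clinical signature:
LumA/LumB high on ESR1/PGR-like markers, Her2 high on the ERBB2-like
marker, LumB above LumA on the MKI67-like proliferation marker, and Basal
low on all of ESR1/PGR/ERBB2 (the "triple-negative"-like pattern).
Background features get per-subtype means drawn once from the spec seed in
[0.35, 0.65] — mild, unstructured subtype signal — and all features receive
Gaussian noise (SD 0.12), clipping to [0, 1] and per-feature min-max
normalization. It is labelled *synthetic* throughout: it reproduces the
signature structure, not the covariance, dropout or batch structure of real
RNA-seq, so passing tests demonstrate the workflow's mechanics, not
clinical performance.

Both generators are pure functions of their spec + seed. Label utilities
never touch `X`: `mask_labels` replaces an exact count (`round(fraction ×
n_labeled)`) of labels with the sentinel −1 (optionally stratified to keep
one label per class); `hide_class` unlabels an entire class and compacts
the remaining class indices so the hidden class has no output neuron, while
the ground truth is retained separately (`y_full`) for evaluation only.

## Benchmark harness

Stratified 5-fold cross-validation over a grid of labeled fractions
(default {0.1, 0.25, 0.5, 0.75, 1.0}), run transductively: each method
trains on the entire dataset, with validation-fold labels hidden and
training-fold labels masked to the target fraction; scoring uses the
held-back validation labels. Masking seeds derive from (protocol seed,
fraction index, fold index), so folds are independent and every method sees
identical conditions. The headline statistic is the grand mean of the
per-fraction mean accuracies. Self-training (SVM/RF/MLP) and label
propagation adapters wrap scikit-learn and are provided for harness parity
only.

## Experiment sizes

The bundled experiments run on one CPU in a few minutes: the CV benchmark
fits 25 models (5 fractions × 5 folds) on 3000 points; the hidden-class,
sweep and expression runs fit one model each on a 75% training split. These
are the study conditions the synthetic generators define, not down-scaled
variants.

## Numerical choices

- BMU ties → lowest unit index; argmax ties in prediction → lowest class.
- Probability clipping `1e-7` before all logs.
- Empty-unit threshold `1e-12` on the batch-update denominator.
- Distance-activation gradient at `a_u = 0` is defined as 0 (the true
  subgradient set contains it, and the event has measure zero).
- `n_total` not divisible by the class count distributes the remainder to
  the lowest class indices with a warning.
- Connectivity of a BMU region uses 8-connectivity on the grid, consistent
  with the Chebyshev-radius-1 neighborhood used for explanations.

## Limitations

- The map size is fixed before training (no growing-map variants) and the
  grid is rectangular with Euclidean map-space distance.
- Abstention is post-hoc: rejection is not learned during training.
- The local-threshold sweep is a sampled search, not an exhaustive one; its
  front is a lower bound.
- The CE-vs-distortion balance (`gamma`) and the L2 weight (`eta`) are
  dataset-dependent; the two reference configurations were selected on the
  bundled synthetic datasets and are starting points, not universal values.
- Synthetic generators validate mechanics and qualitative structure; no
  claim is made about performance on real cohorts, which additionally show
  class imbalance, batch effects and heavier-tailed noise.
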