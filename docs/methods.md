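# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Classification model

Each GO-BP category is treated as an independent two-class problem over
matrix rows (cDNA clones). Rows of genes annotated with the term are
positive; negatives are drawn uniformly without replacement from rows of
genes that have *some other* BP annotation, at most four negatives per
positive. Genes with no BP annotation have unknown class: they are never
used for training or calibration, only scored.

The SVM operates on a precomputed radial-basis kernel
K(x, y) = exp(−‖x − y‖²/σ²). Note the sign: the exponent is negative —
the unnormalized Gaussian is the only bounded, positive-definite reading
of this kernel family, and any implementation must use it. The width
heuristic is

σ = median over positive training points p of min over negative training
points n of ‖p − n‖,

computed on imputed features, separately for every training set in the
rotation (the heuristic is tied to the *training* positives, which change
with the fold arrangement). The median of an even count is the mean of the
two central values. If the median is zero because a positive coincides
with a negative, the smallest strictly positive nearest-neighbour distance
is used; if all distances are zero the task is degenerate and rejected.

### Class-asymmetry diagonal augmentation

With 1:4 sampling the classes remain imbalanced. Each training point's
diagonal entry is augmented by λ·|C|/N, where |C| is the size of the
point's class, N the training-set size, and λ = m/2 with m the median of
the pre-augmentation diagonal (m = 1 for RBF, so λ = 0.5). For N = 100
with 20 positives this gives diagonals 1.10 (positives) and 1.40
(negatives): the majority class is regularized four times harder.
Augmenting the diagonal is algebraically identical to a 2-norm slack
penalty with class-dependent cost, so the dual is a hard-margin problem on
the augmented kernel: maximize Σα − ½ΣΣ αᵢαⱼyᵢyⱼK̃ᵢⱼ subject to αᵢ ≥ 0 and
Σαᵢyᵢ = 0, with no upper box. The primal objects (w, ξ, C) are never
materialized.

The solver is a primal-feasibility active-set iteration: start with all
multipliers free, solve the equality-constrained system forcing
yᵢf(xᵢ) = 1 on the free set, drop the most negative multiplier or add the
most violated margin, repeat. The augmented kernel is strictly positive
definite, so the dual optimum is unique and the iteration terminates; the
solution is accepted only if the KKT residual (dual-constraint violation,
support-vector margin error, margin deficit of inactive points) is ≤ 1e−6.
The bias is averaged over support vectors. Correctness is checked two
independent ways in the tests: exhaustive support-set enumeration on tasks
of ≤ 12 points (exact agreement required to 1e−6) and libsvm with a
precomputed kernel and an effectively unbounded box constraint (loose
agreement, since libsvm solves the 1-norm variant).

Cross-kernel blocks used for prediction are never augmented — the
augmentation is a property of the training problem, not of the kernel
function.

## Probability calibration

Discriminants are mapped through p(f) = 1/(1 + exp(a·f + b)). Under this
sign convention a < 0 whenever larger discriminants indicate the positive
class. (a, b) minimize the cross-entropy against smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) computed from the calibration fold's
class sizes; the smoothing keeps the problem strictly well-posed even when
the calibration fold is perfectly separated. The stated likelihood is
maximized by minimizing its negative.

Fitting is damped Newton from a = 0, b = log((N₋+1)/(N₊+1)), with the
objective, gradient and Hessian evaluated in log1p/exp forms that cannot
overflow. Steps are accepted when they do not increase the objective
beyond a 1e−12 relative roundoff allowance — near the minimum the
objective decrease falls below double-precision resolution while Newton
still contracts the gradient quadratically, and this acceptance rule lets
the iteration reach the 1e−8 gradient-norm tolerance (100-iteration cap;
non-convergence is flagged and the best iterate returned). The tolerance
is this package's choice. Only a fully constant discriminant vector is
rejected; ties are fine.

## Rotation scheme

Labeled rows are split into four folds of near-equal size and near-equal
positive counts (both differ by ≤ 1; which folds take remainders is a
seeded random choice). For each test fold I_α, the three remaining folds
rotate through the calibration role: train on I_γ ∪ I_δ, fit the sigmoid
on I_β, score I_α — three arrangements per test fold, and the training
pair is unordered, so 12 SVM fits per category. A labeled gene's final
probability is the mean of its three arrangement values. Un-annotated
rows are scored by all 12 arrangements and summarized per fold as the mean
of the three arrangements sharing that test fold, mirroring the labeled
averaging and yielding four fold-level scores per gene. Role disjointness
(test ∩ train = test ∩ calib = calib ∩ train = ∅) is asserted on every
arrangement.

Duplicate clone rows of one gene may land in different folds by default —
duplicates are deliberately retained as separate data points so the
consistency of their predictions can be inspected. A `group_duplicates`
switch forces same-fold placement via greedy balanced assignment of gene
groups, at the cost of exact ±1 balance.

## Evaluation

Precision = TP/PP and recall = TP/P under the rule "probability ≥
threshold ⇒ predicted positive", with one PR point per distinct
probability value (tied genes enter and leave the predicted set
together). Precision-at-recall r is the **maximum** precision over
thresholds whose recall reaches r; the alternative reading (precision at
the most conservative such threshold) is available via `mode="threshold"`.
Fold curves are averaged vertically — precision interpolated linearly in
recall on a fixed 101-point grid {0, 0.01, …, 1}, then averaged; linear
interpolation is this package's choice, as is the grid.

The gene-precision score of an un-annotated gene in a fold is the maximum
precision over curve thresholds ≤ the gene's probability; if no threshold
lies at or below it the gene can never enter the predicted-positive set at
an admissible operating point and scores 0. The score is a non-decreasing
step function of the probability by construction. Category selection
(mean precision-at-40 ≥ 0.75) and prediction selection (mean gene
precision ≥ 0.75) both use inclusive bounds. Reported percentages round
half away from zero; exact ratios are kept in machine output.

Because precision-at-recall takes a maximum over thresholds, its null
expectation exceeds the raw prevalence: for a label-free ranker at 1:4
sampling the prevalence is 0.2, but fold-level max-precision-at-40 on
folds of ~40 rows averages roughly 0.24–0.31 depending on the seed. The
synthetic null study should be read against that bias, not against 0.2
exactly.

## Synthetic benchmark

The generator emulates a developmental time-course: each planted category
draws one smooth latent profile (first three Fourier harmonics with random
amplitudes and phases, unit RMS) and its members follow
amplitude·profile + N(0, noise_sd²) with per-gene amplitude jittered
±20%, so members are correlated but not identical. Background rows are
pure noise. Defaults — 500 genes × 60 conditions, signal 1.0, noise_sd
0.25 (signal-to-noise 4 for fully scaled categories), 2% missing cells,
30% un-annotated genes, 5% duplicate clones, planted categories of 30
annotated + 10 hidden members — are the study conditions used by the test
suite and the acceptance script; a null category is the same size with
signal scale 0. Hidden members are generated by the same process as
annotated members and withheld from the annotation table, making the
guilt-by-association premise literally true and recoverable.

What the generator does **not** emulate: array-level artifacts (dye bias,
print-tip effects — inputs are assumed normalized), heavy-tailed or
correlated noise, hierarchical GO structure (terms are flat and
independent; no ancestor propagation), and realistic annotation sparsity
patterns. Passing the planted-category benchmark therefore shows the
machinery is correct and has power under clean co-expression, not that
comparable precision is attainable on real compendia.

## Other choices and limitations

- Missing cells default to zero imputation (log-ratio 0 = "no change",
  neutral and deterministic); row-mean imputation is available. How the
  original analyses handled missing values is not specified anywhere, so
  this is a package decision.
- Category membership uses direct annotations only; no GO-graph ancestor
  propagation. The negative pool excludes only the term itself, not its
  ancestors or descendants.
- Unmapped clones keep their rows under a sentinel gene id (auditable row
  counts) and are excluded at task-building time.
- Per-category seeds are CRC-derived from the master seed and the term id,
  so category results are independent of which other categories run.
- Determinism: one master seed fixes negative sampling, fold assignment
  and the simulator; the solver and Newton fit are deterministic. Two runs
  with the same inputs and seed produce byte-identical outputs.
- Categories are trained independently; no multi-label coupling, no
  ROC/AUC summaries, and no network fetching of expression or annotation
  releases.
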