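# Methods

## Feature extraction

Edges are Pearson correlations between ROI time series, Fisher
z-transformed, upper triangle flattened row-major (feature k ↔ pair (i,j),
i<j, 0-based; the order is arbitrary but must be fixed for indices to be
reproducible, so it is pinned in `EdgeIndexMap` and exported alongside every
artifact). Correlations are clipped to ±(1−1e−7) before arctanh so that
perfectly correlated columns stay finite; at that clip the z value is ~8.4,
far outside the data range, so clipping never distorts realistic inputs.
The diagonal never enters the features. Population vs. sample normalization
of the covariance cancels in the correlation ratio, so either convention
yields identical r.

## The classifier

Architecture: input d → dense(64) → BN → LeakyReLU → dropout → dense(32) →
BN → LeakyReLU → dropout → dense(1) → sigmoid, for whole-brain inputs;
scaled-down studies use hidden widths 16 and 8. All parameters and
arithmetic are float64.

Key knobs and defaults:

- `leaky_slope` α = 0.01. The folded weights depend on α, so it is explicit
  in the config; α = 0 (plain ReLU) is allowed with a warning.
- `dropout_rate` = 0.8 at whole-brain scale, interpreted as the probability
  of *dropping* a unit (the common reading of "dropout ratio");
  it is inactive at evaluation time, so interpretation is unaffected by the
  placement or rate.
- BN: ε = 1e−5 inside the square root; running statistics updated with
  momentum 0.1 and the unbiased batch variance, used verbatim at eval time.
- Optimizer: Adam, lr 5e−4, batch 32, binary cross-entropy on logits (the
  log-sum-exp form, immune to log(0)). Batches with fewer than 2 samples
  are skipped because batch BN is undefined there.
- `standardize` (off by default): optional per-column z-scoring whose
  mean/scale are stored in the checkpoint and folded back into (ŵ, b̂), so
  reported weights are always in raw Fisher-z feature units.
- Labels: patients = 1 (positive), controls = 0, fixing sensitivity as the
  proportion of patients correctly identified.

Cross-validation is stratified k-fold (default k=5) with a fixed seed;
stratification stabilizes per-fold class balance. Fold training seeds are
derived deterministically from the CV seed. AUC comes from the ROC curve
and is cross-checked in the tests against the Mann-Whitney rank form with
tied ranks averaged.

## Exact linearization

At eval time each BN neuron is the affine map γ̃u + β̃ with
γ̃ = γ/√(Var[u]+ε), β̃ = β − γE[u]/√(Var[u]+ε). The activation pattern
records, per hidden neuron, which LeakyReLU branch the instance takes;
pre-activations of exactly 0 take the slope-1 branch (consistent with
f(u)=u for u ≥ 0). Folding proceeds by the recursion in
`linearize.local_linear`: the composed affine map (A, c) from input to the
current pre-activation is updated as A ← W diag(r∘γ̃) A,
c ← W (r∘γ̃∘c + r∘β̃) + b. The intercept b̂ is carried through the same
recursion — the linear form is only exact with it, so it is always
included and reported.

Properties verified by the test suite: exactness (max |logit − ŵ·x − b̂| <
1e−7 on untrained, trained, BN-free and standardized models; observed
~1e−15), region consistency (identical patterns ⇒ identical (ŵ, b̂)),
gradient agreement away from region boundaries (central differences,
rel. 1e−3), and the closed-form α² scaling when both hidden layers sit on
the negative branch.

## Decision features

Default ranking is by |ŵ|: a strongly negative weight is evidence for the
control class and is decision-relevant; signed ranking is available for
strict top-positive-weight reading. The occurrence threshold comparison is
≥ ε. Ties in the top-K cut break toward the lower feature index, making the
mining fully deterministic. The instance population defaults to held-out
subjects pooled over CV folds — each subject interpreted exactly once, by a
model that never saw it — with a whole-dataset single-model mode also
usable by passing any list of interpretations.

|F| is nondecreasing in K (top-K sets are nested) and nonincreasing in ε;
both monotonicities are asserted across the full K = 5…300 (step 5),
ε = 0.70…0.95 (step 0.05) grid.

## Perturbation ("hacking") evaluation

Features are zeroed in Fisher-z space, where 0 means r = 0 — no
connectivity — which is the natural "feature removed" semantics. Post-hack
forward passes recompute activation patterns from scratch; hacked instances
may cross linear-region boundaries and no frozen-pattern shortcut is taken.
Post-hack sensitivity/accuracy are computed on hacked inputs against the
original labels. CPP for a purely linear model has a closed form (the
sigmoid gap after subtracting the zeroed features' contribution), used as
an oracle in the tests; CPP need not be monotone in the feature set for the
nonlinear model, and the suite deliberately does not assert that.

The random-set control (20 seeded draws of same-size feature sets) is an
extension beyond the classical top-weight-SVM comparison: it calibrates
what "uninformative attribution" looks like on the same model and data.
The SVM baseline scores hacked inputs by a logistic squash of the margin,
a deterministic monotone transform adequate for CPP/NLCI comparisons.

## Group statistics

Welch's t test by default (the pooled-variance variant is one flag away),
two-sided. Means are reported on the Fisher-z scale, or back-transformed
per subject via tanh before averaging with `scale="r"`. No multiplicity
correction by default, with Benjamini–Hochberg available and recommended
whenever the feature set is more than a handful.

## Synthetic cohorts

The generator emulates two-group cohorts whose correlation structure
differs on a known edge set. Both groups share a base correlation matrix
built from 3 latent factors (low-rank + diagonal, normalized to unit
diagonal), mimicking the block structure of real functional-connectivity
matrices. The patient target shifts the planted edges by +delta and is
repaired to the nearest valid correlation matrix by eigenvalue clipping at
1e−6 followed by diagonal renormalization — deterministic, and required to
move non-planted edges by less than delta/10 (asserted at construction).
Per-subject variability comes from a symmetric Gaussian jitter (sd 0.05) of
the target followed by the same repair. Time points are i.i.d. Gaussian
rows by default; an AR(1) option (off by default) adds temporal smoothness
without changing the stationary correlation structure.

Default study conditions: p = 20 ROIs, 200 subjects per group, T = 150
timepoints, 5 disjoint planted edges, delta = 0.3 — a scale at which a full
simulate → train → interpret → mine → hack chain runs in seconds while the
planted effect is strong enough (per-edge Fisher-z shift ≈ 0.31 against a
subject-level sd ≈ 0.1) for recovery to be expected, not guaranteed. For
the scaled-down [d,16,8,1] networks the training conditions are epochs 150,
batch 32, lr 5e−4, dropout 0.2 — chosen once as sensible defaults for
~400-sample cohorts and kept fixed. Whole-brain p=116 runs use the paper-
scale architecture [6670, 64, 32, 1] via `ModelConfig`.

What passing tests on these cohorts do **not** show: robustness to BOLD
autocorrelation and hemodynamics, scanner/site heterogeneity, motion
artifacts, or class imbalance — none of which the generator produces.
Results on real multi-site data will be noisier in all of these ways.

## Known limitations

- Exactness of the interpretation is a property of eval-mode BN; train-mode
  batch-statistics interpretation is out of scope.
- Only LeakyReLU/ReLU activations are folded; other piecewise-linear
  activations would need the (provided-for, currently zero) activation
  intercept t.
- The decision-feature algorithm is frequency-based; it does not model
  feature interactions or redundancy (two correlated edges may split votes
  and both fall below ε).
- Training is plain NumPy on CPU: appropriate for these model sizes, not
  for substantially deeper or wider architectures.
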