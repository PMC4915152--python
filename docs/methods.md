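# Methods

## The problem

Multi-omics studies measure several molecular layers (e.g. mRNA, miRNA,
DNA methylation) on the same subjects. Each layer arrives as a features ×
samples matrix with missing entries, and downstream integrative analyses —
clustering, differential testing, regulatory-network reconstruction —
assume complete matrices. Classical imputation estimates a layer's missing
entries from that layer alone; `omicsfill` additionally exploits the fact
that features in different layers are correlated through shared biology,
and combines within-layer and cross-layer estimates into one prediction.

## Single-omics engines

All five engines operate on a target feature row `g_t` split into its
missing part `g_t^miss` and observed part `g_t^c`.

* **KNN** — the k nearest rows by Euclidean distance on the target's
  observed samples contribute an inverse-distance weighted average at each
  missing sample. Distances over partial overlaps are rescaled by
  `n/|overlap|` so candidates with different overlap sizes are comparable.
  A zero-distance neighbour is copied directly (the limit of the weight
  formula); several zero-distance neighbours are averaged. Only rows
  observed at the target column are eligible; if fewer than k exist, all
  eligible rows are used and a warning is emitted. Default k = 15.
* **SVD** — EM-style completion: row-mean initialisation, then repeated
  {rank-q decomposition of the filled matrix; regression of each
  incomplete row's observed entries on the top right-singular vectors
  (eigengenes); replacement of the missing entries by the fitted values}.
  q defaults to 20% of the sample count (rounded half up, minimum 1).
  The right singular vectors are computed from the n × n Gram matrix,
  which is much cheaper than a full SVD when p ≫ n.
* **BPCA** — Bayesian PCA with an automatic-relevance-determination (ARD)
  prior on the loading columns. Feature rows are modelled as
  `y = W x + mu + eps`; the configured component count defaults to the
  "safe" n − 1, and ARD shrinks irrelevant columns during fitting.
  Two deliberate simplifications relative to a full variational treatment:
  (i) one shared posterior covariance is used for the complete rows, while
  each incomplete row's factor scores are estimated from its observed
  entries only (ridge-regularised by the noise variance) — this prevents a
  missing entry from feeding back into its own reconstruction; (ii) the
  point-estimate EM cannot sustain q close to n (it interpolates the
  complete rows and collapses the noise variance), so the fitted component
  count is internally capped at n/2 and ARD prunes from there.
* **LLS** — the k nearest candidate rows are regressed onto the target's
  observed part via the Moore–Penrose pseudo-inverse (minimum-norm
  solution when rank-deficient); the fitted coefficients predict the
  missing samples. Candidate rows are row-mean completed first so they
  are usable at every position.
* **iLLS** — iterative LLS: repeated passes in which previously imputed
  candidate values are reused for both neighbour selection (full-vector
  distances) and regression; the neighbour count is `ratio × (p − 1)`.

**Parameter selection by faking missing values.** When k (LLS) or the
ratio (iLLS) is not fixed, observed entries are hidden at random positions
disjoint from the true missing set and every candidate value in the range
(k from 2 to n − 1; ratio from 0.1 to 1 in steps of 0.1) is scored by
NRMSE on those positions; the minimiser wins, smallest value on ties.
The faking fraction defaults to the matrix's observed missing rate,
clamped to [1%, 10%]. All randomness is seed-derived.

## Cross-omics imputation

To impute `g_t` of layer G1 from layer G2, source features significantly
Pearson-correlated with `g_t^c` (two-sided t-transform p < 0.05 on ≥ 3
mutually observed samples) are stacked under the target row to form an
augmented matrix H, which is imputed by the configured single-omics engine
and back-transformed. Because the layers live on different scales, every
row of H is z-scored; source rows are standardised over the *target's
observed samples*, which makes an exact duplicate of the target
standardise to the identical vector and keeps the regression geometry
consistent. For the regression engines (LLS/iLLS) the selection is
truncated to the top min(n − 1, 50) features by |r| so the system stays
over-determined; KNN and the global engines use every significant feature
(their accuracy improves with source rows, and the truncation rationale
does not apply). Ties in |r| break by feature ID, making selection
invariant to source row order. A prior-knowledge edge list (e.g.
STRING-style scores) can force specific source features into the LLS/iLLS
predictor set: a feature is forced when its edge score exceeds the graph
threshold (default 0.9) *and* it passes the correlation screen. Features
with no significant source partner keep their self-imputed values.

## Ensemble combination

For one target layer with m − 1 complete source layers, basic models are
the self-imputation and each cross-imputation, each run B times on a
feature subsample (fraction 0.7 by default) — subsampling candidates, never
the feature being imputed. In the self arm, a candidate pool of
`round(fraction × p)` rows is imputed on its own and out-of-pool
incomplete rows are then imputed against the filled pool, so every model
sees a different candidate pool while covering every missing entry.

Weights are fitted on *faking missing* entries: a seed-derived random set
of observed positions (size = true missing rate × observed count, floor
1%) is hidden, every basic model is run on that union mask, and the truth
at the fakes is regressed on the models' predictions under the simplex
constraint (β ≥ 0, Σβ = 1), which handles the strong collinearity among
models and implicitly prunes non-contributing ones. T bootstrap rounds
(default 30) resample the faking locations with replacement; the T
solutions are averaged (an average of simplex points is a simplex point).
The solver is non-negative least squares with a heavily weighted
sum-to-one penalty row followed by exact renormalisation; it matches an
exhaustive 0.01-step simplex grid search to 1e-6 on small problems.
Final predictions come from a second pass of the same basic models
(identical subsample streams) run on the true mask only, so the fakes
never handicap the delivered estimates; degenerate rounds with identical
model predictions fall back to uniform weights.

## Iterative multi-matrix algorithm

When several layers have missing entries: every layer is first completed
by self-imputation; then, cyclically, each layer is re-imputed by the
ensemble using the current filled state of the other layers, in order of
increasing missing-feature count (count of features containing ≥ 1 missing
entry; stable ties) so error propagates from the least to the most damaged
layer. Later layers in an iteration see the already-refreshed state of
earlier ones; a config switch (`literal_printed_order`) instead restricts
each layer's sources to the layers already refreshed in the current
iteration. Convergence is declared when
`δ_h / (N_miss × var(imputed values))` ≤ τ (default 1e-4), where δ_h is the
sum of squared changes at the missing locations between consecutive
iterations; the relative form makes the criterion scale-free. The loop is
capped at `max_iterations` (default 10) and reports non-convergence as a
flag, not an error. Warm starts: a layer's previous estimates remain in
place under its mask and replace the row-mean initialisation of the next
pass.

## Synthetic data

The generator emulates a TCGA-like correlated multi-omics study at desk
scale: shared latent factors `F` (rank 3 by default, standard normal,
rank × n) with per-layer Gaussian loadings and i.i.d. noise
(`G_i = L_i F + E_i`, noise sd 0.3 by default). Default shapes 300/60/250
features × 50 samples mirror a large mRNA layer, a small miRNA layer and a
methylation layer. MCAR injection masks exactly `round(rate × p × n)`
uniform entries; MAR injection masks contiguous blocks of (default 5)
adjacent feature rows at random sample columns until the target count is
reached, emulating contaminated array regions. What the generator does
*not* emulate: heavy-tailed and count-valued distributions, non-linear
regulation, feature-specific noise, batch structure, and informative
(MNAR) missingness — so passing benchmarks demonstrate correct mechanics
and the direction of the multi-omics gain under shared linear structure,
not performance guarantees on real data.

## Evaluation

NRMSE is `sqrt(mean((true − imputed)²) / var(true))` with squared
residuals averaged over all missing locations and the sample variance
(n − 1 denominator) of the true values pooled over every location across
matrices; 0 is perfect, ≈ 1 is no better than predicting the pooled mean.
Method comparisons use two-sided paired t-tests on per-replicate NRMSE,
with identical data and masks for every method within a replicate (the
sweep harness derives all masks from the replicate seed). Network recovery
treats complete-data cross-layer Pearson correlations beyond a threshold
(sign-directional, e.g. r < −0.55) as true edges and the imputed-data
correlation as the classifier score; ROC/AUC via the trapezoidal rule.

## Numerical choices and degenerate inputs

* Iterative engines (SVD, BPCA, iLLS) stop on relative change < 1e-5 or
  when the update stagnates (change shrinking by < 10% after the second
  sweep), which cuts sweeps spent shuffling noise below the error floor.
* Fully missing feature rows are rejected at load with a clear error
  (optional flag drops them); imputing them from nothing is untestable.
* Zero pooled variance at evaluation locations, empty overlap in a
  distance computation, and ROC with no positives (or no negatives) raise
  errors rather than returning NaN.
* Zero-variance rows cannot be z-scored and are dropped from H with a
  warning; zero-variance features get zero network correlations.
* All random streams derive from `numpy` `SeedSequence` spawns of
  `(seed, source, subsample, round)`, so results are independent of
  execution order and reproducible bit-for-bit.

## Benchmark problem sizes

The shipped benchmarks run a 100 × 50 target with 300 × 50 and 250 × 50
sources (rank 3, noise sd 0.3) over missing rates 1–20%, with B = 2
subsamples and the default T = 30 bootstrap rounds in the ensemble, fixed LLS k = 10
and iLLS ratio = 0.2, and 15–20 replicates per cell — small enough to run
on one CPU in minutes while preserving the shape ratios of the motivating
study. The library defaults (B = 5, parameter search on) are deliberately
richer than the benchmark settings.

## Known limitations

* The BPCA implementation is a regularised EM variant, not the full
  variational Bayes treatment; its internal component cap (n/2) departs
  from the classical "n − 1 is safe" guidance, which relies on the full
  Bayesian machinery.
* Cross-imputation assumes matched samples across layers; subjects present
  in only one layer degrade to self-imputation for their entries.
* Ensemble weights are fitted per matrix (pooled over features), not per
  feature; per-feature weights would be underdetermined at low missing
  counts.
* MNAR missingness is out of scope; MAR support is limited to the
  block-contamination mechanism described above.
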