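# Methods

This note documents the models and procedures implemented in `caco2qspr`,
the choices made where the methodology was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Data model and curation

The pipeline's currency is the descriptor table: n compounds × p numeric
molecular descriptors plus a log10 Papp endpoint (log10 cm/s). Curation
applies, in order:

1. **Endpoint bounds.** Compounds outside −8 ≤ log Papp ≤ −3.5 (inclusive,
   applied on the log scale) are dropped: Papp values above 10⁻³·⁵ or below
   10⁻⁸ cm/s are experimentally unreliable.
2. **Duplicate structures.** Records sharing a SMILES are merged to their
   mean log Papp when their range is ≤ 0.5 log units, and dropped entirely
   otherwise. The 0.5 default reflects a common inter-laboratory
   reproducibility bound for permeability assays; it is configurable
   (`dup_log_range_max`). Records without a SMILES are never grouped.
3. **Missing-value triage.** A compound with a missing cell in a descriptor
   whose variance among the other compounds exceeds 0.3 is removed (the
   descriptor is informative, so the column is worth keeping); missing
   cells surviving this step cause whole-column removal instead.
4. **Constant/correlated pruning.** Zero-variance columns are dropped.
   Descriptor pairs with |Pearson r| > 0.85 are processed in descending
   |r| (ties by column order); the member with the weaker |r| to the
   endpoint is dropped, and pruning repeats among survivors. The
   deterministic ordering makes the result reproducible; whether the 0.85
   rule uses |r| or signed r is configurable (`use_abs`, default |r|).
   Pearson correlations use pairwise-complete rows; a column with fewer
   than 3 complete pairs is treated as uninformative (r = 0).

The chain is idempotent, and each step emits a reconciling report
(n_in − drops − merges = n_out).

## QPSO optimizer

All global searches (outlier thresholds, hyperparameters, descriptor
subsets) use one quantum-behaved particle swarm optimizer. Each particle is
resampled around a stochastic attractor interpolated between its personal
best and the global best, jumping by β·|mbest − x|·ln(1/u) where mbest is
the mean of personal bests, u ~ U(0,1), and the contraction–expansion
coefficient β anneals linearly 1.0 → 0.5 over the run. A hybrid
Lévy-flight perturbation (Mantegna sampling, α = 1.5) kicks the `L` worst
particles each iteration (default L = 10), with `λ` (default 1) scaling
the step — an interpretation of the published hybrid's "Lévy flight and
hopping" operators, whose exact form is not reconstructible; they are
mapped to perturbation count and step scale and documented as such.
Defaults follow the published settings: population 30, with per-use
iteration budgets. Positions are clamped to bounds before every
evaluation; identical config + seed + fitness gives bit-identical results.

Binary (subset) mode keeps a continuous state per item, maps it through a
logistic transfer to selection probabilities, samples a bit vector, and
repairs oversized sets by dropping the lowest-priority members (priority
supplied by the caller, e.g. importance rank). Every evaluated set is
feasible; empty sets are repaired to the single best-priority item.
Infeasible *constraints of callers* (e.g. the 2% deletion cap in the
outlier filter) are handled by a large additive penalty (10⁶) rather than
rejection, keeping the search space connected.

## Monte-Carlo outlier filtering

Each of n_iterations (default 2000) rounds draws a random 90/10 split,
fits MLR on the 90% and records signed residuals on the 10%. MLR inside
the loop uses ridge-stabilized normal equations (ridge 10⁻⁸): random 90%
splits of wide tables can be rank-deficient, and the loop must never
abort. Per compound, the profile stores the mean *absolute* residual and
the SD of signed residuals; the plotted/filtered "mean" must be
nonnegative for a one-sided threshold to make sense (the signed mean is
available behind a flag). A compound is abnormal when mean_abs > mean_lim
OR std > std_lim (the union rule; AND is configurable since the
flag-region reading is ambiguous). The thresholds are QPSO-tuned within
(0.6–1.8) × (0.1–0.35) to maximize retained-data MLR R²cv5, with the
penalty active above the 2% removal cap. 5-fold CV folds use a fixed
seeded shuffle so the optimization surface is deterministic. If no
feasible threshold pair is found, nothing is removed.

## Splitting

Descriptors are z-scored before PCA (mandatory for mixed-unit PaDEL
descriptors); K is the smallest component count reaching the 90% variance
target. The SOM is a standard online Kohonen network on the K scores:
seeded uniform codebook init from the data range, Gaussian neighborhood
shrinking from max(rows, cols)/2 to 1 unit, learning rate decaying
linearly 0.5 → 0.01, default 3×3 grid and 500 epochs (all configurable;
the reference workflow's SOM hyperparameters are unpublished, so these are
conventional defaults). Within each cluster, compounds are sorted
ascending by endpoint and 1-based positions ≡ 3 (mod 5) go to the test
set: the one-in-five rule's start position is unpublished, and position 3
(the block median) keeps local endpoint extremes in training; the offset
is configurable. The resulting test fraction is ~18–20% and test
endpoints are interior to the training range by construction.

## RBF networks and the dual-RBF ensemble

The RBF regressor is ŷ(x) = b + Σ ωᵢ φ(‖x − cᵢ‖) with Gaussian φ. Two
spread conventions are supported: `matlab` (default),
φ(d) = exp(−(0.8326·d/δ)²), which gives φ(δ) = 0.5 and matches the
MATLAB `newrb` trainer most published permeability models were built
with; and `classic`, φ(d) = exp(−d²/(2δ²)). Training is greedy
largest-error insertion: start bias-only (b = ȳ), repeatedly add the
training point with the largest current |residual| as a center (ties by
lowest row index, each point used at most once), refit (ω, b) by least
squares, and stop when training MSE ≤ ε or the neuron budget is reached.
ε = 0 with a full budget interpolates; ε ≥ var(y) stays bias-only. The
output bias and identical member training data are assumptions the source
methodology leaves open.

The dual-RBF ensemble averages two members with independent (δ, ε); its
prediction is exactly the member mean, and on held-out data its RMSE never
exceeds the worse member's. Hyperparameters (δ₁, ε₁, δ₂, ε₂) are QPSO-
tuned with default bounds δ ∈ (0.1, 20], ε ∈ [10⁻⁴, 0.1]. The tuning
fitness uses reciprocal forms reconstructed from their published
description: robustness-only 1/max(R²cv5, 10⁻⁴) for boosting (which
seldom overfits) and balanced 1/max(R², 10⁻⁴) + 1/max(R²cv5, 10⁻⁴) for
RBF/SVR families; the 10⁻⁴ floor on non-positive R² terms keeps the
fitness finite. `fixed_params` (e.g. a `max_neurons` cap) can be merged
into every candidate so tuning stays tractable on larger tables. SVR,
dual-SVR and gradient boosting are adapters over scikit-learn NuSVR
(gamma = 1/(2·width²)) and xgboost; their internals are out of scope.

## Validation

R² is the squared Pearson correlation of observed and predicted (affine-
and sign-invariant); the coefficient of determination is available via
`mode="determination"` since external comparisons often assume it. CV
metrics are computed on the pooled out-of-fold prediction vector (one
number per model, matching single-row reporting), not averaged per fold.
Y-randomization refits with frozen hyperparameters on shuffled endpoints.
Golbraikh–Tropsha computes k = Σyŷ/Σŷ², k′ = Σyŷ/Σy², the through-origin
R²₀ quantities, and the pass rules 0.85 < k, k′ < 1.15 and ratio < 0.1.
Note that the ratio is very sensitive to prediction-variance shrinkage:
an MSE-optimal model on modest-SNR data compresses its predictions toward
the mean, which drives R′²₀ down and the ratio far above 0.1 even when
slopes are ≈ 1 — so on the synthetic benchmarks (weaker signal than a
strong literature model) the ratio criterion fails honestly while both
slope criteria pass. Topliss ratio (≥ 5) and overfit gap (< 0.3) are
plain arithmetic with boundary-inclusive and strict comparisons
respectively.

## Applicability domains

Leverage uses the raw (uncentered, no-intercept) training design,
h(x) = xᵀ(XᵀX)⁻¹x, with warning threshold h* = 3p/n — the form consistent
with the reference arithmetic (3·50/1458 = 0.1029); the 3(p+1)/n variant
is selectable. The IWD domain weights each descriptor column by its
(normalized, nonnegative) importance score, takes the weighted centroid C
as the arithmetic mean of the weighted rows, and thresholds the Euclidean
distance at u + 3σ_d of the training distances. Scores are normalized to
sum to 1 before weighting — harmless because classification is invariant
under positive rescaling (distances and threshold scale together) — and
with equal scores IWD reduces exactly to unweighted centroid distance.
Williams-plot rows standardize residuals by the *training* RMSE for both
train and test compounds, so the ±3 band is common to both sets.

## Synthetic data

The generator emulates a curated permeability descriptor table:
standard-normal descriptors in equicorrelated blocks (default block size
5, within-block r = 0.7 — redundant structural features), a sparse linear
signal over a support spread across blocks, an optional smooth
nonlinearity (tanh of the scaled linear score, default 30% of the signal
— bounded and smooth, the regime where RBF networks outperform MLR),
Gaussian noise (default 0.35 log units, on the order of reported
permeability-model CV errors), and degeneracy injections (constant
columns, missing cells in non-support columns, duplicate structures with
jittered endpoints). The noiseless signal is affinely mapped into the
interior of [−8, −3.5] with a margin of 0.05·range + noise_sd, leaving
the endpoint SD near the 0.6–0.8 log units typical of curated
permeability compilations, then noise is added and the result clipped to
the range. Planted outliers are shifted by outlier_shift_sd·noise_sd
toward the farther range bound, so the gross error survives clipping.
Ground truth records the support, the effective (post-mapping) linear
coefficients — exactly recoverable by MLR when noise and nonlinearity are
zero — outlier ids, and duplicate groups. Defaults mirror the scale of a
curated modeling set (n = 1864, p = 261); tests and the acceptance script
pass smaller explicit sizes.

What passing synthetic benchmarks shows: the algorithms recover planted
structure (outliers, support, clusters) under controlled SNR and respect
their stated invariants. What it does not show: performance on real
chemistry — real descriptor marginals are heavy-tailed and discrete,
activity cliffs exist, and assay noise is not homoscedastic Gaussian.

## Problem sizes and numerical choices

The acceptance script runs the full pipeline at n = 400 compounds ×
30 descriptors (support 8, 1% outliers at 10 noise SDs), Monte-Carlo
profiling at 300 iterations, SOM at 60 epochs, and RBF tuning with a
60-neuron cap — sizes chosen so statistics are stable while a single-CPU
run finishes in minutes; larger tables only tighten the reported
recoveries. Other numerical choices: tiny ridge (10⁻⁸) fallbacks for
rank-deficient least squares and Gram inverses; MDI importance defaults to
permute-and-predict without retraining (deterministic and fast; retraining
per scramble is available via `retrain=True`); negative importance drops
are clipped to zero; optimizer ties and RBF center ties break
deterministically (stable argsort / lowest row index).

## Known limitations

- The hybrid swarm operators are an interpretation (see above); published
  threshold/hyperparameter optima obtained with the original operator set
  will not be bit-reproduced.
- Model JSON serialization round-trips native families (MLR, RBF,
  dual-RBF) only; adapter families store their spec and must be refit.
- The SOM is an online implementation intended for a few thousand
  compounds; very large tables would want a batch SOM.
- The greedy RBF trainer refits a dense least-squares problem per added
  neuron; with n in the thousands and no neuron cap it becomes the
  pipeline's dominant cost.
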