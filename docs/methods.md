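# Methods

This note documents the models and procedures implemented in `nichemax`,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Grids, occurrences and areas

The analysis grid is a regular raster indexed row-major from the NW
corner.  Cells are half-open — `[x, x+Δx)` horizontally, `(y−Δy, y]`
vertically — so every point maps to exactly one cell and occurrence
deduplication is deterministic.  Deduplication keeps the first record per
occupied cell in input order (the choice of survivor is immaterial for a
presence-only model, but a fixed rule makes runs reproducible) and drops
records outside the grid or on masked cells, logging the counts.

Three grid families are supported.  Planar grids (equal-area projected,
e.g. EPSG:3035, or synthetic) have constant cell area `Δx·Δy` (m² → km²).
Geographic grids use the spherical approximation
`A = R²·Δλ·Δφ·cos φ_center` with `R = 6371 km`; at ~1-km resolution the
error of ignoring ellipsoidal flattening is well below the 10³ km²
rounding used in change tables.  Slope is computed from elevation with the
Horn 3×3 finite-difference kernel (the default in common GIS tools),
reported in degrees, with edge replication at borders; the slope of any
affine surface is `atan‖∇z‖` exactly, which the tests exploit.  Coarser
palaeoclimate rasters are brought onto the analysis grid by bilinear
interpolation of cell centers, with the nodata mask transferred by nearest
neighbour.  Sea/land masks for past scenarios with different coastlines
are treated as *inputs*: the package applies whatever mask the rasters
carry and does not attempt palaeo-coastline reconstruction.

Raster I/O uses ESRI ASCII grids: an exact, human-readable text format
that round-trips through version control and keeps test fixtures
inspectable.

## First-stage variable selection (RM criterion)

Climate layers are heavily collinear, so before modelling, the candidate
set is reduced to the k variables whose span best reproduces the full
correlation structure.  For a correlation matrix `R` over `p` variables
and a subset `K`,

    RM(K) = sqrt( tr(R_{·K} · R_{KK}⁻¹ · R_{K·}) / p ),

the matrix correlation between the standardized data and its orthogonal
projection onto span(K).  RM needs only `R`, not the raw data; it is 1 for
the full set, monotone non-decreasing under subset growth, and invariant
to reordering and sign flips — all asserted as property tests, with the
formula itself verified against an explicit data-space projection oracle.
`R` is estimated from a seeded random background sample (default 100,000
cells, or all cells when fewer are available); constant layers are
excluded with a warning.  Search is exhaustive up to 10⁶ subsets with a
deterministic name-order tie-break, falling back to greedy forward
selection above the guard.  Near-singular `R_KK` blocks are
ridge-regularized (+1e−10·I) with a warning rather than rejected, because
exact collinearity among climate summaries is common and the projection is
still well defined.

## The maximum-entropy model

**Objective.**  Over the landscape sample (presence ∪ background rows),
the fitter maximizes the concave regularized gain

    G(λ) = mean_presence(λ·f) − log Σ exp(λ·f) + log N − Σ_j β_j|λ_j|.

Gain 0 is the uniform distribution; positive gain measures how much more
concentrated presences are than uniform.

**Features.**  Defaults are linear + quadratic + hinge; product and
threshold classes can be switched on.  Each feature is min–max scaled to
[0, 1] on the training data and *clamped* to that range on projection, so
novel climates saturate instead of extrapolating.  Hinge knots sit at 8
equal quantiles of the background values per orientation (forward and
reverse), which bounds the feature count at `2 + 16` per variable while
leaving enough flexibility to bend response curves.  Zero-variance
variables keep a (constant) linear feature and skip nonlinear classes with
a warning.

**Regularization.**  `β_j = r · c_class · s_j/√m` with global multiplier
`r = 1` by default, per-class base constants 1.0 (hinge 0.5), `s_j` the
presence-sample standard deviation of feature j, `m` the presence count.

**Optimizer.**  Cyclic coordinate-wise proximal ascent: for each feature a
Newton-style step `λ_j ← soft_threshold(λ_j + g_j/h_j, β_j/h_j)` with
gradient `g_j = mean_presence f_j − E_q f_j` and curvature
`h_j = Var_q f_j`, backtracked (halving) until the gain does not decrease.
This handles the L1 penalty exactly (weights reach and stay at 0), keeps
the gain monotone, and is deterministic given the data.  Convergence is
declared when the relative gain change over a full cycle falls below
`tol = 1e−5`; the cycle cap is 2,500.  Accepted per-feature gain
increments are recorded as a trace for percent-contribution accounting.
Correctness anchors: with β = 0 and linear features the fitted landscape
expectations equal presence means (moment matching) to 1e−4 against a
brute-force 1-D solver; at any convergence point the KKT box condition
`|E_q f_j − mean_presence f_j| ≤ β_j` holds.

**Outputs.**  Raw scores `q(x) = exp(λ·f(x) − log Z)` sum to 1 over the
training landscape.  The cloglog suitability `1 − exp(−e^H q(x))`, with
`H` the entropy of the fitted distribution, maps scores monotonically to
[0, 1]; a zero-weight model scores `1 − e⁻¹ ≈ 0.632` everywhere.  AUC is
the Mann–Whitney statistic with midrank ties — the probability that a
random presence outranks a random background cell — reported as *training*
AUC and labelled as such, since no train/test split is performed.
Presence cells are part of the landscape normalization sample (union
convention, standard for this model family); the fitter drops exact
duplicate presence rows defensively, with a switch for data where
distinct cells can legitimately share values.

## Variable diagnostics and second-stage reduction

* **Percent contribution** credits each accepted positive gain increment
  to the updated feature's source variable(s), split equally for products;
  normalized to 100%.  It is path-dependent by construction and documented
  as describing the fitting trajectory.
* **Permutation importance** permutes one variable's column jointly across
  presence and background rows (one shared permutation; `reps` averages),
  re-evaluates the *fixed* model, and records the training-AUC drop,
  floored at 0 and normalized to 100%.  AUC drop (rather than gain drop)
  matches the statistic conventionally reported for this model family.
* **Jackknife** refits 2p submodels — each variable removed ("without")
  and each alone ("with only") — reporting gains as ratios to the full
  model's gain.

The aggregate rank is the unweighted mean of the four per-metric ranks
(midrank ties), with the "without" column ranked so that a LOWER
without-gain ratio means more important.  The combination rule and the
"without" direction are genuine design choices: the rank direction of
leave-one-out gain is ambiguous on its face, and this package resolves it
as above, ties broken by permutation importance and then by name.
Backward elimination drops the worst aggregate-rank variable one at a
time, refits, and continues while the refit training AUC stays at or above
`auc_floor × full AUC` (default 0.995).  The ranking is frozen from the
full model — not recomputed between drops — keeping the procedure a single
ranked sweep rather than a stepwise search; an audit log records every
attempted drop.  Degenerate floors behave sensibly: floor 0 reduces to a
single variable, floor > 1 returns the full set with a warning.

Response curves sweep one variable across its training range with all
other variables held at their background means, evaluating cloglog
suitability — a marginal, not a partial-dependence, curve.

## Scenario change accounting

Deltas follow a fixed direction convention: `current − past` for
palaeoclimate pairs and `future − current` for projections, so positive
always means expansion.  Accounting is threshold-free: any strictly
negative delta contributes its cell's area to contraction C, any strictly
positive delta to expansion E (an optional `min_delta` dead-band exists,
default 0), accumulated per class of current suitability with breaks
(0.03, 0.1, 0.2, 0.4, 0.6, 1.0), left-closed right-open, last closed.
Cells with current suitability below 0.03 are excluded as far outside the
species' plausible range.  Two exact invariants are enforced by test:
conservation (C + E + unchanged = eligible area) and antisymmetry
(swapping the map pair negates deltas and swaps C with E).  Suitability
class maps use breaks (0, 0.2, 0.4, 0.6, 0.8, 1.0) with labels
non-suitable/low/general/medium/high; boundary values go up a class.

The packaged `reference_change_areas.csv` stores a published per-class
C/E accounting table for six scenarios (two palaeoclimate, four future
pathway×horizon) together with its printed totals.  One printed row — the
LGM expansion total — does not equal the sum of its per-class entries
(1841 vs 2441); the file stores both and flags the row rather than
guessing which entry is the typo, and net-change arithmetic uses the
printed totals, which are what the accompanying net-change statements are
based on.

## Synthetic data and the recovery benchmark

The generator produces what the real inputs are not available to provide:
spatially smooth cross-correlated fields (white noise → Gaussian smoothing
→ Cholesky mixing to a target correlation → affine mapping to plausible
climate ranges), per-scenario affine shifts whose directions emulate the
target scenarios (past colder/wetter, future warmer/drier, more severe
along the pathway and horizon), and presences drawn without replacement
with probability proportional to a known truth
`s(x) = logistic(a₀ − Σ((v_j − opt_j)/tol_j)²)` over the informative
variables, with `a₀` bisected so mean suitability matches a target
prevalence (default 0.15 — sparse but not rare, typical of a widespread
tree at continental extent).  The niche is unimodal because the modelled
species' observed responses are; the logit-quadratic form means a
linear+quadratic feature basis can represent the truth exactly below
saturation, making recovery a fair but non-trivial test of the fitter.

Benchmark defaults: 64×64 planar grid with 1-km cells, six variables —
three informative (BIO1, BIO9, BIO16), one decoy correlated at 0.8 with an
informative variable (BIO18), two pure-noise — 500 presences, 2,000
background cells, smoothness 4 cells, all seeds recorded.  Against this
truth the fitted model achieves Spearman ≥ 0.9 between predicted and true
suitability over all cells, assigns < 5% permutation importance to each
pure-noise variable, and the backward elimination at floor 0.995 retains
every informative variable.

What passing does *not* show: the generator has no sampling bias or
detection model (real occurrence compilations are roadside- and
effort-biased), no coastlines or elevational structure, Gaussian marginals
rather than realistic climate distributions (e.g. bounded precipitation),
and planar geometry.  Recovery here demonstrates the estimator and
pipeline are correct, not that any real-data application is unbiased.

## Problem sizes and determinism

Default test and benchmark sizes (64×64 grid, ≤ 2,500 landscape rows,
~100 features) keep a full recovery run in seconds and the entire suite
around ten seconds on one CPU, which is the scale at which the oracles
(exhaustive enumeration, brute-force solvers) remain exact.  Every source
of randomness flows through recorded integer seeds; reruns of the pipeline
are byte-identical, which the tests assert on the CSV outputs.

## Known limitations

* No cross-validation or spatially blocked evaluation; AUC is training
  AUC by design and is reported as such.
* Percent contribution inherits the optimizer's path dependence; cyclic
  coordinate order makes it deterministic but still algorithm-specific.
* The greedy RM fallback is not guaranteed optimal (near-optimal on
  well-conditioned instances in the test sweep).
* Geographic areas use the spherical cos-latitude approximation.
* No logistic-output variant, no map cartography, and no reprojection
  beyond the two grid families.
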