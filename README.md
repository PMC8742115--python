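# nichemax

Presence-only maximum-entropy species distribution modelling (SDM) with
climate-scenario projection and threshold-free range-change accounting.

`nichemax` is aimed at ecologists and biogeographers who model where a
species *could* live from occurrence records alone — the typical situation
for compiled herbarium/atlas data such as the Mediterranean strawberry tree
(*Arbutus unedo* L.), where presences are abundant but true absences are
unknowable.  The package covers the full workflow: gridding and
deduplicating occurrences, two-stage environmental-variable selection,
fitting a regularized maximum-entropy model, projecting it onto past and
future climate rasters (glacial/mid-Holocene palaeoclimates, RCP emission
pathways), and summarizing range contraction and expansion without ever
binarizing suitability at an arbitrary threshold.

## The model

Given presence cells and a background sample of the landscape, the model
estimates the distribution *q* over cells that maximizes entropy subject
to matching the presence-sample feature means, which is equivalent to
maximizing the L1-regularized training gain

```
G(λ) = mean_presence(λ·f) − log Σ_landscape exp(λ·f) + log N − Σ_j β_j |λ_j|
```

over feature weights λ.  Features *f* are transformations of the
environmental layers (linear, quadratic, hinge by default; products and
thresholds optional), each min–max scaled to [0, 1] on the training data
and clamped to the training range when projecting onto novel climates.
The per-feature penalty is `β_j = r · c_class · s_j/√m` with `r` the global
regularization multiplier (default 1), `s_j` the presence-sample standard
deviation and `m` the presence count.  The objective is concave and is
maximized by cyclic coordinate-wise proximal (soft-threshold) ascent, so
the gain is non-decreasing and the L1 penalty is handled exactly.  Reported
suitability is the cloglog transform `1 − exp(−e^H · q(x))` with `H` the
entropy of the fitted distribution; model discrimination is summarized by
the rank-based AUC (Mann–Whitney, midrank ties).

Variable handling is two-stage.  First the candidate layers are reduced to
the k-subset maximizing the RM matrix-correlation criterion
`RM(K) = √(tr(R_{·K} R_{KK}⁻¹ R_{K·})/p)` computed from a background
correlation sample (exhaustive search, greedy above an enumeration guard).
Second, four importance diagnostics — percent contribution, permutation
importance, and jackknife "without"/"with only" gain ratios — drive a
backward elimination to the smallest submodel retaining at least 99.5% of
the full model's training AUC.

Scenario change is threshold-free: per-cell suitability differences
(`current − past` for palaeoclimate pairs, `future − current` for
projections, so positive always means expansion) are aggregated into
contraction/expansion areas per class of current suitability (breaks 0.03,
0.1, 0.2, 0.4, 0.6; cells below 0.03 excluded), reported in 10³ km².

A synthetic-data module generates correlated, spatially smooth
environmental fields, scenario shifts (warming/drying), and presence
samples from a known unimodal niche, so the entire pipeline is testable
against ground truth.

## Worked example

Fit a model on a synthetic landscape with a known niche and account for
range change under a severe warming scenario:

```python
from nichemax.synthetic_data import (simulate_env, default_truth, calibrate_intercept,
                                     true_suitability, sample_presences,
                                     apply_scenario_shift, DEFAULT_SCENARIO_SHIFTS)
from nichemax.grid_io import dedup_to_grid, cell_areas
from nichemax.maxent_core import fit_maxent, predict, sample_background
from nichemax.scenario_change import suitability_delta, change_accounting, net_change

stack = simulate_env(seed=0)                       # 64x64 grid, 6 layers
truth = calibrate_intercept(stack, default_truth(0))
occ = sample_presences(true_suitability(stack, truth), 500, seed=1)
occ = dedup_to_grid(occ, stack.grid, stack.nodata_mask)

bg = sample_background(stack, 2000, seed=2)
model = fit_maxent(stack.values_at(occ.cells()), stack.values_at(bg), seed=0)
print(f"training gain: {model.training['gain']:.3f}")
print(f"training AUC:  {model.training['train_auc']:.3f}")

current = predict(model, stack, "cloglog")
future = apply_scenario_shift(stack, DEFAULT_SCENARIO_SHIFTS["synthetic-rcp85-2070"],
                              "synthetic-rcp85-2070")
delta = suitability_delta(current, predict(model, future, "cloglog"),
                          "current-to-future")
table = change_accounting(current, delta, cell_areas(stack.grid))
print(table.to_frame().to_string(index=False))
print(f"net change: {net_change(table):+.3f} thousand km2")
```

Output:

```
training gain: 0.425
training AUC:  0.805
            scenario    class  contraction_1e3km2  expansion_1e3km2
synthetic-rcp85-2070 0.03-0.1               0.083             0.249
synthetic-rcp85-2070  0.1-0.2               0.156             0.186
synthetic-rcp85-2070  0.2-0.4               0.259             0.375
synthetic-rcp85-2070  0.4-0.6               0.359             0.328
synthetic-rcp85-2070     >0.6               0.910             0.168
net change: -0.461 thousand km2
```

The gain (0.425) says presences are about e^0.425 ≈ 1.5× more concentrated
than a uniform landscape distribution; the AUC (0.805) that a random
presence outranks a random background cell ~80% of the time.  The table
reads like a range-change ledger: under the warming scenario the
highest-suitability class (> 0.6) loses 0.910 thousand km² and gains only
0.168, and the landscape shows a net contraction of 461 km² — suitable
habitat is lost fastest exactly where the species is currently best off.

The same workflow runs from the shell:

```bash
nichemax simulate --out data/ --seed 0
nichemax run-all --out run/ --seed 0          # full pipeline + manifest
nichemax fit --occurrences data/occurrences.csv --stack data/current \
             --background 2000 --seed 0 --out model.json
```

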