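# Methods

## Scope and model of the pipeline

`nucleoquant` implements a targeted quantitative workflow for a panel of
11 urinary nucleosides and deoxynucleosides (Pse, U, Ino, 3mU, 2dG, 2mG,
8OH2dG, 6mA, 2,2dmG, 5-MTA, MTA) measured by LC-MS/MS in dynamic-MRM
mode with 8-bromoguanosine (8BrG) as internal standard. The pipeline
covers four stages: weighted calibration with sensitivity limits, the
EMA/FDA bioanalytical validation battery, creatinine-normalized
quantification of study samples, and a hierarchical longitudinal model
for fold changes around tumor resection. A synthetic-study generator
produces every input the pipeline consumes, so the whole chain is
testable without instrument data.

Wet-lab concerns (sample preparation, chromatography and instrument
control, vendor peak integration, the creatinine assay itself) are out
of scope; the pipeline starts from integrated peak areas and externally
measured creatinine.

## Calibration

Calibration regresses the relative response `y` (quantifier area / IS
area) on the nominal concentration `x` (µM) by weighted least squares
with weights `1`, `1/x`, or `1/y` per analyte. Weighting choices follow
the panel's reference table (`1/y` for most analytes, `1/x` for the
nano-scale ones: 2dG, 8OH2dG, MTA). Numerical choices:

- Weights are normalized to mean one. Estimates are invariant to weight
  scaling, and normalization keeps the reported standard errors,
  residual SD (`Sxy = sqrt(weighted SSE / (n - 2))`) and confidence
  intervals in the response units of the unweighted problem; it also
  yields the clean equivariance property that scaling all responses by
  `k` scales slope, intercept, their SDs and `Sxy` by `k` while leaving
  back-calculated concentrations and LOD/LOQ unchanged.
- `1/y` uses the observed responses in a single pass (no IRLS
  refinement), matching common chromatography-software behavior.
- Replicates enter as separate points (no averaging), preserving
  degrees of freedom.
- 95% intervals use the two-sided t distribution with `n - 2` df.
- Sensitivity: `LOD = 3.3 · SD(intercept) / slope`, `LOQ = 10 ·
  SD(intercept) / slope` — the standard convention for curve-based
  limits. Applied to the panel's printed slope / intercept-SD pairs it
  reproduces 20 of the 22 printed LOD/LOQ values within 15%; the two
  exceptions (the U and 6mA LODs) are printing inconsistencies in the
  reference table and are stored as printed, not "fixed".
- Back-calculation `(y - intercept)/slope` never censors: results below
  LOQ/LOD or above the calibrated range carry flags, and downstream
  stages decide handling.

## Validation battery

All pass rules are pure threshold functions with closed intervals (a
value exactly on the boundary passes):

| check          | statistic                                            | rule            |
|----------------|------------------------------------------------------|-----------------|
| accuracy       | 100 · mean(measured)/nominal                         | ±15% (±20% LLOQ)|
| precision      | 100 · SD(n−1)/mean                                   | ≤15% (20% LLOQ) |
| matrix effect  | CV of IS-normalized matrix factors                   | ≤15%            |
| stability      | 100 · mean/nominal per condition and time/cycle      | within ±15%     |
| ion ratio      | 100 · qualifier/quantifier area                      | panel window    |
| ISR            | 100 · \|a−b\| / mean(a,b) per reanalyzed pair        | ≤20% in ≥2/3    |

Decisions where the procedure was underdetermined:

- ISR uses the mean-denominator percent difference (the guideline form);
  the evaluator reports the maximum difference and the count exceeding
  20% in addition to the pass fraction, because strictness conventions
  at the margin vary (the packaged reference matrix has 8 of 165 entries
  above 20.0%, maximum 34.6%, pass fraction 95.2%).
- Within-run statistics use one run's replicates; between-run statistics
  pool all runs' replicates (rather than run means) — the simpler
  reading of a four-run design.
- The ion-ratio window is the per-analyte printed uncertainty range;
  a generic ±20% band around the expected ratio applies only when a
  panel entry has no printed range.
- Selectivity is a threshold screen (blank response ≤ 20% of the LLOQ
  response) rather than a visual comparison.
- Report ranges are rounded half-up to one decimal, applied to the
  decimal expansion of the stored double. This single rule reproduces
  every printed range endpoint of the reference tables, including pairs
  that look mutually inconsistent in print (92.45 → 92.5 but
  97.35 → 97.3): the stored double for 97.35 sits just below the half.

## Quantification

Study-sample concentrations are back-calculated per analyte and divided
by urinary creatinine (mM), giving µmol analyte per mmol creatinine —
the standard correction for urine dilution. The package core works in
µM and mM throughout; the reference study table's alternate nano-scale
unit footnote (whose denominator unit is ambiguous as printed) is
carried as a flag, not interpreted. Ion-ratio failures and below-LOQ
results are flagged, never dropped, and the output has exactly one row
per (study sample × analyte) peak row.

## Longitudinal model

For the log normalized concentration of metabolite *m* in sample *s* of
patient *p*:

    logDV ~ MET + TIME + MET:TIME + (per-patient metabolite vector) +
            (per-sample intercept),   sigma ~ MET

- Fixed effects use reference coding (baseline time "pre"; reference
  metabolite first alphabetically — fold changes are invariant to that
  choice, which a test verifies).
- The per-patient random vector has one component per metabolite with
  an unstructured covariance (a reparameterization of the
  intercept-plus-contrasts form with correlated slopes); a diagonal
  option exists for large panels.
- The per-sample intercept, shared by all metabolites of a urine
  sample, absorbs residual between-sample diuresis variation left after
  creatinine normalization, protecting the time effects from dilution
  confounding. A test injects per-sample shifts and verifies they move
  the sample-intercept SD, not the fold changes.
- Residual SDs are per metabolite (log link internally), the
  distributional-regression reading of `sigma ~ MET`.
- Sparse late follow-up (10/8/7/3/2 samples from two weeks on) is
  handled by pooling all post-24h time points into one "post" level by
  default; `pooling="none"` keeps all seven labels.
- Natural logs are used for logDV; fold changes exponentiate the same
  base, so results are base-invariant.
- Rows flagged below-LOQ are included with their back-calculated values
  by default (`include_flagged=False` excludes them); no substitution
  rule is imposed.

Because every level is Gaussian, the random effects integrate out
analytically: the marginal likelihood is multivariate normal and block
diagonal by patient (blocks of at most time-points × metabolites rows),
evaluated by per-block Cholesky factorizations. The default backend
maximizes the REML criterion over the variance parameters (log-Cholesky
parameterization of the patient covariance, log SDs elsewhere) with the
fixed effects profiled out by GLS; REML is the standard small-sample
choice and improves variance-component calibration. L-BFGS-B is polished
by a derivative-free restart if it reports non-convergence;
non-convergence is flagged on the fitted object, never silent. Wald
intervals for fold-change contrasts use the t distribution with
`n − rank(X)` df.

The `bayes` backend samples the same marginal likelihood with an
affine-invariant ensemble sampler (emcee) under independent normal(0, 1)
priors on the unconstrained variance parameters — weakly informative on
SD scales of order one, appropriate for log-concentration data — and
draws fixed effects from their conditional Gaussian per retained draw;
split-chain R-hat across walkers (< 1.05) gates the convergence flag.
This sampler-over-marginal design was chosen over a full probabilistic-
programming fit as the lightest-dependency route to posterior intervals;
the maximum-marginal-likelihood path remains the default because it is
deterministic and fast enough for replicate simulation studies.

Fold changes for a typical subject and typical diuresis set all random
effects to zero: `exp(TIME + MET:TIME)` per metabolite and post-baseline
time level. The forest table annotates whether each 95% interval lies
entirely outside the 0.8–1.25 band (roughly a ±20% change). The
reference (pre vs pre) contrast is identically 1.

## Synthetic-study generator

The generator draws from exactly the model above, so the simulator and
the likelihood agree by construction. Defaults are the study conditions:

- design: 53 patients, samples per time point 53/50/10/8/7/3/2 (133
  total) across pre, 24 h, 2 wk, 3/6/9/12 months; dropout is the
  designed counts (first *k* patients retained), not a missingness
  model;
- baselines: log of the published pre-surgery mean normalized
  concentrations per analyte (codes outside the reference panel start
  at a unit baseline);
- effects: fold 1 everywhere except MTA 0.5× and Ino 1.7× at 24 h —
  the magnitudes the study design is meant to detect;
- variance components (log scale): between-patient SD 0.3 with
  correlation 0.5 across metabolites, per-sample diuresis SD 0.25,
  residual SD 0.4 — modest values typical of urinary panels;
- creatinine: log-normal, median 10 mM, 50% CV (the physiological
  range of spot urine);
- calibration batches: truth from the published slope/intercept table,
  eight geometrically spaced levels over the published range, noise SD
  proportional to response for 1/y analytes and to sqrt(concentration)
  for 1/x analytes, so each published weighting scheme is approximately
  optimal for its analyte;
- QC batches: nominal × (1 + run bias + replicate noise), run bias
  shared within a run;
- ISR pairs: shared log-normal truth, independent measurement noise,
  an optional outlier fraction pushed past the 20% rule.

All randomness flows from a single integer seed through `SeedSequence`
spawning, giving platform-independent reproducibility. Truth records
(every latent draw) accompany each simulated table for recovery tests.

What the generator does **not** emulate: chromatographic drift and
carry-over, non-Gaussian heavy-tailed outliers, missingness that is
informative about concentration, demographic covariates, and
between-batch calibration drift. Passing recovery tests therefore shows
that the estimator is correct under its own assumptions at the study's
size and noise level — not that those assumptions hold for any given
instrument's data.

## Problem sizes used in tests and the acceptance script

Replicate simulation studies use a three-metabolite reduced panel
(Pse, Ino, MTA) at the full 53-patient/133-sample design with 20
replicates — a panel size chosen so a full covariance fit stays
comfortable on a single core while preserving the design's time
structure and both targeted effects. Consistency checks that need large
samples (residual-SD calibration, QC CV recovery) use dedicated large
synthetic batches (10,000 rows / 1,000 replicates).

## Known limitations

- The printed reference tables contain internal inconsistencies (two
  LODs, one duplicated confidence interval, a results-text matrix-effect
  range that disagrees with its table, an ambiguous unit footnote).
  Fixtures keep the tables as printed and the discrepancies are
  documented where they surface.
- Reproducing the published clinical fold-change estimates is not
  possible from this package alone: the underlying patient-level data
  are not publicly deposited. The longitudinal model is validated by
  parameter recovery on synthetic studies of the same design instead.
- Wald intervals for the REML backend condition on the estimated
  variance parameters and can be slightly anticonservative in very
  small panels; the Bayesian backend propagates that uncertainty at
  higher compute cost.
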