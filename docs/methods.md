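# Methods

## Scope and data model

cortiflow analyses long-format tables of salivary cortisol measured on up to
seven occasions per day (S1 at awakening, S2/S3 at +15/+30 min, S4–S6 at
10:30/12:00/17:00, S7 at bedtime) across three pregnancy stages (early, mid,
late).  Concentrations are in µg/L and modelled on the `ln(x + 1)` scale; a
`×10` helper is the only supported unit conversion (µg/dL inputs).  Bedtimes
past midnight are coded as clock hours > 24 so within-day times stay
monotone; all model time axes use *time since awakening* in decimal hours.

## Quality control

Rules run in a pinned order; every removal is logged and the ledger must
conserve the sample count:

1. subject exclusions — corticosteroid treatment; all date records missing;
2. truncation of raw values below 0.05 µg/L (the assay's functional
   sensitivity) to 0.05 — a modification, not a removal;
3. duplicate assessment days within a subject-stage resolved by (a) more
   non-missing samples, (b) fewer protocol violations, (c) fewer day-specific
   outliers (> 2 SD of the day's own log-scale mean), (d) earlier date — a
   total order, so resolution is input-order independent;
4. illness days removed wholesale; S1 removed when the woman rose before
   sampling; S2/S3 removed when taken strictly more than 60 min after
   awakening; S4 removed strictly within the first 60 min (exactly 60 min is
   compliant on both sides — literal reading of the rules);
5. duplicate aliquots: CV = two-point sample SD (divisor n−1) over the mean;
   CV > 0.25 removes the sample, otherwise aliquots are averaged; lone
   aliquots are kept with undefined CV;
6. missing clock times imputed — protocol times for S2–S6 (awakening +15/+30
   min, 10:30, 12:00, 17:00), stage-specific occasion medians for S1/S7.
   A rule-relevant sample missing its time is imputed before the rule is
   applied.  A median-imputed S1 may precede the diary awakening time; its
   time since awakening is floored at zero (a recorded time may not be);
7. `ln(x + 1)` transform, then two-sided winsorization at mean ± 4 SD within
   each pregnancy stage, fences computed once on the pre-replacement
   log-scale distribution (side and timing are conventions; both are pinned
   here for reproducibility);
8. minimum-sample rules: ≥ 2 samples per retained subject-stage, then ≥ 3
   per retained subject.

Running QC on its own surviving raw rows reproduces the analysis table
exactly (idempotence), because winsorization and imputation are deterministic
functions of the retained raw values.

## Synthetic cohorts

The generator draws, on the log scale,

    y = fixed-effect mean + CAR bump + c0 + c1·t + d(person×stage)
        + plate effect + ε_day(t),

with day residual vectors correlated as `φ^|Δt|` (per-occasion SD
multipliers optional), inverts the transform to µg/L (clipping at zero —
the assay cannot report negative concentrations), and measures each sample
in duplicate with multiplicative lognormal error whose scale is calibrated
so the expected two-point CV equals `duplicate_cv`
(`s = duplicate_cv·√(π/2)`).

Default parameters are the study conditions the package emulates: 600
subjects; attendance patterns matching the observed stage sizes (~60/79/73 %
per stage; 38/36/26 % attending 3/2/1 stages); awakening ~ N(7.3, 1.15²) h
truncated to [4, 12]; bedtime ~ N(23.1, 1.1²) truncated to [20, 27];
fixed effects and variance components from the final published diurnal model
(plate 0.001, person 0.048, slope 0.008, person-stage 0.019, residual
0.189).  The printed intercept–slope "covariance −0.75" is infeasible as a
covariance given those variances and is read as a correlation, giving
cov ≈ −0.0147.  The per-hour residual autocorrelation φ and the occasion
multipliers are not published; φ defaults to 0.4 (a mid-range value for
saliva sampled at sub-day lags) and the multipliers to 1.  Covariate
prevalences follow the cohort description (BMI 23.82 ± 3.93, age
34.63 ± 4.82, hypertensive disorders 5.2 %, GDM 20.8 %, primiparity 51 %,
chromosomal-testing referral 44 %, lifetime mental disorder 12 %,
corticosteroid use 2.2 %; smoking 6 % — not reported, set to a typical
Nordic-cohort value).  The mean evaluator also accepts `bmi`, `gdm` and
`hypertensive` terms so exposure effects can be planted for power studies.

The CAR is an additive log-scale bump at S2/S3 whose sign is drawn per
person-stage: negative (declining CAR) with probability `car_absent_frac`
(default 0.64, the published mid-pregnancy absence rate).  With low noise
the realized absent fraction equals the planted one; with
`car_absent_frac = 0` the absent fraction is strictly decreasing in
`car_amplitude`, which is the property the tests target.

Protocol violations are planted at configured rates and recorded in an exact
truth ledger.  Rates are per sampling day for day-level rules (rising before
S1 0.076, illness 0.009, late S2/S3 0.007, early S4 0.012 — chosen so the
per-sample removal fractions match the published QC accounting), per sample
for missing times (0.002) and discordant duplicates (0.016), per
subject-stage for duplicate days (0.017) and per subject for missing dates
(0.009).  At most one day-level violation is planted per day, sample-level
violations only on violation-free days, and discordant duplicates only above
the truncation floor, so each planted event triggers exactly one QC rule and
the QC ledger can be required to equal the truth ledger *exactly*, not
statistically.

What the generator does not emulate: gestational-week-continuous hormone
trajectories, placental CRH dynamics, register-linkage artefacts, or any
dependence of compliance on cortisol level.  Passing tests therefore
demonstrate correctness of the pipeline and estimators under the stated
generative model, not validity of the scientific conclusions on real data.
With the published components the random slope implies a wide log-scale
spread at bedtime (slope SD ≈ 0.09/h over ~16 h), so more raw values fall
below the truncation floor than in the real cohort; analyses of estimator
behaviour therefore use the direct log-scale generator
(`simulate_analysis_table`), which skips the raw-scale inverse transform.

## Mixed-model engine

The marginal covariance is `V = Σ_r σ²_r Z_r Z_rᵀ + R(φ, σ², multipliers)`
with R block-diagonal over person-stage day series and
`corr = φ^|Δt hours|`.  One likelihood evaluation factors V by subject
blocks (≤ 21 rows) and handles the crossed plate intercept by a Woodbury
correction with a plate-by-plate inner solve, so study-size fits (600
subjects, ~8000 rows) take seconds.  The restricted likelihood uses
Harville's form including the `−½ log|XᵀX|` term, so it is invariant to the
fixed-effects basis; the residual variance and β are profiled out and the
remaining parameters are optimised on log-variance-ratio / atanh-correlation
/ logit-φ scales by bounded L-BFGS-B with three documented restarts
(baseline, all ratios ×e^1.5, ×e^−1.5).  Finite-difference gradients are
used; the scaled gradient norm at the optimum is reported and tested to be
< 1e-4.  Variance ratios are bounded in [1e-7, 1e4]; a ratio at the lower
bound is reported as a boundary estimate pinned at 1e-10 with a
`BoundaryWarning`.  Heterogeneous AR(1) fixes the S1 multiplier at 1 for
identifiability.  Two samples at identical times within one series make a
day block singular and raise; upstream QC guarantees strictly increasing
times.

AIC is reported as `−2ℓ + 2k` with `k` = fixed effects + optimised variance
parameters + the profiled σ².  Denominator degrees of freedom for t tests
use a containment-style two-level rule: columns varying within subjects test
against `n − n_subjects − p_within`, between-subject columns against
`n_subjects − p_between`.  This differs from reference implementations'
exact rules; printed p-values are descriptive and nothing in the acceptance
checks depends on them.

Structure selection climbs random-intercepts → + random slope →
+ continuous AR(1) → + heterogeneous AR(1) under REML, keeping a rung only
if it lowers AIC *and* the nested LRT rejects at P < .05 (plain χ², as in
the original procedure; no boundary-mixture correction, which makes the
variance tests conservative).  Timing covariates (awakening time, season and
their stage/time interactions) are pruned family-wise, highest-order first,
by ML likelihood-ratio tests, with marginality protecting the parts of any
retained interaction; variance structures are compared under REML only with
identical fixed effects.

## Indices and ICCs

AUCg/AUCi use trapezoids over the actual recorded times (a config switch to
protocol-nominal spacing exists because the published time base is
ambiguous; actual times are the default since times were recorded).  AUCi is
referenced to the S1 value; `AUCi ≤ 0` classifies the CAR as absent.
"Complete cases" means all 3 (AUCi) or all 7 (AUCg) occasions.  Morning peak
ties resolve to the earliest occasion.  Cross-stage agreement of the indices
uses the two-way consistency, single-rater ICC (pingouin's ICC(C,1)).

Model-based stability ICCs exclude the plate variance (a batch artefact):
`ICC_throughout = var_person / (var_person + var_slope + var_stage +
var_residual)` and `ICC_within_stage` adds slope and stage variances to the
numerator.  This decomposition reproduces the published 0.12/0.75 (morning)
and 0.18 (diurnal) values from the published components; the published
within-stage diurnal value (0.26) depends on an unpublished handling of the
intercept–slope covariance and evaluation time, is sensitive to it
(0.25–0.28), and is deliberately not an anchor.  `formula_id` records the
choice so alternatives can be swapped in.

## Complication testing

Each exposure (grand-mean-centered prepregnancy BMI; hypertensive disorders
pooled as one indicator; GDM) is tested in a separate model by three nested
augmentations of the final morning/diurnal model: main effect, × time, and
× time × stage (with exposure × stage included for marginality — published
tables list only the interaction rows).  The adjusted repeat adds
chromosomal-testing group, age, parity, smoking, lifetime mental disorder
and education.  BMI stratification (≥ 25 vs < 25, boundary in the high
stratum) reuses the pooled covariance structure rather than re-running
selection per stratum.

## Problem sizes in the test suite

Simulation-backed checks run at the sizes the package treats as its study
scale: variance-component recovery over 20 seeds × 600 subjects (components
within 3 Monte-Carlo SEs of truth; simulated with zero CAR bump and fitted
on full days so the fixed-effect mean is correctly specified — the
peak-to-bedtime row filter selects on the response and is a design feature,
not an estimator property); type-I error of the step-2 exposure × time test
over 200 seeds × 60 subjects against a 99 % binomial envelope around 5 %;
ladder selection over 50 seeds × 80 subjects (majority recovery of the
generative slope + AR(1) structure); QC-vs-truth ledger equality on three
120-subject cohorts.  The full suite runs in about six minutes on one CPU.

## Known limitations

Gaussian responses only; no crossed random slopes, sandwich standard errors
or small-sample df corrections; one ingestion dialect (long-format CSV); the
heterogeneous-AR(1) multipliers for occasions absent from a model window are
inert but still counted as parameters in AIC/LRT df, making the
heterogeneous rung slightly harder to select on morning-only data.
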