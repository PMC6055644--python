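# Methods

## The statistical problem

Enteric CH4 production of a lactating dairy cow (g/day) is modelled as a
linear function of farm-measurable covariates — dry matter intake (DMI,
kg/d), gross energy intake (GEI, MJ/d), diet composition (CP, EE, NDF, ash
as % of DM), milk yield and composition (MY kg/d, MF %, MP %; or
energy-corrected milk, ECM), and body weight (BW, kg).  The same machinery
applies to CH4 yield (g/kg DMI) and intensity (g/kg ECM).  Records come
from many studies run by many research groups, and group- and study-level
idiosyncrasies (measurement technique, protocol, climate, management)
induce strong within-cluster correlation that a pooled regression would
ignore.  The package therefore fits

    Y = β0 + β1 X1 + … + βn Xn + S_i(R_j) + R_j + ε,

with independent Gaussian random intercepts for research group R_j
(variance σ²_R) and study nested in group S_i(R_j) (variance σ²_S), and a
residual ε (variance σ²).  Estimation is restricted maximum likelihood via
statsmodels `MixedLM` (random group intercept plus a study variance
component), which is deterministic given the data; variance components are
bounded at zero and boundary fits are reported, not raised.  A constant
response short-circuits to the exact degenerate solution.  When every
study contributes a single record, σ²_S and σ² are not separately
identifiable and the result carries an explicit flag rather than an
arbitrary split.

## Derived quantities and constants

* ECM (3.5 % fat) = 12.95 × fat yield + 7.65 × true-protein yield + 0.327
  × milk yield, with true protein = 0.93 × milk crude protein.  The 0.93
  factor lives inside the formula, not on the record.
* CH4 energy density 0.05565 MJ/g is a fixed physical constant used by the
  Ym conversion (Ym = 100·CH4·0.05565/GEI, plausibility window 0–15 %)
  and the IPCC Tier 2 comparators (Ym·GEI)/0.05565 with Ym = 0.065 (2006)
  or 0.060 (1997).
* Percentages are stored in percent units (4.1 means 4.1 %); formulas
  divide by 100 internally.  Missing values are first-class (`None`/NaN)
  and propagate through derived quantities instead of raising.

## Screening and filtering

Outliers are screened on the two derived ratios (yield, intensity),
region by region, with Tukey fences Q1 − k·IQR, Q3 + k·IQR, k = 1.5.
Quartiles use linear interpolation at position p·(n−1) (the common
"type 7" convention); exact fence values on small samples depend on this
choice, so the tests pin it.  A record is flagged when either ratio falls
strictly outside its fence (union rule; a sequential yield-then-intensity
variant is available).  Screening is single-pass — fences are not
recomputed after removal — and regions with fewer than four records are
skipped with a warning, since quartiles of two or three points are not
meaningful fences.  Complete-case filtering takes an explicit required
field list (default: response plus all twelve measurement fields), and the
method whitelist keeps chamber, GreenFeed and SF6 records only.

## Variable selection

Candidate subsets are scored with BIC = n·ln(SSE/n) + ln(n)·p (natural
logarithm; p counts the intercept plus slopes), and every non-empty
subset of the candidate list is scored (capped at 12 candidates = 4,095
fits).  SSE comes from an ordinary-least-squares fit of each subset by
default — the form in which the score is written; an `engine="lmm"`
option scores subsets by the conditional residual SSE of the mixed model
instead.  Collinearity is handled by iterative VIF pruning: VIF_j =
1/(1−R²_j) from regressing predictor j on the rest with an intercept,
removing the single largest offender above 5 per round; exact
collinearity reports VIF = ∞, and ties are resolved by keeping the
predictor that appears earlier in the candidate list.  Pruning precedes
the subset search by default; checking the selected subset afterwards is
available (`vif_order="after"`) since either reading of the workflow is
defensible.

## Cross-validation and metrics

Model evaluation uses leave-one-study-out CV: folds are the studies
themselves, each fold is predicted by a model fitted on all other
studies, and predictions for held-out records use fixed effects only —
the random intercepts of unseen studies have expectation zero, which
mirrors deployment on a new farm.  (Reusing a training group's intercept
BLUP is available behind a flag.)  Held-out predictions are pooled across
folds before computing metrics, not averaged per fold.  A fold whose REML
fit does not converge falls back to OLS and is counted in the result.
Scoped evaluation filters the pooled predictions by region set
(`intercontinental` = EU + US + AU, `EU`, `US`, or any custom set).

All standard deviations in the metric suite are population (denominator
n) SDs.  That convention makes

    MSPE = (P̄ − Ō)² + (Sp − r·So)² + (1 − r²)·So²
           (mean bias)  (slope bias)   (random error)

an exact identity, which the tests assert to 1e-10; sample (n−1) SDs
would break it.  RSR = RMSPE/So uses the same So.  Lin's concordance is
CCC = r·Cb with Cb = ((v + 1/v + u²)/2)⁻¹, v = So/Sp,
u = (P̄−Ō)/√(So·Sp).  Statistics that are undefined for constant vectors
(r, SB, RSR, CCC) are reported as an explicit `None` state, never a
silent zero or NaN.  Mean and slope bias are also exposed as percentages
of MSPE, the convention used in comparison tables.

## Equation registry

The 51 published prediction equations (11 intercontinental production
categories, 11 EU, 11 US, 7 yield, 9 intensity, 2 IPCC comparators) are
bundled with coefficients and standard errors exactly at printed
precision — the registry is a transcription layer and never re-derives
values.  Equation 29 is published identically to equation 27 (the
diet-composition selection retained only DMI and NDF); both ids are kept
for traceability.  The GEI-based equations carry an energy transform flag
(division by 0.05565).  Standard errors are stored for reference only; no
prediction intervals are propagated from them.  `best_available` picks,
among equations whose predictors are all present, the one with the most
predictors, breaking ties by a documented category-preference order; the
available set is taken literally (include `"ecm"` explicitly to admit
ECM-based equations).  Regional yield/intensity equations that were not
published in the main tables are not bundled; the JSON registry schema
accepts user-supplied equations.

## Synthetic herd generator

The generator emulates the structure of the real multi-country database:
cows nested in studies nested in research groups, covariates drawn from
truncated normals (rejection sampling within [min, max]) whose mean, SD
and range reproduce the published per-region summaries for the EU, US and
pooled data sets, an explicit dmi–my correlation (default 0.6, a
bivariate-normal construction), gei derived as dmi × ge_diet, and
CH4 = β0 + Σ βx + group + study + residual effects, floored at 1 g/day.
Default truth: the published all-variables production coefficients
(−60.5 + 12.4·DMI − 8.78·EE + 2.10·NDF + 16.1·MF + 0.148·BW) with
group/study/residual SDs of 20/25/40 g/day, chosen so regional CH4
coefficients of variation land in the ~23–33 % range reported for real
data.  Randomness is split into counter-based substreams keyed by (seed,
group, study), so enlarging one study never perturbs another's draws and
a config reproduces its dataset bit-for-bit.

What the generator does **not** emulate: covariate dependence beyond the
dmi–my link (the published summaries constrain only marginals),
measurement-method biases, lactation-stage or breed effects, and
non-Gaussian residuals.  Passing recovery tests therefore demonstrate the
estimation machinery, not the realism of any particular covariance
structure in field data.

## Problem sizes and numerical choices

The test suite and the reproduction script run at desk scale: recovery
uses 50 replicates of 6 groups × 10 studies × 20 cows (1,200 records);
selection consistency uses 50 replicates at n = 2,000 with a sparse
two-variable truth among six candidates; CV fixtures use 3 × 3 × 8
herds.  These sizes give stable pass rates (each fixed effect within 2
estimated SEs of truth in ≥ 90 % of replicates; the true subset selected
in ≥ 80 %) while keeping the whole suite under half a minute.  REML uses
L-BFGS with a Powell fallback and a Nelder-Mead retry; optimizer
non-convergence is flagged on the results object and, inside CV, triggers
a per-fold OLS fallback rather than aborting.

## Known limitations

* Fixed-effect SEs from REML are not small-sample corrected (no
  Kenward-Roger); with very few groups the intercept SE can be
  optimistic.
* The all-subsets default scores subsets by OLS SSE, so cluster
  correlation influences selection only through the final mixed-model
  fit, not the score; `engine="lmm"` trades 2^k REML fits for coherence.
* No random slopes, crossed random effects, or heteroscedastic residuals
  by measurement method.
* `best_available` never auto-selects the IPCC comparator rows.
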