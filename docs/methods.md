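# Methods

## Data model and exclusions

The unit of analysis is a specimen: sex (F/M, no unknowns survive
ingestion), age at death in decimal years (≥ 0; infant ages like 0.1 are
taken as-is, no month parsing), lateral angle in degrees (open interval
0–90, may be missing) and biauricular breadth (AUB) in mm (open interval
40–180, may be missing). Missing values are empty cells; sentinel codes
are rejected at ingestion so they can never masquerade as measurements.
Collections outside the four named ones map to `other` with a warning so
the pipeline generalises beyond the original design.

Exclusion rules are declarative and order-independent: a global age cap
(default 30 y, the design's inclusion window), per-collection caps
(default Graz ≤ 21 y: its older specimens form a separate cluster with
unknown inclusion criteria), and a flag for trauma/pathology rows. The
log records each removed row with the first violated rule; applying the
same rules twice is a no-op.

Descriptive summaries report n, mean, sd, median, min, max per
(collection, sex, variable) stratum over non-missing values. The sd uses
the n−1 denominator and is reported as missing for single-observation
strata (the denominator is undefined; 0 would overstate certainty).

## Regression suite

All models are ordinary least squares with an intercept, complete-case
deletion, and two-sided p-values from the t distribution on n−p−1
degrees of freedom (delegated to statsmodels). Coefficients are raw
slopes in natural units (degrees/year, degrees/mm); standardised betas
are available behind a flag because "β" labels in the craniometric
literature are ambiguous. The simple angle–breadth model is fitted in
both directions and the direction-invariant R² is the headline number.
The covariate-adjusted model uses untransformed age; a log-age axis is a
display convention for breadth growth, not part of the model. The Holm
step-down correction is applied across the suite's four primary tests
(age slope of model A, breadth slope of model B, both partial slopes of
model C). Rank-deficient designs raise an error naming the collinear
columns rather than silently dropping terms. Mixed per-collection models
are deliberately out of scope.

## Classification assessment

ROC curves sweep the unique score values (ties grouped into single
steps); AUC is the trapezoidal area, which equals the Mann–Whitney
probability that a random female outscores a random male with half
credit for ties. The positive class is female with higher-score →
positive orientation, because adult females have larger lateral angles;
an AUC below 0.5 is reported as-is, never flipped — chance-level
performance is itself the finding for subadults. Logistic fits are
maximum likelihood via iteratively reweighted least squares
(deterministic, tolerance 1e-8, ≤ 100 iterations); perfect separation
raises an explicit error instead of returning divergent estimates. The
classical cut-off rule is applied exactly: score strictly above the
cut-off → female, a score exactly at 45° → male.

## Growth divergence

LOESS is local polynomial regression with tricube weights over the
⌈span·n⌉ nearest neighbours, degrees 0–2, no robustness iterations, and
no extrapolation beyond the training range. Local rank deficiency (all
neighbourhood ages equal) is an error naming the evaluation point.

The difference analysis fits one smoother per sex, evaluates both on a
grid covering the overlap of the sexes' age ranges (0.5-y step), and
takes female − male. The bootstrap draws B = 1000 case resamples with
replacement, stratified by sex with per-sex n preserved (the pooled
alternative is an option), and recomputes the whole difference curve per
replicate. Grid ages outside a replicate's own resampled age range are
undefined (NaN) rather than extrapolated; dropping whole replicates for
edge non-coverage would discard ≈ 1/e of them whenever the age extreme
is a single case, so only replicates with an actual local-fit failure
are dropped (> 10% failures is an error advising a larger span).

Per grid age, a 95% BCa interval is computed from the replicates defined
there (≥ 100 required, else the band is undefined at that age): bias
term z0 = Φ⁻¹(proportion of replicates below the observed value, ties
half-counted, clamped to [1/(B+1), B/(B+1)] with a warning when all
replicates fall on one side); acceleration a = Σd³ / 6(Σd²)^{3/2} from
leave-one-case-out jackknife values d (stratified: deleting a case
recomputes only its own sex's curve); adjusted percentiles via the
standard BCa mapping; empirical quantiles with linear interpolation.
With z0 = a = 0 the interval reduces exactly to the percentile interval.

Divergence windows are contiguous runs of grid ages whose interval
excludes zero, merged by sign, with runs shorter than `min_run` grid
points (default 2, i.e. 1 year) discarded as flicker. The bands are
pointwise, as in the procedure they implement; no family-wise adjustment
is applied, and this matters for interpretation (below).

### Smoothing span

The span for the divergence analysis defaults to 0.3 (generic
`loess_fit` keeps the conventional 0.75). This is a resolution argument:
the pubertal transition spans roughly 2–4 years, so the smoother's
neighbourhood half-width must be comparable — span 0.3 over a 0–30 y
design gives ≈ ±3 y. A span of 0.75 averages over ≈ ±11 y, smearing the
male breadth acceleration far into childhood and biasing any onset
estimate downward by several years. Degree 1 is used for stability at
the age-range edges; both are configurable.

### Onset reporting

All windows are reported, but the headline "divergence onset" is the
start of the male-larger window that persists to the oldest shared age
(within 1 y). Growth dimorphism, once established, does not revert, so a
persistent separation is the scientifically meaningful detection. This
also addresses multiplicity: simulation with correctly calibrated
pointwise bands (92–95% pointwise coverage; ≈ 7% of grid ages flagged
under the null) still shows *some* transient ≥ 2-point window in roughly
half of null cohorts, because neighbouring grid ages are strongly
correlated — pointwise bands cannot control the cohort-level false
rate. The persistent-window rule keeps null false detections at a few
percent while detecting the simulated pubertal divergence essentially
always, with onset localised to 10–17 y in ~90% of cohorts
(n = 300/sex, δ = 5.6 mm, B = 500; measured by `scripts/acceptance.py`).

## Synthetic cohort generator

The generator encodes the study's verbal growth description as the
simplest adequate parametric form:

    AUB(age, sex) = b0 + b1·log(1 + age) + δ·ramp(age)·1[male] + N(0, σ_aub)
    LA(AUB, sex)  = a0 + a1·AUB + s·1[male] + N(0, σ_angle)

with ramp a logistic function of age (midpoint τ, scale `ramp_width`)
renormalised so ramp(0) = 0 exactly: b0 is the common birth mean and
there is no pre-pubertal dimorphism. Defaults: b0 = 75 mm, b1 = 14
mm/log-y (birth mean ≈ 75 mm, adult female mean ≈ 119 mm), δ = 5.6 mm
(the modern-block adult gap 124.5 − 118.9), τ = 13 y, width 1.5 y,
σ_aub = 5 mm, a0 = 75°, a1 = −0.274 deg/mm (the printed partial
coefficient of the adjusted model), σ_angle = 5°, and s = 0 — under the
default, angle dimorphism is purely breadth-mediated, which is the
hypothesis the analysis probes; setting s ≠ 0 simulates a direct local
anatomical sex effect instead. b1 and the block compositions were set
from the published descriptive table before any testing; they are
emulation choices, not estimates.

The default design mirrors the four collections (Vienna 30M/20F ages
0.1–17, Graz 23M/18F ages 3–21, Terzer 8M/9F ages 0.1–11, modern block
45M/51F ages 12–30 with breadth only; historical blocks child-heavy via
log-uniform ages), with the lateral angle observed only at ages ≤ 21.
A single explicit generator stream per cohort makes identical seeds
byte-identical. What the generator does **not** emulate: joint
non-normality, measurement error in age-at-death, cranial length or any
covariance structure beyond the single angle–breadth coupling, and
population heterogeneity between collections. Passing tests therefore
demonstrate that the estimators recover the truth of *this* generative
model at realistic n and noise — not that the biological claims hold in
any particular real population.

A separate moment-matched specimen table (`synthetic_specimen_table`,
explicitly labelled synthetic) reproduces the published per-stratum n,
mean and sd exactly (deterministic standardised beta-quantile grids,
affinely rescaled) plus the rows the study excluded, to verify the
exclusion → descriptives path end to end; its variables are independent
within strata, so it is not suitable for the regression or divergence
stages.

## Numerical choices and degenerate inputs

* Local fits use closed-form weighted normal equations (degree ≤ 1
  vectorised; degree 2 solved per point) with a relative singularity
  threshold of 1e-12.
* Zero-radius neighbourhoods (duplicated ages) fall back to weighting
  the exact ties; degree ≥ 1 then errors if no age spread remains.
* Empirical quantiles use linear interpolation throughout, so interval
  reductions (BCa → percentile) are exact identities.
* All replicate-degenerate cases (identical replicates, observed outside
  the replicate range) warn and return defined values rather than NaN.
* Single-observation strata: mean reported, sd missing. Empty strata:
  n = 0, all statistics missing.

## Problem sizes

Test-suite and acceptance-script simulation sizes are the package's
study conditions: 50 cohorts of 300 per sex with B = 500 bootstrap
replicates for recovery and null calibration, 200 cohorts of 100 per sex
for chance-level AUC, B = 1000 for single-cohort analyses. A full
bootstrap-divergence analysis of a ~600-specimen cohort takes well under
two seconds on one CPU core.

## Known limitations

* The divergence bands are pointwise; cohort-level inference rests on
  the persistent-window rule, not on family-wise coverage.
* BCa intervals show mild undercoverage (≈ 92–95% observed at 95%
  nominal) at bootstrap sizes of a few hundred, as expected.
* Smoothed difference curves inherit boundary variance from one-sided
  neighbourhoods at the grid edges; edge windows should be read with
  care.
* The onset estimate is the first grid age at which the *band* excludes
  zero, which is a detection threshold, not the biological start of
  divergence: it moves later as noise grows and earlier as n grows.
* No mixed/hierarchical modelling across collections; collection is a
  stratification label only.
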