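# petrodim

Analysis pipeline for the development of sexual dimorphism in the
**lateral angle** of the petrous bone during childhood, and its
relationship to cranial width.

## The problem

The lateral angle — the acute angle between the lateral wall of the
internal acoustic meatus and the posterior surface of the petrous bone —
is used in osteology and forensic anthropology to estimate the sex of
fragmentary or cremated human remains (classically: angle > 45° →
female, ≤ 45° → male). Reported accuracies vary wildly between studies
and populations. A key open question is *when* the dimorphism arises:
if it only emerges during puberty, the method cannot work on subadults,
and if it is mediated by overall cranial breadth, population differences
in cranial dimorphism explain the inconsistent cut-offs.

This package implements the statistical machinery to answer those
questions on a cohort table of specimens (known sex, age at death,
lateral angle LA in degrees, biauricular breadth AUB in mm):

1. **Regression suite** — ordinary least squares with t inference:
   LA ~ age, LA ~ AUB (both directions; R² is direction-invariant), and
   the covariate-adjusted model LA ~ age + AUB, with Bonferroni–Holm
   correction of the primary p-values. If β_age becomes non-significant
   once AUB is in the model, breadth, not age per se, drives the angle.
2. **Classification assessment** — ROC curves and AUC (equal to the
   Mann–Whitney probability, ties half-credited), binary logistic
   regression, and the fixed 45° cut-off rule, with females as the
   positive, higher-angle class.
3. **Growth divergence** — the core procedure: sex-stratified LOESS
   curves of AUB over age, the female−male difference evaluated on a
   shared age grid, a stratified case-resampling bootstrap (B = 1000) of
   the whole difference curve, pointwise 95% BCa (bias-corrected and
   accelerated) intervals with jackknife acceleration, and detection of
   contiguous **divergence windows** where the interval excludes zero.
   The headline onset is the start of the window that persists to the
   oldest shared age.
4. **Synthetic cohorts** — a generative model emulating the study
   design: AUB(age) = b₀ + b₁·log(1+age) + δ·ramp(age)·1[male] + ε with
   a logistic pubertal ramp (midpoint τ = 13 y, adult gap δ = 5.6 mm),
   LA = a₀ + a₁·AUB + ε with a₁ = −0.274 deg/mm, and four collection
   blocks (three child-heavy historical blocks with both measurements,
   one modern block aged 12–30 with breadth only). Every downstream
   stage is testable against known generative truth.

## Worked example

```python
import petrodim as P

cohort = P.simulate_cohort(P.SimConfig.default(seed=42))
kept, log = P.apply_exclusions(cohort)

suite = P.model_suite(kept)
roc = P.roc_curve(kept, "lateral_angle_deg", positive="F")
ens = P.bootstrap_difference(kept, B=1000, seed=42)
win = P.detect_divergence_windows(ens)
```

prints (assembled as in `scripts/acceptance.py`):

```
retained 204 of 204 specimens
angle ~ age:        R2 = 0.334
angle ~ AUB:        R2 = 0.477
angle ~ age + AUB:  adj R2 = 0.478, beta_AUB = -0.375 (p = 1.6e-07), beta_age = 0.228 (p = 0.13)
AUC(lateral angle) = 0.559
45-degree rule accuracy = 55.6%
window 13.9-15.9 y (males larger)
window 17.9-28.9 y (males larger)
persistent divergence onset: 17.9 y
```

Reading: the apparent age effect on the lateral angle disappears once
cranial breadth is adjusted for (β_age non-significant, β_AUB strongly
negative); the angle classifies subadult sex no better than chance
(AUC ≈ 0.5, 45° rule ≈ coin toss); and male and female breadth growth
separates persistently from the late teens in this simulated cohort.

A command-line interface mirrors the library:

```sh
petrodim simulate --seed 1 --out cohort.csv
petrodim summarize --input cohort.csv
petrodim roc --input cohort.csv --score lateral_angle_deg
petrodim divergence --input cohort.csv --reps 1000 --seed 1
petrodim analyze --input cohort.csv --out-dir out/   # full report.json
```

Cohort tables are delimited text (comma or tab) with columns
`specimen_id, collection, sex, age_years, lateral_angle_deg, aub_mm,
excluded_flag, exclusion_reason`; measurements may be blank (missing),
never sentinel-coded.

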