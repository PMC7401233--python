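# Methods

`mcodcvd` implements a multiple-cause-of-death (MCOD) analysis of
overweight/obesity-related cardiovascular mortality, validated end to end
on a synthetic vital-registration world with exact ground truth.  This
note records the models, the defaults and why they were chosen, and what
the synthetic validation does and does not demonstrate.

## The cause taxonomy

Every death certificate carries an underlying cause (UCOD) and any number
of additional cause mentions (entity axis: codes with certificate part,
line and position; record axis: codes after coding rules).  Three nested
definitions drive the analysis:

* **CVD UCOD** — the underlying cause lies in the circulatory chapter
  (default I00–I99).
* **CVD MCOD** — cardiovascular disease appears *anywhere* on the
  certificate, except that cardiac arrest (I46) counts only when it is the
  UCOD.  As a mere mention, cardiac arrest is the terminal event of many
  non-cardiovascular deaths and would otherwise inflate the CVD universe.
* **DKOLH-CVD** — a CVD MCOD death with any mention (including the UCOD
  line) of **D**iabetes (E10–E14), chronic **K**idney disease (N18),
  **O**besity (E65–E68), **L**ipidemias (E78) or **H**ypertensive heart
  disease (I10–I15, deliberately including essential hypertension I10: as
  a multiple cause it is informative even though it is a classic garbage
  underlying cause).  All other CVD MCOD deaths are **non-DKOLH-CVD**.

The five DKOLH causes are the conditions most strongly and specifically
associated with excess body weight, so the DKOLH/non-DKOLH split acts as
a certificate-level proxy for the obesity-related share of CVD mortality.
All code sets are prefix/range collections loaded from YAML and fully
overridable; the defaults are standard ICD-10 groupings and the tracked
co-occurrence cause list (ischemic heart disease, cerebrovascular
disease, heart failure, COPD, pneumonia, lung cancer, sepsis, intestinal
ischemia, ileus/obstruction, plus the five DKOLH causes) stands in for a
fuller certificate cause list.  Duplicate mentions of one cause count
once; classification can be run on either axis, and an `axis_delta`
harness reports the per-year count differences between the two.

## Rates and standardization

Age-specific rates are deaths over person-years per 100,000 by (year,
sex, age band); 10-year bands are formed by summing adjacent 5-year
population cells (for smaller populations).  Zero-death cells keep rate 0
so that smoothing always sees a complete series.  The age-standardized
rate is the direct standardization Σ w_a r_a with standard weights
renormalized over the analysis window; the premature window is ages
35–74 (bands 35–39 … 70–74), all-ages analyses use 0–95+.  The shipped
standard (`data/standard_population_synthetic.csv`) is a synthetic smooth
age distribution — users comparing against published analyses should
supply their preferred standard as a weights file.

## Smoothing and trend summaries

Rate series are smoothed over calendar time with a local polynomial:
at each observed year a degree-*d* polynomial is fitted by kernel-weighted
least squares and evaluated there.  Defaults: degree 1, Gaussian kernel,
bandwidth 2.0 years, evaluation at observed years only (no
extrapolation; endpoints use the asymmetric kernel).  Degree 1 avoids the
boundary bias of a degree-0 smoother, which matters because the
most-recent-year change is a headline quantity; the exact smoother
settings are exposed in configuration and echoed in output metadata, and
the smoother reproduces polynomials up to its degree exactly.

Annual % change is the year-on-year ratio of smoothed rates,
100·(s_t/s_{t−1} − 1); annualized % change between years y0 < y1 is the
geometric rate 100·((r_{y1}/r_{y0})^{1/(y1−y0)} − 1); absolute change is
the plain difference.  A local linear fit of an exponential trend carries
a small curvature bias at series endpoints (≈0.1 percentage points at 3%
per annum growth with the default bandwidth); tests account for this.

Confidence intervals for annualized change come from a Poisson
log-linear model on the underlying death counts: log μ = α + β·year
(+ age-band levels) + log(person-years), fitted by `statsmodels` GLM, with
the Wald interval on β transformed to % per annum.  Under a null trend
with Poisson counts the 95% interval covers zero in ~95% of replicates
(calibration is asserted at 93–97% over 1000 worlds).  For age-banded
series a separate model per band is used.

## Cause co-occurrence PCA

For premature CVD MCOD deaths, a 0/1 mention-indicator matrix over the
tracked causes is decomposed by PCA on its Pearson correlation (phi)
matrix — correlation rather than covariance because mention prevalences
span orders of magnitude.  Components are sign-oriented so the largest
|loading| is positive; |loading| ties break by cause-list order.  The
scientific readout is whether the five DKOLH causes occupy the five
largest |loadings| of some component — the signature of a mutually
correlated cluster sharing one underlying risk factor.  Zero-variance
columns are dropped with a warning; eigenvalues sum to the number of
retained causes.

## Cohort relative lifetime obesity prevalence

A grouped prevalence surface (year × sex × 5-year age group, emulating a
1980–2015 obesity prevalence product) is split into single years of age
by fitting, per year and sex, a 5th-degree least-squares polynomial over
band midpoints (0–4 → 2, …, 95+ → 97) and evaluating at integer ages,
clipping to [0, 1] with a logged count (degree-5 fits can overshoot at
boundary ages; the fit RMSE per year is reported as a diagnostic).  Each
cohort — a 5-year age band at a reference year — is traced back through
the surface (age = cohort age − (reference year − calendar year)), its
prevalence averaged over all traced cells at ages ≥ 5, and divided by the
period-average prevalence at those same ages; the result is expressed as
% above/below average.  The default denominator pools all (year, age)
cells at the traced ages, unweighted; an alternative that averages each
age over years first is available behind a flag (`denominator="age-mean"`)
— the two agree whenever every age is observed in every year, and the
pooled reading is the default because exposure weighting is not part of
the statistic's definition.

## The synthetic world

Because real MCOD unit-record files are restricted, every stage is
validated against a generator with known truth:

* **Deaths.** Three cause-group Poisson processes per (year, sex, 5-year
  band): obesity-related CVD, other CVD, non-CVD.  Cell means are
  population × rate with rate = base·exp(slope·(age−55))·(1+trend/100)^t;
  trends may step by age band.  Certificate ages are uniform within the
  band (95+ → 95–99).
* **Mentions.** Each CVD death draws a latent Bernoulli obesity factor
  and an independent Bernoulli sepsis factor; each tracked cause is
  mentioned with probability logistic(base + loading·factor +
  age-slope·(age−55)).  The obesity factor loads on the five DKOLH
  causes (making them mutually correlated), the sepsis factor on the
  septic digestive cluster (giving the PCA a competing component,
  mirroring the sepsis-related structure seen in real certificates); the
  obesity mention probability declines with age.  By default the DKOLH
  block applies only to obesity-related-group deaths and at least one
  DKOLH mention is guaranteed there (rejection sampling), so the
  classified partition coincides with the generating groups and the
  configured trends are exact recovery targets.  Both switches can be
  turned off, yielding fully independent indicators for null analyses.
* **Underlying causes.** CVD UCODs are drawn from circulatory codes
  outside the tracked list (pulmonary embolism, cardiomyopathy, aortic
  aneurysm, hypotension), with a small configurable fraction of cardiac
  arrest UCODs; a categorical UCOD over tracked causes would inject
  mutual-exclusivity (negative) correlation into the mention matrix that
  the co-mention model is meant to control exactly.  A fraction of
  non-CVD deaths carries a part-2 cardiac-arrest mention to exercise the
  I46 gate.
* **Prevalence.** log prevalence = log(base·profile(age)) +
  rate(age)·(year−2015) with rate(age) = period% + gradient%·(65−age).
  A gradient acting multiplicatively on birth year alone cancels out of
  the relative lifetime statistic (the cohort factor appears identically
  in numerator and denominator), so the age-graded growth — prevalence
  rising faster at younger ages, as in observed obesity trends — is the
  minimal structure under which the statistic is genuinely cohort-graded
  and strictly declining with cohort age.  Defaults (base 0.23 at the
  age-profile peak, 2.2%/yr period growth, 0.06%/age-year gradient) give
  a youngest premature cohort about 13–14% above the period average and
  the oldest about 2% below.

`ground_truth(config)` derives recovery targets without sampling: group
trends pass through directly; the DKOLH share uses exhaustive enumeration
of the mention model (factor × 2⁵ outcomes) where membership is
stochastic; cohort relative prevalence is computed from the exact
generating formula.

### Default study conditions and problem sizes

The default world (`ScenarioConfig.paper_regime`) covers 2005–2017, two
sexes, ages 0–95+, 100,000 persons per cell, obesity-related CVD rising
(steeper at younger ages: +4%/yr at 35–44 down to +1.5%/yr at 65–74),
other CVD falling 2.5%/yr, and the positive prevalence gradient above —
about 1.2 million deaths per run.  The trend-recovery benchmark
(`ScenarioConfig.trend_recovery`) uses a single sex, ages 35–74 and
±3.0%/yr group trends over a 12-year span with ≈10⁵ CVD deaths per
replicate; recovery is asserted to ±0.5 percentage points with ≥90% CI
coverage over 50 replicates.  PCA detection uses worlds of ≥50,000
premature CVD deaths.

### What the synthetic validation does not show

The generator emulates the *structures* the analysis relies on — 2–3
causes per CVD certificate, a latent co-mention cluster, exponential
group trends, a cohort-graded prevalence surface — not the messiness of
real registration data: no coding-rule record-axis transformations (the
synthetic record axis simply mirrors the entity codes), no cause-chain
sequencing logic, no registration delays, no migration, no certifier
reporting drift (the causes-per-death diagnostic is therefore flat by
construction), and no garbage-code redistribution.  Passing tests
demonstrate that the estimators recover known truth under the stated
data-generating process, not that the taxonomy itself is the correct
proxy for obesity-related mortality in any particular registry.

## Numerical choices

Half-open integer age bands [lo, hi) with a terminal open band avoid
boundary double-counting.  Weights must sum to 1 within 1e-9 and are
renormalized exactly over windows.  The rate identity (rate = 10⁵ ·
deaths/person-years) is enforced to 1e-9 on age-specific series.
Nonpositive smoothed rates make % change undefined and raise; all-zero
count series yield a flagged, not fabricated, CI.  Undefined cells
(empty age groups, cohorts aged <5 throughout the surface) propagate as
NaN with a warning, never as zero.  PCA uses a symmetric eigensolver
(`eigh`); sign orientation and tie-breaking are deterministic, so every
pipeline output is bit-identical for a fixed configuration, which the
run manifest (config hash + seed + versions) makes checkable.
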