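# mcodcvd

Multiple-cause-of-death (MCOD) analysis of overweight/obesity-related
cardiovascular mortality: cause-set classification of death certificates,
age-standardized rate trends with local polynomial smoothing, cause
co-occurrence PCA, and cohort relative lifetime obesity prevalence — with
a synthetic vital-registration generator carrying exact ground truth, so
the whole pipeline is testable without restricted registry microdata.

## Who this is for

Epidemiologists and biostatisticians analysing vital-registration
unit-record files (e.g. national multiple-cause mortality files) who want
to go beyond the underlying cause of death.  Cardiovascular deaths are
usually co-morbid: conditions such as diabetes, chronic kidney disease,
obesity, lipidemias and hypertensive heart disease (the **DKOLH**
cluster) appear as *contributory* causes far more often than as the
underlying cause, and together act as a certificate-level proxy for the
contribution of excess body weight to CVD mortality trends.

## The statistics at its core

* **Taxonomy.** A death is *CVD MCOD* if cardiovascular disease (I00–I99)
  appears anywhere on the certificate, counting cardiac arrest (I46) only
  when it is the underlying cause.  It is *DKOLH-CVD* if additionally any
  of the five DKOLH causes is mentioned; otherwise *non-DKOLH-CVD*.
* **Rates.** Age-specific rates per 100,000 person-years and directly
  standardized rates ASDR_t = Σ_a w_a r_{a,t}, over all ages or the
  premature window 35–74.
* **Trends.** Local-polynomial smoothing over calendar years (degree 1,
  Gaussian kernel, bandwidth 2y by default); annual % change
  100·(s_t/s_{t−1} − 1); annualized change 100·((r_{y1}/r_{y0})^{1/(y1−y0)} − 1)
  with 95% CIs from a Poisson log-linear count model with person-years
  exposure.
* **Co-occurrence.** PCA of the phi (Pearson) correlation matrix of 0/1
  cause-mention indicators over CVD MCOD deaths; the DKOLH cluster is
  detected when the five causes hold the top-5 |loadings| of a component.
* **Cohort statistic.** Grouped prevalence surfaces are split to single
  ages with per-year 5th-degree polynomials; each cohort's mean
  prevalence over its traced (year, age) cells at ages ≥5 is divided by
  the period mean at those same ages: % above/below average lifetime
  obesity prevalence.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import mcodcvd as m

cfg = m.StudyConfig(scenario=m.ScenarioConfig.paper_regime(seed=0),
                    period=(2011, 2017))
res = m.run_study(cfg, outdir="out")          # writes CSVs + manifest.json

c = res.manifest["record_counts"]
print(c["cvd_mcod"], "CVD MCOD deaths,",
      round(100 * c["dkolh"] / c["cvd_mcod"], 1), "% DKOLH")

fig2 = res.frames["fig2_annual_change"]
print(fig2[(fig2.year == 2017) & (fig2.sex == "female")]
      [["series", "rate", "smoothed", "annual_change_pct"]].round(2))
```

prints (seed 0):

```
564665 CVD MCOD deaths, 46.7 % DKOLH
       series    rate  smoothed  annual_change_pct
        dkolh  167.60    163.80               3.95
    non_dkolh  130.39    132.65              -2.51
```

i.e. in this synthetic world the obesity-related half of premature CVD
mortality is rising ~4% in the final year while the remainder keeps
falling — the divergence the classification is designed to expose.  The
same run yields the co-occurrence PCA (the five DKOLH causes hold the
top-5 loadings of the leading component, eigenvalue 2.04) and the cohort
table, where relative lifetime obesity prevalence falls monotonically
from +13.6% for the 35–39 cohort to −2.2% for the 70–74 cohort while the
share of DKOLH deaths with obesity reported falls from 56% to 12%.

Real unit-record data go through the same pipeline via file paths
(`records_path`, `population_path`, `prevalence_path`, `weights_path`)
in `StudyConfig`, or the CLI:

```bash
mcodcvd simulate --out data/ --seed 0
mcodcvd run --records data/records.csv --pop data/population.csv \
            --prevalence data/prevalence.csv --out bundle/
```

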