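"""End-to-end study runs: synthetic world (or user files) -> output bundle.

One run produces, per sex, the machinery behind the study's headline
artefacts as plain CSVs:

* ``fig1_annual_change.csv`` — CVD underlying-cause and multiple-cause
  age-standardized rates, smoothed, with annual % change (all ages and the
  premature 35-74 window);
* ``fig2_annual_change.csv`` — the same for the DKOLH vs non-DKOLH split
  (35-74 only);
* ``table1_changes.csv`` — absolute and annualized % change over a chosen
  period for each DKOLH component cause and the DKOLH total;
* ``fig3_age_specific.csv`` — age-band-specific annualized changes with
  Poisson-model 95% CIs for the two groups;
* ``fig4_cohort.csv`` — % of DKOLH deaths with obesity reported per cohort
  age band, next to each cohort's relative lifetime obesity prevalence;
* ``pca_eigenvalues.csv`` / ``pca_loadings.csv`` — the co-occurrence PCA;
* ``avg_causes.csv`` — mean tracked causes per CVD MCOD death per year;
* ``manifest.json`` — config hash, seed, versions, stage record counts.

Stage-level record accounting is asserted (no silent record loss) and
recorded in the manifest; reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    DKOLH_COMPONENTS,
    CauseSetConfig,
    avg_causes_per_death,
    classify_frame,
    pct_with_cause,
)
from .cohort import cohort_relative_table, split_to_single_ages
from .cooccurrence import build_mention_matrix, dkolh_cluster_rank, pca_correlation
from .io import read_population, read_prevalence, read_unit_records, read_weights
from .rates import PREMATURE_WINDOW, age_specific_rates, age_standardized_rate
from .synth import (
    ScenarioConfig,
    generate_deaths,
    generate_population,
    generate_prevalence_surface,
)
from .trends import summarize_trend, trend_ci
from .types import (
    PopulationTable,
    PrevalenceSurface,
    StandardPopulation,
    ValidationError,
    band_label,
    five_year_bands,
)

logger = logging.getLogger(__name__)


def default_standard_population() -> StandardPopulation:
    """The synthetic smooth age standard shipped with the package."""
    with resources.files("mcodcvd.data").joinpath(
        "standard_population_synthetic.csv"
    ).open("r") as fh:
        f = pd.read_csv(fh)
    f["age_hi"] = pd.to_numeric(f["age_hi"], errors="coerce")
    return StandardPopulation(f)


@dataclass
class StudyConfig:
    """Everything one study run needs.

    Either a synthetic scenario or paths to unit-record/population/
    prevalence files; cause sets; axis choice; smoothing settings; the
    table-1 style comparison period and the cohort reference year.
    """

    scenario: Optional[ScenarioConfig] = None
    records_path: Optional[str] = None
    population_path: Optional[str] = None
    prevalence_path: Optional[str] = None
    weights_path: Optional[str] = None
    causes: CauseSetConfig = field(default_factory=CauseSetConfig.default)
    axis: str = "entity"
    band_width: int = 5
    window: tuple[int, int] = PREMATURE_WINDOW
    smoothing: dict = field(default_factory=lambda: {"degree": 1, "bandwidth": 2.0, "kernel": "gaussian"})
    period: Optional[tuple[int, int]] = None
    reference_year: Optional[int] = None
    cohort_bands: tuple = tuple(
        (lo, lo + 5) for lo in range(35, 75, 5)
    )

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Output bundle of one run: named frames plus the run manifest."""

    frames: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.frames.items():
            frame.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return outdir


def _trend_frame(rs, counts_source, sex, series, window_label, cfg) -> pd.DataFrame:
    series_rates = rs.series(sex)
    tr = summarize_trend(series_rates, counts=None, **cfg.smoothing)
    out = tr.by_year.reset_index()
    out.insert(0, "window", window_label)
    out.insert(0, "series", series)
    out.insert(0, "sex", sex)
    return out


def run_study(cfg: StudyConfig, outdir: Optional[str | Path] = None) -> StudyResult:
    """Execute the full analysis and (optionally) write the bundle to disk."""
    # ---- stage: inputs -----------------------------------------------------
    if cfg.scenario is not None:
        scenario = cfg.scenario
        records = generate_deaths(scenario)
        pop = generate_population(scenario)
        prevalence = generate_prevalence_surface(scenario)
        seed = scenario.seed
    else:
        if not (cfg.records_path and cfg.population_path):
            raise ValidationError("need either a scenario or records/population paths")
        rr = read_unit_records(cfg.records_path)
        logger.info("read %d records (%d row errors)", len(rr.records), len(rr.errors))
        records = rr.frame
        pop = read_population(cfg.population_path)
        prevalence = read_prevalence(cfg.prevalence_path) if cfg.prevalence_path else None
        seed = None
    if cfg.weights_path:
        std = read_weights(cfg.weights_path)
    else:
        std = default_standard_population()

    n_records = len(records)
    counts = {"records": n_records}
    logger.info("stage inputs: %d death records", n_records)

    # ---- stage: classification --------------------------------------------
    classed = classify_frame(records, cfg.causes, axis=cfg.axis)
    if len(classed) != n_records:
        raise ValidationError("classification lost records")
    counts["classified"] = len(classed)
    counts["cvd_mcod"] = int(classed["cvd_mcod"].sum())
    counts["dkolh"] = int(classed["dkolh"].sum())
    counts["non_dkolh"] = int((classed["cvd_mcod"] & ~classed["dkolh"]).sum())
    assert counts["dkolh"] + counts["non_dkolh"] == counts["cvd_mcod"]

    period = cfg.period
    years = sorted(classed["year"].unique())
    if period is None:
        period = (int(years[0]), int(years[-1]))
    ref_year = cfg.reference_year or int(years[-1])

    # ---- stage: rates + trends --------------------------------------------
    non_dkolh_mask = (classed["cvd_mcod"] & ~classed["dkolh"]).to_numpy()
    fig1, fig2, table1, fig3 = [], [], [], []
    for sex in sorted(classed["sex"].unique()):
        sex_mask = (classed["sex"] == sex).to_numpy()
        for series, sel in (("cvd_ucod", "cvd_ucod"), ("cvd_mcod", "cvd_mcod")):
            for window_label, window in (("all", None), ("35-74", cfg.window)):
                ar = age_specific_rates(
                    classed[sex_mask], pop, selection=sel,
                    band_width=cfg.band_width, window=window,
                )
                asdr = age_standardized_rate(ar, std, window=window)
                fig1.append(_trend_frame(asdr, ar, sex, series, window_label, cfg))

        for series, sel in (("dkolh", "dkolh"), ("non_dkolh", non_dkolh_mask[sex_mask])):
            ar = age_specific_rates(
                classed[sex_mask], pop, selection=sel,
                band_width=cfg.band_width, window=cfg.window,
            )
            asdr = age_standardized_rate(ar, std, window=cfg.window)
            fig2.append(_trend_frame(asdr, ar, sex, series, "35-74", cfg))

            # table 1 style period change on the standardized smoothed series
            sm = summarize_trend(asdr.series(sex), counts=None, period=period, **cfg.smoothing)
            table1.append(
                {
                    "sex": sex,
                    "series": series,
                    "period": f"{period[0]}-{period[1]}",
                    "abs_change": sm.absolute,
                    "annualized_pct": sm.annualized_smoothed_pct,
                }
            )

            # age-specific annualized change + Poisson CI over the full period
            for band in ar.bands:
                sub = ar.frame[(ar.frame["sex"] == sex) & (ar.frame["age_lo"] == band[0])]
                est = trend_ci(sub, int(years[0]), int(years[-1]))
                fig3.append(
                    {
                        "sex": sex,
                        "series": series,
                        "age_group": band_label(band),
                        "age_lo": band[0],
                        "annualized_pct": est.annualized_pct,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "defined": est.defined,
                    }
                )

        # component-cause series (mentions with CVD MCOD), table-1 rows
        for comp in DKOLH_COMPONENTS:
            comp_mask = (classed["cvd_mcod"] & classed[f"has_{comp}"]).to_numpy()
            ar = age_specific_rates(
                classed[sex_mask], pop, selection=comp_mask[sex_mask],
                band_width=cfg.band_width, window=cfg.window,
            )
            asdr = age_standardized_rate(ar, std, window=cfg.window)
            sm = summarize_trend(asdr.series(sex), counts=None, period=period, **cfg.smoothing)
            table1.append(
                {
                    "sex": sex,
                    "series": comp,
                    "period": f"{period[0]}-{period[1]}",
                    "abs_change": sm.absolute,
                    "annualized_pct": sm.annualized_smoothed_pct,
                }
            )

    fig1_frame = pd.concat(fig1, ignore_index=True)
    fig2_frame = pd.concat(fig2, ignore_index=True)
    table1_frame = pd.DataFrame(table1)
    fig3_frame = pd.DataFrame(fig3)

    # ---- stage: co-occurrence PCA -----------------------------------------
    mm = build_mention_matrix(classed, cfg.causes, window=cfg.window)
    counts["mention_matrix_rows"] = len(mm.values)
    pca = pca_correlation(mm)
    cluster_counts, best = dkolh_cluster_rank(pca)
    pca_eigen = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
            "eigenvalue": pca.eigenvalues,
            "dkolh_in_top5": cluster_counts,
        }
    )
    pca_loadings = pca.loadings.reset_index(names="cause")

    # ---- stage: diagnostics ------------------------------------------------
    avg_causes = avg_causes_per_death(classed).rename("avg_tracked_causes").reset_index()

    window_bands = [b for b in five_year_bands(cfg.window[0], cfg.window[1], open_end=False)]
    pct_obesity = pct_with_cause(classed, "obesity", window_bands)

    # ---- stage: cohort prevalence -----------------------------------------
    if prevalence is not None:
        single = split_to_single_ages(prevalence, degree=5)
        cohort = cohort_relative_table(single, cfg.cohort_bands, ref_year)
        fig4 = cohort.copy()
        fig4["pct_dkolh_with_obesity"] = fig4["cohort"].map(pct_obesity)
    else:
        fig4 = pd.DataFrame(
            {"cohort": pct_obesity.index, "pct_dkolh_with_obesity": pct_obesity.values}
        )

    frames = {
        "fig1_annual_change": fig1_frame,
        "fig2_annual_change": fig2_frame,
        "table1_changes": table1_frame,
        "fig3_age_specific": fig3_frame,
        "fig4_cohort": fig4,
        "pca_eigenvalues": pca_eigen,
        "pca_loadings": pca_loadings,
        "avg_causes": avg_causes,
    }
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "axis": cfg.axis,
        "band_width": cfg.band_width,
        "window": list(cfg.window),
        "period": list(period),
        "reference_year": ref_year,
        "smoothing": cfg.smoothing,
        "record_counts": counts,
        "pca_best_component": int(best),
        "versions": {
            "mcodcvd": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    result = StudyResult(frames=frames, manifest=manifest)
    if outdir is not None:
        result.write(outdir)
    return result
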