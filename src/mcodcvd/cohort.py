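"""Cohort relative lifetime obesity prevalence from a grouped surface.

The grouped prevalence surface (year x sex x 5-year age group) is split
into single years of age by fitting, for each year, a 5th-degree
polynomial over age-band midpoints.  Each cohort — a 5-year age band at a
reference year — is then traced back through the surface (age at year y =
cohort age - (reference year - y)), its prevalence averaged over all
traced cells at ages >= 5, and divided by the period-average prevalence at
those same ages.  The result is a % above/below the period average: a
life-course exposure summary, higher for cohorts that lived through high
prevalence at every age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    AgeBand,
    PrevalenceSurface,
    ValidationError,
    band_ages,
    band_label,
    band_midpoint,
)

logger = logging.getLogger(__name__)


@dataclass
class SingleAgeSurface:
    """Prevalence by (year, sex, single age 0-99) with split diagnostics.

    ``frame`` columns: year, sex, age, prevalence (clipped to [0, 1]).
    ``diagnostics`` records per (year, sex): fit RMSE against the band
    values and the number of clipped single-age cells; ``degree`` is the
    polynomial degree used.
    """

    frame: pd.DataFrame
    degree: int
    diagnostics: pd.DataFrame

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["age"].unique()))

    def lookup(self, sex: str) -> pd.DataFrame:
        """Years x ages pivot for one sex."""
        sub = self.frame[self.frame["sex"] == sex]
        return sub.pivot_table(index="year", columns="age", values="prevalence")


def split_to_single_ages(
    surface: PrevalenceSurface,
    degree: int = 5,
    ages: Optional[Sequence[int]] = None,
) -> SingleAgeSurface:
    """Split a grouped prevalence surface into single years of age.

    Per (year, sex), a least-squares polynomial of the requested degree is
    fitted to the band prevalences at band midpoints (0-4 -> 2, ..., 95+ ->
    97) and evaluated at integer ages; evaluations are clipped to [0, 1]
    and clip counts logged.  Exact for surfaces generated from a polynomial
    of degree <= ``degree`` sampled at the midpoints.
    """
    bands = surface.age_groups
    if len(bands) < degree + 1:
        raise ValidationError(
            f"{len(bands)} age groups cannot support a degree-{degree} fit; "
            f"reduce degree to <= {len(bands) - 1}"
        )
    if ages is None:
        last = bands[-1]
        max_age = band_ages(last)[-1]
        ages = range(bands[0][0], max_age + 1)
    ages = np.asarray(list(ages), dtype=float)
    mids = np.array([band_midpoint(b) for b in bands])

    rows = []
    diags = []
    f = surface.frame
    for (year, sex), grp in f.groupby(["year", "sex"]):
        grp = grp.sort_values("age_lo")
        y = grp["prevalence"].to_numpy(dtype=float)
        x = np.array(
            [band_midpoint((int(lo), None if pd.isna(hi) else int(hi)))
             for lo, hi in zip(grp["age_lo"], grp["age_hi"])]
        )
        poly = np.polynomial.Polynomial.fit(x, y, degree)
        fitted_bands = poly(x)
        vals = poly(ages)
        clipped = int(((vals < 0) | (vals > 1)).sum())
        vals = np.clip(vals, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {"year": int(year), "sex": sex, "age": ages.astype(int), "prevalence": vals}
            )
        )
        diags.append(
            {
                "year": int(year),
                "sex": sex,
                "rmse": float(np.sqrt(np.mean((fitted_bands - y) ** 2))),
                "clipped_cells": clipped,
            }
        )
    if any(d["clipped_cells"] for d in diags):
        total = sum(d["clipped_cells"] for d in diags)
        logger.warning("polynomial age split clipped %d single-age cells to [0, 1]", total)
    return SingleAgeSurface(
        frame=pd.concat(rows, ignore_index=True),
        degree=degree,
        diagnostics=pd.DataFrame(diags),
    )


def _traced_cells(
    single: SingleAgeSurface,
    cohort_band: AgeBand,
    reference_year: int,
    min_age: int = 5,
) -> tuple[list[tuple[int, int]], list[int]]:
    """(year, age) cells traced by the cohort, and the distinct traced ages."""
    years = single.years
    if reference_year < max(years):
        raise ValidationError(
            f"reference year {reference_year} precedes the surface's last year {max(years)}"
        )
    lo_age, hi_age = min(single.ages), max(single.ages)
    cells = []
    for a0 in band_ages(cohort_band):
        for y in years:
            a = a0 - (reference_year - y)
            if a >= min_age and lo_age <= a <= hi_age:
                cells.append((y, a))
    ages = sorted({a for _, a in cells})
    return cells, ages


def cohort_lifetime_mean(
    single: SingleAgeSurface,
    cohort_band: AgeBand,
    reference_year: int,
    sex: str,
    min_age: int = 5,
) -> float:
    """Mean prevalence over a cohort's traced (year, age) cells at ages >= ``min_age``.

    NaN (flagged undefined) when no cell contributes, e.g. a cohort aged
    < 5 throughout the surface period.
    """
    cells, _ = _traced_cells(single, cohort_band, reference_year, min_age)
    if not cells:
        logger.warning(
            "cohort %s at %d has no traced cells in the surface; lifetime mean undefined",
            band_label(cohort_band), reference_year,
        )
        return float("nan")
    table = single.lookup(sex)
    return float(np.mean([table.loc[y, a] for y, a in cells]))


def relative_lifetime_prevalence(
    single: SingleAgeSurface,
    cohort_band: AgeBand,
    reference_year: int,
    sex: str,
    min_age: int = 5,
    denominator: str = "pooled",
) -> float:
    """Cohort lifetime prevalence as % above/below the period average.

    ``denominator='pooled'`` (default) averages over every (year, age) cell
    of the surface at the cohort's traced ages; ``'age-mean'`` first
    averages each age over years, then averages those age means.  The two
    agree when every age is observed in every year.
    """
    cohort = cohort_lifetime_mean(single, cohort_band, reference_year, sex, min_age)
    if np.isnan(cohort):
        return float("nan")
    _, ages = _traced_cells(single, cohort_band, reference_year, min_age)
    table = single.lookup(sex)
    block = table.loc[:, ages]
    if denominator == "pooled":
        denom = float(block.to_numpy().mean())
    elif denominator == "age-mean":
        denom = float(block.mean(axis=0).mean())
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom == 0:
        raise ValidationError("period average prevalence is zero at the traced ages")
    return 100.0 * (cohort / denom - 1.0)


def cohort_relative_table(
    single: SingleAgeSurface,
    cohort_bands: Sequence[AgeBand],
    reference_year: int,
    sexes: Optional[Sequence[str]] = None,
    min_age: int = 5,
    denominator: str = "pooled",
) -> pd.DataFrame:
    """Relative lifetime prevalence for several cohorts, per sex."""
    if sexes is None:
        sexes = sorted(single.frame["sex"].unique())
    rows = []
    for sex in sexes:
        for band in cohort_bands:
            rows.append(
                {
                    "sex": sex,
                    "cohort": band_label(band),
                    "cohort_age_lo": band[0],
                    "reference_year": reference_year,
                    "relative_prevalence_pct": relative_lifetime_prevalence(
                        single, band, reference_year, sex, min_age, denominator
                    ),
                }
            )
    return pd.DataFrame(rows)
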