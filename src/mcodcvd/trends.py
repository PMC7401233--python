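"""Smoothing of annual rate series and trend summaries.

Rates are smoothed over calendar time with a local polynomial (kernel-
weighted least squares at each observed year; default local linear with a
Gaussian kernel, bandwidth 2 years).  Annual % change is the year-on-year
ratio of smoothed rates; annualized % change between two years is the
geometric mean rate of change.  Confidence intervals for annualized change
come from a Poisson log-linear trend model on the underlying death counts
with person-years exposure (age entered as a categorical level when the
series is age-banded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .types import ValidationError

KERNELS = {
    "gaussian": lambda u: np.exp(-0.5 * u**2),
    "epanechnikov": lambda u: np.maximum(0.0, 0.75 * (1.0 - u**2)),
    "triangular": lambda u: np.maximum(0.0, 1.0 - np.abs(u)),
    "uniform": lambda u: (np.abs(u) <= 1.0).astype(float),
}


def smooth_series(
    years: Sequence[float],
    values: Sequence[float],
    degree: int = 1,
    bandwidth: float = 2.0,
    kernel: str = "gaussian",
) -> np.ndarray:
    """Local polynomial smoother evaluated at each observed year.

    At every year a polynomial of the given degree is fitted by kernel-
    weighted least squares and evaluated at that year.  No extrapolation:
    endpoints use the (asymmetric) kernel over the observed years only.
    Reproduces polynomials up to ``degree`` exactly.
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    if degree < 0:
        raise ValidationError("degree must be >= 0")
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("years and values must be 1-d and aligned")
    if len(x) < degree + 2:
        raise ValidationError(f"need at least degree+2={degree + 2} points, got {len(x)}")
    try:
        kfun = KERNELS[kernel]
    except KeyError:
        raise ValidationError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}") from None

    out = np.empty_like(y)
    for i, x0 in enumerate(x):
        w = kfun((x - x0) / bandwidth)
        support = w > 0
        if support.sum() < degree + 1:
            raise ValidationError(
                f"kernel support at year {x0:g} has {int(support.sum())} points; "
                f"degree {degree} needs {degree + 1} (increase bandwidth)"
            )
        # np.polyfit weights multiply residuals, i.e. correspond to sqrt of
        # WLS weights.
        coef = np.polyfit(x[support] - x0, y[support], degree, w=np.sqrt(w[support]))
        out[i] = coef[-1]
    return out


def annual_pct_change(smoothed: pd.Series) -> pd.Series:
    """Year-on-year % change of a (smoothed) rate series: 100*(s_t/s_{t-1} - 1)."""
    s = smoothed.sort_index()
    if (s <= 0).any():
        bad = s.index[s <= 0][0]
        raise ValidationError(f"nonpositive smoothed rate at year {bad}; % change undefined")
    return (100.0 * (s / s.shift(1) - 1.0)).dropna()


def annualized_change(series: pd.Series, y0: int, y1: int) -> float:
    """Annualized % change between two years: 100*((r1/r0)^(1/(y1-y0)) - 1)."""
    if y0 >= y1:
        raise ValidationError(f"need y0 < y1, got {y0} >= {y1}")
    for y in (y0, y1):
        if y not in series.index:
            raise ValidationError(f"year {y} not present in series")
    r0, r1 = float(series.loc[y0]), float(series.loc[y1])
    if r0 <= 0:
        raise ValidationError(f"rate at {y0} is {r0}; annualized change undefined")
    return 100.0 * ((r1 / r0) ** (1.0 / (y1 - y0)) - 1.0)


def absolute_change(series: pd.Series, y0: int, y1: int) -> float:
    """Rate difference r_{y1} - r_{y0}."""
    if y0 >= y1:
        raise ValidationError(f"need y0 < y1, got {y0} >= {y1}")
    return float(series.loc[y1]) - float(series.loc[y0])


@dataclass(frozen=True)
class TrendEstimate:
    """Annualized % change with its 95% Wald CI from a Poisson trend model."""

    annualized_pct: float
    ci_low: float
    ci_high: float
    se_log: float
    nobs: int
    defined: bool = True

    def covers(self, truth_pct: float) -> bool:
        return self.ci_low <= truth_pct <= self.ci_high


def trend_ci(
    counts: pd.DataFrame,
    y0: Optional[int] = None,
    y1: Optional[int] = None,
    alpha: float = 0.05,
) -> TrendEstimate:
    """Poisson log-linear trend on death counts with exposure offset.

    ``counts`` columns: year, deaths, person_years and optionally age_lo
    (added as categorical age levels).  The slope on calendar year is
    transformed to % per annum; the CI is the Wald interval on the slope.
    All-zero counts give an undefined (flagged) estimate.
    """
    needed = {"year", "deaths", "person_years"} - set(counts.columns)
    if needed:
        raise ValidationError(f"counts frame missing columns {sorted(needed)}")
    f = counts.copy()
    if y0 is not None:
        f = f[f["year"] >= y0]
    if y1 is not None:
        f = f[f["year"] <= y1]
    years = np.sort(f["year"].unique())
    if len(years) < 3:
        raise ValidationError(f"trend CI needs >= 3 years of counts, got {len(years)}")
    if (f["deaths"] == 0).all():
        return TrendEstimate(np.nan, np.nan, np.nan, np.nan, len(f), defined=False)

    t = f["year"].to_numpy(dtype=float) - years.mean()
    X = [np.ones(len(f)), t]
    if "age_lo" in f.columns and f["age_lo"].nunique() > 1:
        levels = np.sort(f["age_lo"].unique())
        for lev in levels[1:]:
            X.append((f["age_lo"] == lev).to_numpy(dtype=float))
    X = np.column_stack(X)
    model = sm.GLM(
        f["deaths"].to_numpy(dtype=float),
        X,
        family=sm.families.Poisson(),
        offset=np.log(f["person_years"].to_numpy(dtype=float)),
    )
    res = model.fit()
    beta, se = res.params[1], res.bse[1]
    z = float(norm.ppf(1 - alpha / 2))
    lo, hi = beta - z * se, beta + z * se
    return TrendEstimate(
        annualized_pct=100.0 * (np.exp(beta) - 1.0),
        ci_low=100.0 * (np.exp(lo) - 1.0),
        ci_high=100.0 * (np.exp(hi) - 1.0),
        se_log=float(se),
        nobs=len(f),
    )


@dataclass
class TrendResult:
    """Smoothed series plus change summaries for one rate series.

    ``by_year`` carries the observed rate, smoothed rate and annual %
    change; ``annualized`` the % and absolute change over the requested
    period with the model-based 95% CI.  Smoothing settings are recorded in
    ``settings``.
    """

    by_year: pd.DataFrame
    annualized: Optional[TrendEstimate]
    annualized_smoothed_pct: Optional[float]
    absolute: Optional[float]
    settings: dict


def summarize_trend(
    rates: pd.Series,
    counts: Optional[pd.DataFrame] = None,
    period: Optional[tuple[int, int]] = None,
    degree: int = 1,
    bandwidth: float = 2.0,
    kernel: str = "gaussian",
) -> TrendResult:
    """Smooth one year-indexed rate series and summarize its trend.

    ``counts`` (year/deaths/person_years[/age_lo]) feeds the CI model; the
    point annualized change is computed from the smoothed rates over
    ``period`` (default: full span).
    """
    rates = rates.sort_index()
    years = rates.index.to_numpy(dtype=int)
    smoothed = pd.Series(
        smooth_series(years, rates.to_numpy(dtype=float), degree, bandwidth, kernel),
        index=rates.index,
        name="smoothed",
    )
    by_year = pd.DataFrame({"rate": rates, "smoothed": smoothed})
    by_year["annual_change_pct"] = annual_pct_change(smoothed).reindex(by_year.index)

    if period is None:
        period = (int(years.min()), int(years.max()))
    ann_sm = annualized_change(smoothed, *period)
    abs_chg = absolute_change(smoothed, *period)
    est = trend_ci(counts, *period) if counts is not None else None
    return TrendResult(
        by_year=by_year,
        annualized=est,
        annualized_smoothed_pct=ann_sm,
        absolute=abs_chg,
        settings={
            "degree": degree,
            "bandwidth": bandwidth,
            "kernel": kernel,
            "period": period,
        },
    )
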