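"""Age-specific and age-standardized death rates for classified subsets.

Direct standardization: ASDR = sum_a w_a * rate_a with fixed standard
weights w_a renormalized over the analysis age window.  The premature
window is ages 35-74 (bands 35-39 ... 70-74); all-ages analyses run 0-95+.
Zero-death cells keep rate 0 so downstream smoothing sees complete series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AgeBand,
    PopulationTable,
    StandardPopulation,
    ValidationError,
    band_label,
)

PREMATURE_WINDOW: tuple[int, int] = (35, 75)


@dataclass
class RateSeries:
    """Death counts, person-years and rates per 100,000 by (year, sex, stratum).

    ``frame`` columns: year, sex, age_lo, age_hi, deaths, person_years,
    rate.  For an age-standardized series the stratum columns carry the
    window bounds and ``meta['stratum']`` is ``'age-standardized'``.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if self.meta.get("stratum") != "age-standardized":
            # identity holds for age-specific strata; a standardized rate is
            # a weighted combination, not deaths/person-years.
            expected = 1e5 * f["deaths"] / f["person_years"]
            if not np.allclose(f["rate"], expected, rtol=0, atol=1e-9):
                raise ValidationError("rate != 100000 * deaths / person_years")
        self.frame = f.sort_values(["sex", "age_lo", "year"]).reset_index(drop=True)

    @property
    def bands(self) -> tuple[AgeBand, ...]:
        sub = self.frame[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
        return tuple(
            (int(lo), None if pd.isna(hi) else int(hi))
            for lo, hi in zip(sub["age_lo"], sub["age_hi"])
        )

    def pivot(self, sex: str, value: str = "rate") -> pd.DataFrame:
        """Years x bands table of ``value`` for one sex."""
        sub = self.frame[self.frame["sex"] == sex]
        return sub.pivot_table(index="year", columns="age_lo", values=value, aggfunc="sum")

    def series(self, sex: str, value: str = "rate") -> pd.Series:
        """Year-indexed series for one sex (single-stratum frames only)."""
        sub = self.frame[self.frame["sex"] == sex]
        if sub.duplicated("year").any():
            raise ValidationError("series() needs a single-stratum rate series")
        return sub.set_index("year")[value].sort_index()


def _bands_in_window(bands: Sequence[AgeBand], window: Optional[tuple[int, int]]) -> list[AgeBand]:
    if window is None:
        return list(bands)
    lo, hi = window
    return [b for b in bands if b[0] >= lo and b[1] is not None and b[1] <= hi]


def age_specific_rates(
    classified: pd.DataFrame,
    pop: PopulationTable,
    selection: Union[str, pd.Series, np.ndarray, None] = None,
    band_width: int = 5,
    window: Optional[tuple[int, int]] = None,
) -> RateSeries:
    """Death rates per 100,000 by (year, sex, age band) for a classified subset.

    ``selection`` is a boolean column name of ``classified`` (e.g.
    ``'dkolh'``) or an aligned boolean mask; None selects all records.
    ``band_width`` of 10 regroups the population's 5-year bands by summing
    adjacent cells.  Records whose age falls outside population coverage
    are excluded and counted in ``meta['excluded_records']``.
    """
    if band_width % 5 or band_width <= 0:
        raise ValidationError("band_width must be a positive multiple of 5")
    pop = pop.regrouped(band_width // 5)
    bands = _bands_in_window(pop.age_groups, window)
    if not bands:
        raise ValidationError(f"no population bands inside window {window}")

    if selection is None:
        sub = classified
    elif isinstance(selection, str):
        sub = classified[classified[selection].astype(bool)]
    else:
        sub = classified[np.asarray(selection, dtype=bool)]

    lo_edges = np.array([b[0] for b in bands])
    hi_edges = np.array([np.inf if b[1] is None else b[1] for b in bands])
    ages = sub["age"].to_numpy()
    idx = np.searchsorted(lo_edges, ages, side="right") - 1
    ok = (idx >= 0) & (ages < hi_edges[np.clip(idx, 0, len(bands) - 1)])
    excluded = int((~ok).sum())
    sub = sub.loc[ok].copy()
    sub["age_lo"] = lo_edges[idx[ok]]

    counts = (
        sub.groupby(["year", "sex", "age_lo"]).size().rename("deaths").reset_index()
    )
    popf = pop.frame[pop.frame["age_lo"].isin(lo_edges)]
    grid = popf.rename(columns={"count": "person_years"})
    merged = grid.merge(counts, on=["year", "sex", "age_lo"], how="left")
    merged["deaths"] = merged["deaths"].fillna(0).astype(int)
    merged["rate"] = 1e5 * merged["deaths"] / merged["person_years"]
    meta = {
        "band_width": band_width,
        "window": window,
        "excluded_records": excluded,
        "selection": selection if isinstance(selection, str) else "<mask>",
    }
    return RateSeries(
        merged[["year", "sex", "age_lo", "age_hi", "deaths", "person_years", "rate"]], meta
    )


def age_standardized_rate(
    age_rates: RateSeries,
    std: StandardPopulation,
    window: Optional[tuple[int, int]] = None,
) -> RateSeries:
    """Directly standardized rate per 100,000 by (year, sex).

    Standard weights are matched to the rate series' bands by age_lo and
    renormalized to sum to 1 over the (optionally windowed) band set; a
    band present in the rates but absent from the standard is an error.
    """
    bands = _bands_in_window(age_rates.bands, window)
    if not bands:
        raise ValidationError(f"no rate bands inside window {window}")
    weights = std.weights_for(bands)  # raises on band mismatch

    f = age_rates.frame[age_rates.frame["age_lo"].isin(weights.index)].copy()
    f["w"] = f["age_lo"].map(weights)
    f["wrate"] = f["w"] * f["rate"]
    g = f.groupby(["year", "sex"], as_index=False).agg(
        deaths=("deaths", "sum"),
        person_years=("person_years", "sum"),
        asdr=("wrate", "sum"),
        wsum=("w", "sum"),
    )
    if not np.allclose(g["wsum"], 1.0, atol=1e-9):
        raise ValidationError("standard weights do not cover every (year, sex) cell")
    lo = bands[0][0]
    hi = bands[-1][1]
    out = pd.DataFrame(
        {
            "year": g["year"],
            "sex": g["sex"],
            "age_lo": lo,
            "age_hi": hi,
            "deaths": g["deaths"],
            "person_years": g["person_years"],
            "rate": g["asdr"],
        }
    )
    meta = dict(age_rates.meta)
    meta.update({"stratum": "age-standardized", "window": window, "n_bands": len(bands)})
    return RateSeries(out, meta)
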