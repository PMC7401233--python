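"""Synthetic vital-registration world with known ground truth.

Real multiple-cause mortality unit-record files are restricted; this
module generates populations, multi-cause death certificates and a
grouped obesity-prevalence surface whose generating parameters (rate
trends, co-mention structure, cohort gradient) are known exactly, so every
downstream stage can be validated against truth.

Model sketch
------------
* Deaths arise from three cause-group Poisson processes per (year, sex,
  age band): obesity-related CVD ("dkolh_cvd"), other CVD
  ("non_dkolh_cvd") and non-CVD.  Cell means are population x rate, with
  rate = base * exp(slope * (age_mid - ref_age)) * (1 + trend/100)^(year - year0);
  the trend may step by age band.
* Every CVD death draws a latent binary obesity factor and a latent binary
  sepsis factor; each tracked cause is mentioned with probability
  logistic(base + loading * factor + age_slope * (age - 55)).  By default
  the five DKOLH-cause probabilities apply only to obesity-related-group
  deaths and at least one DKOLH mention is guaranteed there (rejection
  sampling), so the classified partition coincides with the generating
  groups; both switches can be turned off to produce fully independent
  indicators for null analyses.
* The prevalence surface is base * age-profile(age) * (1 + g/100)^(birth
  year - reference birth year): a pure cohort gradient g on top of a fixed
  age profile, aggregated to 5-year bands.

Underlying causes of CVD deaths are drawn from CVD codes outside the
tracked co-occurrence list (pulmonary embolism, cardiomyopathy, aortic
aneurysm, hypotension): a categorical UCOD over tracked causes would
inject mutual-exclusivity correlation into the mention matrix, which the
co-mention model is meant to control exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AgeBand,
    PopulationTable,
    PrevalenceSurface,
    ValidationError,
    band_ages,
    band_label,
    band_midpoint,
    five_year_bands,
    records_to_frame,
)
from .classify import DKOLH_COMPONENTS

TrendSpec = Union[float, Sequence[tuple[int, float]]]

#: representative ICD-10 code written on the certificate for each tracked cause
CAUSE_CODES: dict[str, str] = {
    "diabetes": "E119",
    "chronic_kidney_disease": "N189",
    "obesity": "E669",
    "lipidemias": "E785",
    "hypertensive_heart_disease": "I110",
    "ischemic_heart_disease": "I251",
    "cerebrovascular": "I639",
    "heart_failure": "I500",
    "copd": "J449",
    "pneumonia": "J189",
    "lung_cancer": "C349",
    "sepsis": "A419",
    "intestinal_ischemia": "K559",
    "ileus_obstruction": "K560",
}

CARDIAC_ARREST_CODE = "I469"
#: CVD UCOD pool: I-chapter codes outside the tracked cause list
CVD_UCOD_CODES = ("I269", "I429", "I719", "I959")
CVD_UCOD_PROBS = (0.32, 0.30, 0.23, 0.15)
NONCVD_UCOD_CODES = ("C509", "C189", "G309", "K709")
NONCVD_UCOD_PROBS = (0.3, 0.3, 0.25, 0.15)


def _trend_pct(trend: TrendSpec, age_lo: int) -> float:
    if isinstance(trend, (int, float)):
        return float(trend)
    steps = sorted(trend)
    val = steps[0][1]
    for thr, pct in steps:
        if age_lo >= thr:
            val = pct
    return float(val)


@dataclass(frozen=True)
class RateParams:
    """Cause-group death rate surface: log-linear in age, exponential in time.

    ``base_rate`` is per 100,000 person-years at ``ref_age``; ``age_slope``
    is the log-rate increase per year of age; ``trend`` is % per annum,
    either a scalar or age-banded steps ``[(age_lo_threshold, pct), ...]``.
    """

    base_rate: float
    ref_age: float = 55.0
    age_slope: float = 0.075
    trend: TrendSpec = 0.0

    def rate(self, year: int, year0: int, band: AgeBand) -> float:
        """Rate per person-year at the band midpoint."""
        mid = band_midpoint(band)
        pct = _trend_pct(self.trend, band[0])
        return (
            self.base_rate
            / 1e5
            * np.exp(self.age_slope * (mid - self.ref_age))
            * (1.0 + pct / 100.0) ** (year - year0)
        )

    def trend_for_band(self, band: AgeBand) -> float:
        return _trend_pct(self.trend, band[0])


@dataclass(frozen=True)
class MentionParams:
    """Mention probability of one cause on a CVD certificate (logit scale)."""

    base_logit: float
    loading: float = 0.0
    age_slope: float = 0.0
    factor: Optional[str] = None  # "obesity" | "sepsis" | None

    def prob(self, factor_on: np.ndarray | float, age: np.ndarray | float) -> np.ndarray:
        z = self.base_logit + self.loading * factor_on + self.age_slope * (np.asarray(age) - 55.0)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class MentionModel:
    """Latent-factor co-mention model for CVD death certificates.

    One Bernoulli obesity factor (prevalence ``obesity_factor_prev`` among
    obesity-related-group deaths) ties the five DKOLH causes together; a
    second Bernoulli sepsis factor (all CVD deaths) ties the septic
    digestive cluster, giving the PCA stage a competing component.
    """

    causes: dict[str, MentionParams]
    obesity_factor_prev: float = 0.55
    sepsis_factor_prev: float = 0.07
    dkolh_group_only: bool = True
    require_dkolh_mention: bool = True
    cardiac_arrest_ucod_frac: float = 0.01
    noncvd_i46_mention_frac: float = 0.03

    def __post_init__(self) -> None:
        for p in (
            self.obesity_factor_prev,
            self.sepsis_factor_prev,
            self.cardiac_arrest_ucod_frac,
            self.noncvd_i46_mention_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        for name in self.causes:
            if name not in CAUSE_CODES:
                raise ValidationError(f"mention model names unknown cause {name!r}")


def default_mention_model() -> MentionModel:
    return MentionModel(
        causes={
            "diabetes": MentionParams(-0.41, loading=1.2, factor="obesity"),
            "hypertensive_heart_disease": MentionParams(-0.94, loading=1.2, factor="obesity"),
            "chronic_kidney_disease": MentionParams(-1.27, loading=1.4, factor="obesity"),
            "lipidemias": MentionParams(-1.52, loading=1.0, factor="obesity"),
            "obesity": MentionParams(-2.20, loading=1.8, age_slope=-0.075, factor="obesity"),
            "ischemic_heart_disease": MentionParams(-0.20),
            "heart_failure": MentionParams(-1.10),
            "cerebrovascular": MentionParams(-1.73),
            "copd": MentionParams(-1.99),
            "pneumonia": MentionParams(-1.99),
            "lung_cancer": MentionParams(-3.18),
            "sepsis": MentionParams(-2.94, loading=2.2, factor="sepsis"),
            "intestinal_ischemia": MentionParams(-4.19, loading=2.6, factor="sepsis"),
            "ileus_obstruction": MentionParams(-4.41, loading=2.6, factor="sepsis"),
        }
    )


@dataclass(frozen=True)
class PrevalenceParams:
    """Obesity prevalence surface with a cohort gradient.

    log prevalence = log(base x profile(age)) + rate(age) x (year - year_ref)
    with rate(age) = [period_pct + cohort_gradient_pct x (age_ref - age)] / 100.

    ``age_coeffs`` are ascending polynomial coefficients of the age profile.
    ``period_pct`` is the annual % growth at ``age_ref``;
    ``cohort_gradient_pct`` adds that many % per year of age *younger* —
    prevalence rises faster at young ages, so successively younger birth
    cohorts accumulate more lifetime exposure at every age.  (A gradient
    acting multiplicatively on birth year alone would cancel out of the
    relative lifetime statistic; the age-graded growth is the minimal
    structure that makes it genuinely cohort-graded.)  Band values are
    single-age means, clipped to [0, 1] with a logged count.
    """

    base: float = 0.23
    age_coeffs: tuple[float, ...] = (0.25, 0.025, -1.0 / 4800.0)
    period_pct: float = 2.2
    cohort_gradient_pct: float = 0.06
    age_ref: float = 65.0
    year_ref: float = 2015.0
    years: tuple[int, int] = (1980, 2015)

    def value(self, year, age) -> np.ndarray:
        """Exact (unclipped) generating formula at single (year, age)."""
        age = np.asarray(age, dtype=float)
        profile = sum(c * age**k for k, c in enumerate(self.age_coeffs))
        rate = (self.period_pct + self.cohort_gradient_pct * (self.age_ref - age)) / 100.0
        return self.base * profile * np.exp(rate * (np.asarray(year, dtype=float) - self.year_ref))


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth parameters of one synthetic vital-registration world."""

    years: tuple[int, int] = (2005, 2017)
    sexes: tuple[str, ...] = ("female", "male")
    age_groups: tuple[AgeBand, ...] = field(default_factory=lambda: five_year_bands(0, 95))
    base_pop: float = 100_000.0
    pop_growth_pct: float = 0.0
    rate_params: dict[str, RateParams] = field(default_factory=dict)
    mention_model: MentionModel = field(default_factory=default_mention_model)
    prevalence_params: PrevalenceParams = field(default_factory=PrevalenceParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[0] > self.years[1]:
            raise ValidationError(f"empty year range {self.years}")
        if self.base_pop <= 0:
            raise ValidationError("base_pop must be > 0")
        from .types import validate_bands

        validate_bands(self.age_groups)
        known = {"dkolh_cvd", "non_dkolh_cvd", "non_cvd"}
        unknown = set(self.rate_params) - known
        if unknown:
            raise ValidationError(f"unknown cause groups {sorted(unknown)}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def to_yaml(self, path) -> None:
        """Write the scenario as a nested key/value config file."""
        import dataclasses

        import yaml

        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(clean(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["years"] = tuple(raw["years"])
        raw["sexes"] = tuple(raw["sexes"])
        raw["age_groups"] = tuple(
            (int(lo), None if hi is None else int(hi)) for lo, hi in raw["age_groups"]
        )
        raw["rate_params"] = {
            g: RateParams(
                **{
                    **p,
                    "trend": (
                        p["trend"]
                        if isinstance(p["trend"], (int, float))
                        else [tuple(step) for step in p["trend"]]
                    ),
                }
            )
            for g, p in raw["rate_params"].items()
        }
        mm = raw["mention_model"]
        mm["causes"] = {n: MentionParams(**mp) for n, mp in mm["causes"].items()}
        raw["mention_model"] = MentionModel(**mm)
        pp = raw["prevalence_params"]
        pp["age_coeffs"] = tuple(pp["age_coeffs"])
        pp["years"] = tuple(pp["years"])
        raw["prevalence_params"] = PrevalenceParams(**pp)
        return cls(**raw)

    @classmethod
    def paper_regime(cls, seed: int = 0) -> "ScenarioConfig":
        """Default study conditions: obesity-related CVD mortality rising
        (more steeply at younger ages), other CVD falling, a positive
        cohort gradient in obesity prevalence."""
        return cls(
            rate_params={
                "dkolh_cvd": RateParams(
                    base_rate=120.0,
                    trend=[(0, 2.0), (35, 4.0), (45, 3.0), (55, 2.5), (65, 1.5), (75, 2.0)],
                ),
                "non_dkolh_cvd": RateParams(base_rate=180.0, trend=-2.5),
                "non_cvd": RateParams(base_rate=400.0, age_slope=0.07, trend=-0.5),
            },
            seed=seed,
        )

    @classmethod
    def trend_recovery(cls, seed: int = 0, base_pop: float = 120_000.0) -> "ScenarioConfig":
        """Recovery benchmark: +3%/yr obesity-related vs -3%/yr other CVD over
        a 12-year span, ages 35-74 only, ~1e5 CVD deaths per replicate."""
        return cls(
            years=(2005, 2017),
            sexes=("female",),
            age_groups=five_year_bands(35, 75, open_end=False),
            base_pop=base_pop,
            rate_params={
                "dkolh_cvd": RateParams(base_rate=250.0, trend=3.0),
                "non_dkolh_cvd": RateParams(base_rate=375.0, trend=-3.0),
            },
            seed=seed,
        )

    @classmethod
    def independence(cls, seed: int = 0, base_pop: float = 400_000.0) -> "ScenarioConfig":
        """No latent structure: all loadings zero, DKOLH probabilities applied
        to every CVD death, no guaranteed DKOLH mention — mention indicators
        are iid Bernoulli."""
        mm = default_mention_model()
        causes = {n: replace(p, loading=0.0) for n, p in mm.causes.items()}
        return cls(
            years=(2010, 2016),
            sexes=("female",),
            age_groups=five_year_bands(35, 75, open_end=False),
            base_pop=base_pop,
            rate_params={"dkolh_cvd": RateParams(base_rate=300.0, trend=0.0)},
            mention_model=replace(
                mm,
                causes=causes,
                dkolh_group_only=False,
                require_dkolh_mention=False,
                cardiac_arrest_ucod_frac=0.0,
            ),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# generators


def generate_population(config: ScenarioConfig) -> PopulationTable:
    """Deterministic population counts per (year, sex, age band)."""
    y0 = config.years[0]
    growth = 1.0 + config.pop_growth_pct / 100.0
    rows = [
        (year, sex, band[0], band[1], config.base_pop * growth ** (year - y0))
        for year in config.year_list
        for sex in config.sexes
        for band in config.age_groups
    ]
    return PopulationTable(
        pd.DataFrame(rows, columns=["year", "sex", "age_lo", "age_hi", "count"])
    )


def _cell_means(config: ScenarioConfig) -> pd.DataFrame:
    """Expected death counts per (year, sex, band, cause group)."""
    y0 = config.years[0]
    growth = 1.0 + config.pop_growth_pct / 100.0
    rows = []
    for year in config.year_list:
        popc = config.base_pop * growth ** (year - y0)
        for sex in config.sexes:
            for band in config.age_groups:
                for group, rp in config.rate_params.items():
                    lam = popc * rp.rate(year, y0, band)
                    if lam > popc:
                        raise ValidationError(
                            f"rate implies {lam:.0f} expected deaths > population "
                            f"{popc:.0f} in cell (year={year}, sex={sex}, "
                            f"band={band_label(band)}, group={group})"
                        )
                    rows.append((year, sex, band[0], band[1], group, lam))
    return pd.DataFrame(
        rows, columns=["year", "sex", "age_lo", "age_hi", "group", "mean_deaths"]
    )


def _sample_mentions(
    model: MentionModel,
    group: np.ndarray,
    age: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bernoulli mention indicators for n CVD deaths (columns = cause names)."""
    n = len(age)
    is_dkolh_group = group == "dkolh_cvd"
    ob = (rng.random(n) < model.obesity_factor_prev).astype(float)
    sep = (rng.random(n) < model.sepsis_factor_prev).astype(float)
    out = {}
    for name, mp in model.causes.items():
        fac = ob if mp.factor == "obesity" else sep if mp.factor == "sepsis" else 0.0
        p = mp.prob(fac, age)
        if model.dkolh_group_only and name in DKOLH_COMPONENTS:
            p = np.where(is_dkolh_group, p, 0.0)
        out[name] = rng.random(n) < p
    ind = pd.DataFrame(out)

    if model.require_dkolh_mention:
        comp = [c for c in DKOLH_COMPONENTS if c in ind.columns]
        need = is_dkolh_group & ~ind[comp].any(axis=1).to_numpy()
        for _ in range(100):
            if not need.any():
                break
            idx = np.flatnonzero(need)
            for name in comp:
                mp = model.causes[name]
                fac = ob[idx] if mp.factor == "obesity" else sep[idx] if mp.factor == "sepsis" else 0.0
                p = mp.prob(fac, age[idx])
                ind.iloc[idx, ind.columns.get_loc(name)] = rng.random(len(idx)) < p
            need = is_dkolh_group & ~ind[comp].any(axis=1).to_numpy()
        if need.any():
            # pathological probabilities: force the most probable component
            ind.loc[need, comp[0]] = True
    return ind


def _assemble_entity_strings(ucods: np.ndarray, other_codes: list[list[str]]) -> list[str]:
    """Deterministic certificate layout: non-underlying mentions fill part-1
    lines 1-2 then part 2; the UCOD sits on part-1 line 3 (the bottom line)."""
    out = []
    for u, codes in zip(ucods, other_codes):
        toks = []
        for i, c in enumerate(codes):
            if i < 2:
                toks.append(f"1:{i + 1}:1:{c}")
            else:
                toks.append(f"2:1:{i - 1}:{c}")
        toks.append(f"1:3:1:{u}")
        out.append(";".join(toks))
    return out


def generate_deaths(config: ScenarioConfig) -> pd.DataFrame:
    """Sample the scenario's death certificates; returns the canonical record frame.

    Deterministic for a fixed config (including seed).  Use
    :func:`mcodcvd.types.frame_to_records` for DeathRecord objects.
    """
    rng = np.random.default_rng(config.seed)
    cells = _cell_means(config)
    counts = rng.poisson(cells["mean_deaths"].to_numpy())
    n = int(counts.sum())
    if n == 0:
        return pd.DataFrame(
            columns=["id", "year", "sex", "age", "ucod", "entity_mentions", "record_axis"]
        )

    year = np.repeat(cells["year"].to_numpy(), counts)
    sex = np.repeat(cells["sex"].to_numpy(), counts)
    age_lo = np.repeat(cells["age_lo"].to_numpy(dtype=int), counts)
    cell_width = np.array(
        [
            5 if pd.isna(hi) else int(hi) - int(lo)
            for lo, hi in zip(cells["age_lo"], cells["age_hi"])
        ]
    )
    width = np.repeat(cell_width, counts)
    group = np.repeat(cells["group"].to_numpy(), counts)
    age = age_lo + rng.integers(0, width)

    is_cvd = group != "non_cvd"
    model = config.mention_model
    ucod = np.empty(n, dtype=object)
    mention_codes: list[list[str]] = [[] for _ in range(n)]

    cvd_idx = np.flatnonzero(is_cvd)
    if len(cvd_idx):
        ind = _sample_mentions(model, group[cvd_idx], age[cvd_idx].astype(float), rng)
        u = rng.choice(np.array(CVD_UCOD_CODES, dtype=object), size=len(cvd_idx), p=CVD_UCOD_PROBS)
        ca = rng.random(len(cvd_idx)) < model.cardiac_arrest_ucod_frac
        u[ca] = CARDIAC_ARREST_CODE
        ucod[cvd_idx] = u
        names = list(ind.columns)
        codes = [CAUSE_CODES[c] for c in names]
        mat = ind.to_numpy()
        for row, j in enumerate(cvd_idx):
            mention_codes[j] = [codes[k] for k in np.flatnonzero(mat[row])]

    non_idx = np.flatnonzero(~is_cvd)
    if len(non_idx):
        u = rng.choice(
            np.array(NONCVD_UCOD_CODES, dtype=object), size=len(non_idx), p=NONCVD_UCOD_PROBS
        )
        ucod[non_idx] = u
        pneu = rng.random(len(non_idx)) < 0.15
        i46 = rng.random(len(non_idx)) < model.noncvd_i46_mention_frac
        for row, j in enumerate(non_idx):
            codes = []
            if pneu[row]:
                codes.append(CAUSE_CODES["pneumonia"])
            if i46[row]:
                codes.append(CARDIAC_ARREST_CODE)
            mention_codes[j] = codes

    entity = _assemble_entity_strings(ucod, mention_codes)
    record_axis = [
        ";".join(sorted(set(codes) | {u})) for u, codes in zip(ucod, mention_codes)
    ]
    frame = pd.DataFrame(
        {
            "id": [f"d{config.seed}-{i}" for i in range(n)],
            "year": year.astype(int),
            "sex": sex,
            "age": age.astype(int),
            "ucod": ucod.astype(str),
            "entity_mentions": entity,
            "record_axis": record_axis,
        }
    )
    return frame


def generate_prevalence_surface(config: ScenarioConfig) -> PrevalenceSurface:
    """Grouped prevalence surface (band value = mean of its single-age values)."""
    pp = config.prevalence_params
    rows = []
    clipped = 0
    for year in range(pp.years[0], pp.years[1] + 1):
        for sex in config.sexes:
            for band in config.age_groups:
                ages = np.array(list(band_ages(band)), dtype=float)
                vals = pp.value(year, ages)
                clipped += int(((vals < 0) | (vals > 1)).sum())
                v = float(np.clip(vals, 0.0, 1.0).mean())
                rows.append((year, sex, band[0], band[1], v))
    if clipped:
        import logging

        logging.getLogger(__name__).warning(
            "prevalence surface clipped %d single-age values to [0, 1]", clipped
        )
    return PrevalenceSurface(
        pd.DataFrame(rows, columns=["year", "sex", "age_lo", "age_hi", "prevalence"])
    )


# ---------------------------------------------------------------------------
# ground truth


def _enumerate_dkolh_mention_prob(model: MentionModel, age: float, in_dkolh_group: bool) -> float:
    """P(>=1 DKOLH mention) by exhaustive enumeration over factor x 2^5 outcomes."""
    comps = [c for c in DKOLH_COMPONENTS if c in model.causes]
    if model.dkolh_group_only and not in_dkolh_group:
        return 0.0
    if model.require_dkolh_mention and in_dkolh_group:
        return 1.0
    total = 0.0
    for f, pf in ((1.0, model.obesity_factor_prev), (0.0, 1.0 - model.obesity_factor_prev)):
        probs = []
        for c in comps:
            mp = model.causes[c]
            fac = f if mp.factor == "obesity" else 0.0  # sepsis factor never loads on DKOLH
            probs.append(float(mp.prob(fac, age)))
        p_any = 0.0
        for outcome in itertools.product((0, 1), repeat=len(comps)):
            if not any(outcome):
                continue
            p = 1.0
            for o, pc in zip(outcome, probs):
                p *= pc if o else 1.0 - pc
            p_any += p
        total += pf * p_any
    return total


def _expected_classified(config: ScenarioConfig, year: int, band: AgeBand) -> tuple[float, float]:
    """Expected (DKOLH, non-DKOLH) classified CVD MCOD deaths in one
    (year, band) cell, summed over sexes, by enumeration of the mention model."""
    y0 = config.years[0]
    growth = 1.0 + config.pop_growth_pct / 100.0
    popc = config.base_pop * growth ** (year - y0)
    ages = list(band_ages(band))
    dk = nd = 0.0
    for group in ("dkolh_cvd", "non_dkolh_cvd"):
        rp = config.rate_params.get(group)
        if rp is None:
            continue
        lam = popc * rp.rate(year, y0, band) * len(config.sexes)
        q = float(
            np.mean(
                [
                    _enumerate_dkolh_mention_prob(
                        config.mention_model, a, in_dkolh_group=(group == "dkolh_cvd")
                    )
                    for a in ages
                ]
            )
        )
        dk += lam * q
        nd += lam * (1.0 - q)
    return dk, nd


@dataclass
class GroundTruth:
    """Exact recovery targets derived from a ScenarioConfig (no sampling)."""

    config: ScenarioConfig

    def annual_pct_change(self, group: str, band: Optional[AgeBand] = None) -> float:
        """Configured annual % trend of a cause group (optionally one band)."""
        rp = self.config.rate_params[group]
        if band is not None:
            return rp.trend_for_band(band)
        trends = {rp.trend_for_band(b) for b in self.config.age_groups}
        if len(trends) > 1:
            raise ValidationError(
                "trend differs by age band; pass a band or use annualized_change()"
            )
        return trends.pop()

    def annualized_change(
        self,
        group: str,
        band: Optional[AgeBand] = None,
        weights: Optional[Sequence[float]] = None,
        window: tuple[int, int] = (35, 75),
    ) -> float:
        """Exact annualized % change of the classified group's (weighted) rate
        between the first and last scenario year."""
        y0, y1 = self.config.years
        bands = (
            [band]
            if band is not None
            else [
                b
                for b in self.config.age_groups
                if b[0] >= window[0] and b[1] is not None and b[1] <= window[1]
            ]
        )
        if weights is None:
            weights = [1.0 / len(bands)] * len(bands)
        idx = 0 if group == "dkolh_cvd" else 1

        def wrate(year: int) -> float:
            growth = 1.0 + self.config.pop_growth_pct / 100.0
            popc = self.config.base_pop * growth ** (year - y0) * len(self.config.sexes)
            return sum(
                w * _expected_classified(self.config, year, b)[idx] / popc
                for w, b in zip(weights, bands)
            )

        r0, r1 = wrate(y0), wrate(y1)
        return 100.0 * ((r1 / r0) ** (1.0 / (y1 - y0)) - 1.0)

    def dkolh_share(self, window: tuple[int, int] = (35, 75)) -> float:
        """Expected DKOLH share of CVD MCOD deaths over the window and period."""
        bands = [
            b
            for b in self.config.age_groups
            if b[0] >= window[0] and b[1] is not None and b[1] <= window[1]
        ]
        dk = nd = 0.0
        for year in self.config.year_list:
            for b in bands:
                d, n = _expected_classified(self.config, year, b)
                dk += d
                nd += n
        # cardiac-arrest-UCOD deaths remain inside their group: the UCOD gate
        # keeps them CVD MCOD, so the share is unaffected.
        return dk / (dk + nd)

    def relative_prevalence(
        self,
        cohort_band: AgeBand,
        reference_year: int,
        min_age: int = 5,
        max_age: int = 99,
    ) -> float:
        """Exact cohort relative lifetime prevalence from the generating formula."""
        pp = self.config.prevalence_params
        years = range(pp.years[0], pp.years[1] + 1)
        cells = []
        for a0 in band_ages(cohort_band):
            for y in years:
                a = a0 - (reference_year - y)
                if min_age <= a <= max_age:
                    cells.append((y, a))
        if not cells:
            return float("nan")
        ages = sorted({a for _, a in cells})
        cohort = float(np.mean([np.clip(pp.value(y, a), 0, 1) for y, a in cells]))
        denom = float(
            np.mean([np.clip(pp.value(y, a), 0, 1) for y in years for a in ages])
        )
        return 100.0 * (cohort / denom - 1.0)


def ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Recovery targets implied by a scenario; a pure function of the config."""
    return GroundTruth(config)
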