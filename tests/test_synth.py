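"""Generator laws: determinism, Poisson counts, mention independence, ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mcodcvd.classify import DKOLH_COMPONENTS, CauseSetConfig, classify_frame
from mcodcvd.synth import (
    MentionParams,
    PrevalenceParams,
    RateParams,
    ScenarioConfig,
    default_mention_model,
    generate_deaths,
    generate_population,
    generate_prevalence_surface,
    ground_truth,
)
from mcodcvd.types import ValidationError, five_year_bands


def one_cell_scenario(rate=100.0, base_pop=100_000.0, seed=0, trend=0.0):
    return ScenarioConfig(
        years=(2010, 2010),
        sexes=("female",),
        age_groups=((55, 60),),
        base_pop=base_pop,
        rate_params={"dkolh_cvd": RateParams(base_rate=rate, ref_age=57.0, age_slope=0.0, trend=trend)},
        seed=seed,
    )


class TestPopulation:
    def test_constant_population_fills_every_cell(self):
        sc = ScenarioConfig(
            years=(2010, 2011),
            sexes=("female",),
            age_groups=five_year_bands(35, 95),
            base_pop=100_000,
            rate_params={},
        )
        pop = generate_population(sc)
        assert len(pop.frame) == 2 * 13
        assert (pop.frame["count"] == 100_000).all()

    def test_growth_rate_is_exact(self):
        sc = ScenarioConfig(years=(2000, 2005), pop_growth_pct=1.0, rate_params={})
        pop = generate_population(sc)
        piv = pop.frame.pivot_table(index="year", columns=["sex", "age_lo"], values="count")
        ratios = piv.iloc[1:].to_numpy() / piv.iloc[:-1].to_numpy()
        assert np.allclose(ratios, 1.01, rtol=0, atol=1e-12)

    def test_total_matches_independent_loop(self):
        sc = ScenarioConfig(years=(2001, 2003), pop_growth_pct=0.7, rate_params={})
        pop = generate_population(sc)
        expected = 0.0
        for year in (2001, 2002, 2003):
            for _sex in sc.sexes:
                for _band in sc.age_groups:
                    expected += sc.base_pop * 1.007 ** (year - 2001)
        assert pop.frame["count"].sum() == pytest.approx(expected, rel=1e-12)

    def test_bad_band_ordering_is_config_error(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(age_groups=((10, 5), (5, None)), rate_params={})


class TestDeaths:
    def test_identical_config_gives_identical_records(self):
        sc = ScenarioConfig.trend_recovery(seed=42, base_pop=2_000)
        f1, f2 = generate_deaths(sc), generate_deaths(sc)
        pd.testing.assert_frame_equal(f1, f2)

    def test_different_seed_changes_records(self):
        a = generate_deaths(ScenarioConfig.trend_recovery(seed=1, base_pop=2_000))
        b = generate_deaths(ScenarioConfig.trend_recovery(seed=2, base_pop=2_000))
        assert not a.equals(b)

    def test_death_counts_follow_poisson_law(self):
        # rate 100/100k on pop 100k => mean 100, sd 10; 2000 replicates
        means = []
        for seed in range(2000):
            means.append(len(generate_deaths(one_cell_scenario(seed=seed))))
        grand = np.mean(means)
        se = 10.0 / np.sqrt(len(means))
        assert abs(grand - 100.0) < 3 * se
        assert np.var(means) == pytest.approx(100.0, rel=0.15)

    def test_rate_exceeding_population_is_config_error(self):
        with pytest.raises(ValidationError, match="population"):
            generate_deaths(one_cell_scenario(rate=2e5))

    def test_every_record_has_a_mention_and_age_in_band(self):
        frame = generate_deaths(one_cell_scenario(seed=3))
        assert (frame["entity_mentions"].str.len() > 0).all()
        assert frame["age"].between(55, 59).all()
        assert frame["entity_mentions"].str.contains("1:3:1:").all()  # UCOD bottom line

    def test_degenerate_probabilities_yield_only_non_dkolh(self):
        mm = default_mention_model()
        causes = {
            n: (dataclasses.replace(p, base_logit=-60.0, loading=0.0)
                if n in DKOLH_COMPONENTS else p)
            for n, p in mm.causes.items()
        }
        sc = dataclasses.replace(
            one_cell_scenario(rate=500, seed=5),
            mention_model=dataclasses.replace(
                mm, causes=causes, dkolh_group_only=False, require_dkolh_mention=False,
                cardiac_arrest_ucod_frac=0.0,
            ),
        )
        classed = classify_frame(generate_deaths(sc), CauseSetConfig.default())
        assert classed["cvd_mcod"].all()
        assert not classed["dkolh"].any()

    def test_zero_loadings_give_uncorrelated_dkolh_mentions(self):
        sc = ScenarioConfig.independence(seed=9, base_pop=250_000)
        classed = classify_frame(generate_deaths(sc), CauseSetConfig.default())
        cols = [f"has_{n}" for n in DKOLH_COMPONENTS]
        sub = classed.loc[classed["cvd_mcod"], cols].astype(float)
        assert len(sub) > 50_000
        phi = np.corrcoef(sub.to_numpy(), rowvar=False)
        off = phi[~np.eye(len(cols), dtype=bool)]
        assert np.abs(off).max() < 0.02


class TestPrevalenceSurface:
    def test_flat_profile_no_gradient_is_constant(self):
        sc = ScenarioConfig(
            rate_params={},
            prevalence_params=PrevalenceParams(
                base=0.2, age_coeffs=(1.0,), period_pct=0.0, cohort_gradient_pct=0.0
            ),
        )
        surf = generate_prevalence_surface(sc)
        assert np.allclose(surf.frame["prevalence"], 0.2, atol=1e-12)

    def test_positive_gradient_makes_prevalence_rise_in_year(self):
        surf = generate_prevalence_surface(ScenarioConfig.paper_regime())
        for (_sex, _lo), grp in surf.frame.groupby(["sex", "age_lo"]):
            vals = grp.sort_values("year")["prevalence"].to_numpy()
            assert (np.diff(vals) > 0).all()

    def test_cells_match_generating_formula(self):
        sc = ScenarioConfig.paper_regime()
        pp = sc.prevalence_params
        surf = generate_prevalence_surface(sc)
        sample = surf.frame.sample(100, random_state=1)
        for row in sample.itertuples():
            lo = int(row.age_lo)
            hi = lo + 5 if pd.isna(row.age_hi) else int(row.age_hi)
            ages = np.arange(lo, hi)
            expected = np.clip(pp.value(row.year, ages), 0, 1).mean()
            assert row.prevalence == pytest.approx(expected, abs=1e-12)


class TestGroundTruth:
    def test_configured_trend_passes_through(self):
        sc = ScenarioConfig.trend_recovery()
        gt = ground_truth(sc)
        assert gt.annual_pct_change("dkolh_cvd") == 3.0
        assert gt.annualized_change("dkolh_cvd") == pytest.approx(3.0, abs=1e-9)
        assert gt.annualized_change("non_dkolh_cvd") == pytest.approx(-3.0, abs=1e-9)

    def test_symmetric_groups_give_half_share(self):
        sc = dataclasses.replace(
            ScenarioConfig.trend_recovery(),
            rate_params={
                "dkolh_cvd": RateParams(base_rate=200.0, trend=0.0),
                "non_dkolh_cvd": RateParams(base_rate=200.0, trend=0.0),
            },
        )
        assert ground_truth(sc).dkolh_share() == pytest.approx(0.5, abs=1e-12)

    def test_share_matches_hand_enumeration_without_gating(self):
        # one cell, DKOLH probabilities applied to every CVD death, no
        # guaranteed mention: share = P(>=1 DKOLH mention), enumerated here
        # independently over the factor and the 2^5 outcomes.
        mm = default_mention_model()
        sc = dataclasses.replace(
            one_cell_scenario(rate=300.0),
            mention_model=dataclasses.replace(
                mm, dkolh_group_only=False, require_dkolh_mention=False
            ),
        )
        gt = ground_truth(sc)
        comps = [c for c in DKOLH_COMPONENTS]
        expect = 0.0
        for age in range(55, 60):
            for f, pf in ((1.0, mm.obesity_factor_prev), (0.0, 1.0 - mm.obesity_factor_prev)):
                p_none = 1.0
                for c in comps:
                    mp = mm.causes[c]
                    z = mp.base_logit + mp.loading * f + mp.age_slope * (age - 55.0)
                    p_none *= 1.0 - 1.0 / (1.0 + np.exp(-z))
                expect += pf * (1.0 - p_none) / 5.0
        assert gt.dkolh_share(window=(55, 60)) == pytest.approx(expect, abs=1e-12)

    def test_share_recovered_empirically_within_two_points(self):
        sc = ScenarioConfig.trend_recovery(seed=17, base_pop=60_000)
        classed = classify_frame(generate_deaths(sc), CauseSetConfig.default())
        empirical = classed["dkolh"].sum() / classed["cvd_mcod"].sum()
        truth = ground_truth(sc).dkolh_share()
        assert classed["cvd_mcod"].sum() >= 50_000
        assert abs(empirical - truth) < 0.02

    def test_relative_prevalence_monotone_under_positive_gradient(self):
        gt = ground_truth(ScenarioConfig.paper_regime())
        vals = [gt.relative_prevalence((lo, lo + 5), 2017) for lo in range(35, 75, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_underage_cohort_is_undefined(self):
        gt = ground_truth(ScenarioConfig.paper_regime())
        assert np.isnan(gt.relative_prevalence((0, 5), 2017))


class TestScenarioSerialization:
    def test_yaml_round_trip_preserves_every_parameter(self, tmp_path):
        for sc in (ScenarioConfig.paper_regime(seed=4), ScenarioConfig.trend_recovery(seed=1)):
            path = tmp_path / "scenario.yaml"
            sc.to_yaml(path)
            assert ScenarioConfig.from_yaml(path) == sc

    def test_round_tripped_scenario_generates_identical_records(self, tmp_path):
        sc = ScenarioConfig.trend_recovery(seed=6, base_pop=1_500)
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        back = ScenarioConfig.from_yaml(path)
        pd.testing.assert_frame_equal(generate_deaths(sc), generate_deaths(back))
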