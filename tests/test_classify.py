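"""Cause-set membership, the CVD/DKOLH taxonomy, and certificate diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mcodcvd.classify import (
    DKOLH_COMPONENTS,
    CauseSet,
    CauseSetConfig,
    avg_causes_per_death,
    axis_delta,
    classify,
    classify_frame,
    code_in_set,
    pct_with_cause,
)
from mcodcvd.synth import ScenarioConfig, generate_deaths
from mcodcvd.types import DeathRecord, Mention, ValidationError, five_year_bands


def make_record(ucod, mention_codes=(), age=60, year=2010, sex="m", record_axis=None):
    mentions = [Mention(1, i + 1, 1, c) for i, c in enumerate(mention_codes)]
    if ucod not in mention_codes:
        mentions.append(Mention(1, 3, 1, ucod))
    return DeathRecord(
        id="t", year=year, sex=sex, age=age, ucod=ucod,
        entity_mentions=tuple(mentions), record_axis=record_axis,
    )


class TestCodeInSet:
    @pytest.mark.parametrize(
        "code,spec,expected",
        [
            ("I251", ["I00-I99"], True),
            ("E119", ["E10-E14"], True),
            ("E159", ["E10-E14"], False),
            ("I46", ["I46"], True),
            ("I469", ["I46"], True),
            ("J449", ["I00-I99"], False),
        ],
    )
    def test_membership_examples(self, code, spec, expected):
        assert code_in_set(code, CauseSet.from_spec(spec)) is expected

    @given(st.integers(0, 2599), st.integers(0, 2599))
    def test_range_matches_brute_force_over_all_stems(self, a, b):
        stems = [f"{ch}{i:02d}" for ch in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" for i in range(100)]
        lo, hi = sorted((stems[a], stems[b]))
        cs = CauseSet(ranges=((lo, hi),))
        match = cs.match(pd.Series(stems))
        brute = np.array([lo <= s <= hi for s in stems])
        assert (match == brute).all()

    def test_reversed_range_rejected(self):
        with pytest.raises(ValidationError):
            CauseSet(ranges=(("I99", "I00"),))


class TestConfigInvariants:
    def test_cardiac_arrest_must_lie_inside_cvd(self):
        cfg = CauseSetConfig.default()
        sets = dict(cfg.sets)
        sets["cardiac_arrest"] = CauseSet.from_spec(["R99"])
        with pytest.raises(ValidationError, match="not inside CVD"):
            CauseSetConfig(sets=sets, tracked=cfg.tracked)

    def test_overlapping_dkolh_components_rejected(self):
        cfg = CauseSetConfig.default()
        sets = dict(cfg.sets)
        sets["lipidemias"] = CauseSet.from_spec(["E78", "E10"])
        with pytest.raises(ValidationError, match="overlap"):
            CauseSetConfig(sets=sets, tracked=cfg.tracked)

    def test_yaml_round_trip(self, tmp_path, cause_config):
        path = tmp_path / "causes.yaml"
        cause_config.to_yaml(path)
        back = CauseSetConfig.from_yaml(path)
        assert back.tracked == cause_config.tracked
        assert back.sets == cause_config.sets


class TestClassify:
    def test_cardiac_arrest_as_ucod_is_cvd_mcod(self, cause_config):
        rec = make_record("I469")
        cls = classify(rec, cause_config)
        assert cls.cvd_mcod and cls.cvd_ucod and not cls.dkolh

    def test_cardiac_arrest_mention_only_is_not_cvd_mcod(self, cause_config):
        rec = make_record("C349", mention_codes=("I469",))
        cls = classify(rec, cause_config)
        assert not cls.cvd_mcod and not cls.cvd_ucod

    def test_noncvd_ucod_with_cvd_and_diabetes_mentions_is_dkolh(self, cause_config):
        rec = make_record("J449", mention_codes=("I500", "E119"))
        cls = classify(rec, cause_config)
        assert cls.cvd_mcod and not cls.cvd_ucod
        assert cls.dkolh and cls.components == {"diabetes"}

    def test_dkolh_requires_cvd_gate(self, cause_config):
        # diabetes UCOD without any CVD involvement is not DKOLH-CVD
        rec = make_record("E119")
        cls = classify(rec, cause_config)
        assert not cls.cvd_mcod and not cls.dkolh

    def test_frame_path_agrees_with_record_path(self, cause_config, small_scenario_frame):
        _, frame, classed = small_scenario_frame
        sample = frame.sample(300, random_state=0)
        from mcodcvd.types import frame_to_records

        for rec, (_, row) in zip(frame_to_records(sample), classed.loc[sample.index].iterrows()):
            cls = classify(rec, cause_config)
            assert cls.cvd_mcod == row["cvd_mcod"]
            assert cls.dkolh == row["dkolh"]

    def test_partition_is_exact(self, small_scenario_frame):
        _, _, classed = small_scenario_frame
        n_dkolh = int(classed["dkolh"].sum())
        n_non = int((classed["cvd_mcod"] & ~classed["dkolh"]).sum())
        assert n_dkolh + n_non == int(classed["cvd_mcod"].sum())

    def test_adding_diabetes_mention_never_unsets_dkolh(self, cause_config):
        base = make_record("I219", mention_codes=("I500",))
        assert not classify(base, cause_config).dkolh
        with_diab = make_record("I219", mention_codes=("I500", "E119"))
        assert classify(with_diab, cause_config).dkolh
        also = make_record("I219", mention_codes=("I500", "E669", "E119"))
        assert classify(also, cause_config).dkolh

    def test_record_axis_requested_but_absent_errors(self, cause_config):
        frame = pd.DataFrame(
            {
                "id": ["a"], "year": [2010], "sex": ["m"], "age": [50],
                "ucod": ["I219"], "entity_mentions": ["1:3:1:I219"], "record_axis": [""],
            }
        )
        with pytest.raises(ValidationError, match="record-axis"):
            classify_frame(frame, cause_config, axis="record")


class TestDiagnostics:
    def test_avg_causes_single_cause_records(self, cause_config):
        frame = pd.DataFrame(
            {
                "id": ["a", "b"], "year": [2010, 2010], "sex": ["m", "m"], "age": [50, 55],
                "ucod": ["I219", "I219"],
                "entity_mentions": ["1:3:1:I219", "1:3:1:I219"],
                "record_axis": ["", ""],
            }
        )
        classed = classify_frame(frame, cause_config)
        assert avg_causes_per_death(classed).loc[2010] == 1.0

    def test_avg_causes_arithmetic(self, cause_config):
        frame = pd.DataFrame(
            {
                "id": ["a", "b"], "year": [2011, 2011], "sex": ["m", "m"], "age": [50, 55],
                "ucod": ["I219", "I219"],
                "entity_mentions": [
                    "1:1:1:E119;1:3:1:I219",  # IHD + diabetes = 2 tracked
                    "1:1:1:E119;1:2:1:N189;2:1:1:I500;1:3:1:I219",  # 4 tracked
                ],
                "record_axis": ["", ""],
            }
        )
        classed = classify_frame(frame, cause_config)
        assert avg_causes_per_death(classed).loc[2011] == 3.0

    def test_avg_causes_matches_brute_recount(self, cause_config, small_scenario_frame):
        _, frame, classed = small_scenario_frame
        from mcodcvd.types import frame_to_records

        sub_frame = frame.head(500)
        sub_classed = classed.head(500)
        got = avg_causes_per_death(sub_classed)
        sets = {n: cause_config.sets[n] for n in cause_config.tracked}
        by_year: dict[int, list[int]] = {}
        for rec, cvd in zip(frame_to_records(sub_frame), sub_classed["cvd_mcod"]):
            if not cvd:
                continue
            codes = rec.mention_codes()
            n = sum(1 for s in sets.values() if any(s.contains(c) for c in codes))
            by_year.setdefault(rec.year, []).append(n)
        for year, ns in by_year.items():
            assert got.loc[year] == pytest.approx(np.mean(ns))

    def test_pct_with_cause_extremes_and_empty_band(self, cause_config):
        frame = pd.DataFrame(
            {
                "id": ["a", "b"], "year": [2010, 2010], "sex": ["m", "m"], "age": [37, 52],
                "ucod": ["I219", "I219"],
                "entity_mentions": ["1:1:1:E669;1:3:1:I219", "1:1:1:E669;1:3:1:I219"],
                "record_axis": ["", ""],
            }
        )
        classed = classify_frame(frame, cause_config)
        bands = five_year_bands(35, 75, open_end=False)
        pct_ob = pct_with_cause(classed, "obesity", bands)
        assert pct_ob["35-39"] == 100.0
        assert pct_ob["50-54"] == 100.0
        assert np.isnan(pct_ob["40-44"])  # no DKOLH deaths there
        pct_ck = pct_with_cause(classed, "chronic_kidney_disease", bands)
        assert pct_ck["35-39"] == 0.0

    def test_pct_with_cause_declines_with_age_in_synth_scenario(self, small_scenario_frame, cause_config):
        _, _, classed = small_scenario_frame
        bands = five_year_bands(35, 75, open_end=False)
        pct = pct_with_cause(classed, "obesity", bands).dropna()
        # the generator's obesity mention probability falls with age
        assert pct.iloc[0] > pct.iloc[-1]
        # matches a direct tabulation
        sub = classed[classed["dkolh"] & (classed["age"] >= 35) & (classed["age"] < 40)]
        assert pct["35-39"] == pytest.approx(100 * sub["has_obesity"].mean())

    def test_axis_delta_harness_reports_both_axes(self, small_scenario_frame):
        _, frame, _ = small_scenario_frame
        out = axis_delta(frame.head(2000), CauseSetConfig.default())
        assert {"cvd_mcod_delta", "dkolh_delta"} <= set(out.columns)
        # synthetic record axis mirrors entity mentions, so deltas are zero here
        assert (out["cvd_mcod_delta"] == 0).all()
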