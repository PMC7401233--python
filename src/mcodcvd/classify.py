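"""Cause-of-death taxonomy for overweight/obesity-related CVD mortality.

A death is *CVD MCOD* when cardiovascular disease appears anywhere on the
certificate, with one carve-out: cardiac arrest only counts when it is the
underlying cause, because as a mere mention it can be the terminal event of
an entirely non-cardiovascular death.  CVD MCOD deaths are then partitioned
into *DKOLH-CVD* — any mention of Diabetes, chronic Kidney disease, Obesity,
Lipidemias, or Hypertensive heart disease, the cause cluster most strongly
associated with excess body weight — and *non-DKOLH-CVD* (all the rest).

Cause sets are ICD-10 prefix/range collections and are fully configurable;
the defaults below use standard ICD-10 groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import AgeBand, DeathRecord, ValidationError, band_for_age, band_label

# ---------------------------------------------------------------------------
# cause sets


@dataclass(frozen=True)
class CauseSet:
    """A named set of ICD-10 codes given as prefixes and inclusive 3-character ranges.

    A code belongs to the set when it starts with one of ``prefixes`` or its
    3-character stem falls inside one of ``ranges`` (inclusive at both ends),
    e.g. ``I251`` is inside ``("I00", "I99")``.
    """

    prefixes: tuple[str, ...] = ()
    ranges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in self.ranges:
            if len(lo) != 3 or len(hi) != 3:
                raise ValidationError(f"range bounds must be 3-character stems: {lo}-{hi}")
            if lo > hi:
                raise ValidationError(f"reversed code range {lo}-{hi}")

    @classmethod
    def from_spec(cls, items: Iterable[str]) -> "CauseSet":
        """Parse items like ``"I46"`` (prefix) or ``"I00-I99"`` (stem range)."""
        prefixes: list[str] = []
        ranges: list[tuple[str, str]] = []
        for item in items:
            item = item.strip().upper().replace(".", "")
            if "-" in item:
                lo, hi = item.split("-")
                ranges.append((lo, hi))
            else:
                prefixes.append(item)
        return cls(tuple(prefixes), tuple(ranges))

    def to_spec(self) -> list[str]:
        return list(self.prefixes) + [f"{lo}-{hi}" for lo, hi in self.ranges]

    def contains(self, code: str) -> bool:
        stem = code[:3]
        return any(code.startswith(p) for p in self.prefixes) or any(
            lo <= stem <= hi for lo, hi in self.ranges
        )

    def match(self, codes: pd.Series) -> np.ndarray:
        """Vectorized membership test for a Series of normalized codes."""
        hit = np.zeros(len(codes), dtype=bool)
        s = codes.to_numpy(dtype=object)
        for p in self.prefixes:
            hit |= np.char.startswith(s.astype(str), p)
        if self.ranges:
            stems = codes.str.slice(0, 3).to_numpy(dtype=str)
            for lo, hi in self.ranges:
                hit |= (stems >= lo) & (stems <= hi)
        return hit


def code_in_set(code: str, cause_set: CauseSet) -> bool:
    """True iff a normalized ICD-10 code belongs to the cause set."""
    return cause_set.contains(code)


DKOLH_COMPONENTS = (
    "diabetes",
    "chronic_kidney_disease",
    "obesity",
    "lipidemias",
    "hypertensive_heart_disease",
)

_DEFAULT_SETS: dict[str, list[str]] = {
    # gates
    "cvd": ["I00-I99"],
    "cardiac_arrest": ["I46"],
    # DKOLH components (pairwise disjoint).  Hypertensive heart disease
    # includes essential hypertension (I10): as a multiple cause it carries
    # real information even though it is a classic "garbage" underlying cause.
    "diabetes": ["E10-E14"],
    "chronic_kidney_disease": ["N18"],
    "obesity": ["E65-E68"],
    "lipidemias": ["E78"],
    "hypertensive_heart_disease": ["I10-I15"],
    # other tracked causes for the co-occurrence cause list
    "ischemic_heart_disease": ["I20-I25"],
    "cerebrovascular": ["I60-I69"],
    "heart_failure": ["I50"],
    "copd": ["J40-J47"],
    "pneumonia": ["J09-J18"],
    "lung_cancer": ["C33-C34"],
    "sepsis": ["A40-A41"],
    "intestinal_ischemia": ["K55"],
    "ileus_obstruction": ["K56"],
}

_ALL_STEMS = [f"{ch}{i:02d}" for ch in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" for i in range(100)]


@dataclass
class CauseSetConfig:
    """All cause sets driving classification and the co-occurrence cause list.

    ``sets`` must contain ``cvd`` and ``cardiac_arrest`` plus the five DKOLH
    component sets; ``tracked`` lists the causes entering the mention matrix
    and the causes-per-death diagnostic (a stand-in for a full certificate
    cause list, overridable from file).
    """

    sets: dict[str, CauseSet]
    tracked: tuple[str, ...]

    def __post_init__(self) -> None:
        needed = {"cvd", "cardiac_arrest", *DKOLH_COMPONENTS}
        missing = needed - set(self.sets)
        if missing:
            raise ValidationError(f"cause config missing sets {sorted(missing)}")
        for name in self.tracked:
            if name not in self.sets:
                raise ValidationError(f"tracked cause {name!r} has no code set")
        # structural invariants checked by enumeration over all 3-char stems
        cvd, ca = self.sets["cvd"], self.sets["cardiac_arrest"]
        for stem in _ALL_STEMS:
            if ca.contains(stem) and not cvd.contains(stem):
                raise ValidationError(f"cardiac arrest set is not inside CVD set ({stem})")
        for i, a in enumerate(DKOLH_COMPONENTS):
            for b in DKOLH_COMPONENTS[i + 1:]:
                sa, sb = self.sets[a], self.sets[b]
                for stem in _ALL_STEMS:
                    if sa.contains(stem) and sb.contains(stem):
                        raise ValidationError(
                            f"DKOLH component sets {a} and {b} overlap at {stem}"
                        )

    @classmethod
    def default(cls) -> "CauseSetConfig":
        sets = {name: CauseSet.from_spec(items) for name, items in _DEFAULT_SETS.items()}
        tracked = tuple(n for n in _DEFAULT_SETS if n not in ("cvd", "cardiac_arrest"))
        return cls(sets=sets, tracked=tracked)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CauseSetConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sets = {name: CauseSet.from_spec(items) for name, items in raw["sets"].items()}
        return cls(sets=sets, tracked=tuple(raw["tracked"]))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "sets": {name: cs.to_spec() for name, cs in self.sets.items()},
            "tracked": list(self.tracked),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class DeathClass:
    """Classification flags for one death."""

    cvd_ucod: bool
    cvd_mcod: bool
    dkolh: bool
    components: frozenset[str]


def classify(record: DeathRecord, config: CauseSetConfig, axis: str = "entity") -> DeathClass:
    """Classify a single record (reference implementation of the frame path)."""
    cvd, ca = config.sets["cvd"], config.sets["cardiac_arrest"]
    mentions = record.mention_codes(axis)
    cvd_ucod = cvd.contains(record.ucod)
    cvd_mcod = (
        ca.contains(record.ucod)
        or cvd_ucod
        or any(cvd.contains(c) and not ca.contains(c) for c in mentions)
    )
    components = frozenset(
        name for name in DKOLH_COMPONENTS if any(config.sets[name].contains(c) for c in mentions)
    )
    dkolh = cvd_mcod and bool(components)
    return DeathClass(cvd_ucod, cvd_mcod, dkolh, components if dkolh else frozenset(components))


def _exploded_mentions(frame: pd.DataFrame, axis: str) -> pd.DataFrame:
    """One row per (record, mentioned code), UCOD included; 'ridx' is the positional index."""
    if axis == "entity":
        raw = frame["entity_mentions"].fillna("").astype(str)
        lists = [
            [tok.rsplit(":", 1)[-1] for tok in s.split(";") if tok]
            for s in raw.to_numpy()
        ]
    elif axis == "record":
        if "record_axis" not in frame.columns:
            raise ValidationError("record-axis classification requested but column absent")
        raw = frame["record_axis"].fillna("").astype(str)
        if (raw.str.len() == 0).all():
            raise ValidationError("record-axis classification requested but no record-axis codes present")
        lists = [[c for c in s.split(";") if c] for s in raw.to_numpy()]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    ucods = frame["ucod"].astype(str).to_numpy()
    for codes, u in zip(lists, ucods):
        if u not in codes:
            codes.append(u)
    lengths = np.fromiter((len(c) for c in lists), dtype=int, count=len(lists))
    return pd.DataFrame(
        {
            "ridx": np.repeat(np.arange(len(frame)), lengths),
            "code": pd.Series([c for codes in lists for c in codes], dtype=str),
        }
    )


def classify_frame(frame: pd.DataFrame, config: CauseSetConfig, axis: str = "entity") -> pd.DataFrame:
    """Vectorized classification of a canonical record frame.

    Returns a frame aligned with the input carrying id/year/sex/age plus
    boolean flags ``cvd_ucod``, ``cvd_mcod``, ``dkolh``, one ``has_<name>``
    column per tracked cause (presence on the chosen axis, duplicates
    collapsed), and ``n_tracked`` (distinct tracked causes mentioned).
    """
    ex = _exploded_mentions(frame, axis)
    # duplicate mentions need no dedup: the any()/max aggregation below is
    # presence/absence semantics already
    cvd, ca = config.sets["cvd"], config.sets["cardiac_arrest"]
    ex["cvd_non_ca"] = cvd.match(ex["code"]) & ~ca.match(ex["code"])
    for name in config.tracked:
        ex[f"has_{name}"] = config.sets[name].match(ex["code"])
    flag_cols = ["cvd_non_ca"] + [f"has_{name}" for name in config.tracked]
    agg = ex.groupby("ridx")[flag_cols].any()
    agg = agg.reindex(np.arange(len(frame)), fill_value=False)

    out = frame[["id", "year", "sex", "age"]].copy().reset_index(drop=True)
    ucod = frame["ucod"].astype(str)
    out["cvd_ucod"] = cvd.match(ucod)
    out["cvd_mcod"] = ca.match(ucod) | out["cvd_ucod"].to_numpy() | agg["cvd_non_ca"].to_numpy()
    comp_cols = [f"has_{name}" for name in DKOLH_COMPONENTS]
    for name in config.tracked:
        out[f"has_{name}"] = agg[f"has_{name}"].to_numpy()
    out["dkolh"] = out["cvd_mcod"] & out[comp_cols].any(axis=1)
    out["n_tracked"] = out[[f"has_{name}" for name in config.tracked]].sum(axis=1)
    return out


def avg_causes_per_death(classified: pd.DataFrame) -> pd.Series:
    """Mean distinct tracked causes per CVD MCOD death, by year.

    The certificate-inflation diagnostic: a material rise over time would
    bias multiple-cause trends upward.  Years with no CVD MCOD deaths are
    absent from the output.
    """
    sub = classified[classified["cvd_mcod"]]
    if sub.empty:
        raise ValidationError("no CVD MCOD deaths in selection")
    return sub.groupby("year")["n_tracked"].mean()


def pct_with_cause(
    classified: pd.DataFrame,
    component: str,
    bands: Sequence[AgeBand],
) -> pd.Series:
    """% of DKOLH-CVD deaths mentioning ``component``, per age band.

    Bands with no DKOLH deaths yield NaN (undefined, not zero).
    """
    if component not in DKOLH_COMPONENTS:
        raise ValueError(f"{component!r} is not a DKOLH component")
    sub = classified[classified["dkolh"]]
    labels = [band_label(b) for b in bands]
    out = pd.Series(np.nan, index=labels, name=f"pct_{component}")
    for b, lab in zip(bands, labels):
        lo, hi = b
        mask = (sub["age"] >= lo) & ((sub["age"] < hi) if hi is not None else True)
        n = int(mask.sum())
        if n:
            out[lab] = 100.0 * sub.loc[mask, f"has_{component}"].sum() / n
    return out


def axis_delta(frame: pd.DataFrame, config: CauseSetConfig) -> pd.DataFrame:
    """Sensitivity harness: classify on both axes and report count deltas.

    Returns per-year counts of CVD MCOD and DKOLH deaths under each axis and
    their differences.  The harness only computes the deltas; judging their
    size is the analyst's task.
    """
    ent = classify_frame(frame, config, axis="entity")
    rec = classify_frame(frame, config, axis="record")

    def counts(c: pd.DataFrame, tag: str) -> pd.DataFrame:
        g = c.groupby("year").agg(**{
            f"cvd_mcod_{tag}": ("cvd_mcod", "sum"),
            f"dkolh_{tag}": ("dkolh", "sum"),
        })
        return g

    out = counts(ent, "entity").join(counts(rec, "record"), how="outer").fillna(0).astype(int)
    out["cvd_mcod_delta"] = out["cvd_mcod_record"] - out["cvd_mcod_entity"]
    out["dkolh_delta"] = out["dkolh_record"] - out["dkolh_entity"]
    return out.reset_index()
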