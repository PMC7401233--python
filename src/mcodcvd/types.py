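"""Shared domain types: death records, age bands, and demographic tables.

Ages are completed years (integers); age bands are half-open integer
intervals ``[lo, hi)`` with the terminal band open-ended (``hi is None``,
read "lo+").  The canonical banding is 5-year groups 0-4 ... 90-94, 95+.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

AgeBand = tuple[int, Optional[int]]

#: Width assumed for the open-ended terminal band when a midpoint or an
#: explicit age list is needed (95+ is treated as ages 95-99).
OPEN_BAND_WIDTH = 5


class ValidationError(ValueError):
    """Raised when a table or record violates a structural invariant."""


def five_year_bands(lo: int = 0, hi: int = 95, open_end: bool = True) -> tuple[AgeBand, ...]:
    """5-year age bands from ``lo`` up to ``hi``; terminal open band ``hi+`` if requested.

    ``five_year_bands(0, 95)`` -> 0-4 ... 90-94, 95+;
    ``five_year_bands(35, 75, open_end=False)`` -> 35-39 ... 70-74.
    """
    bands: list[AgeBand] = [(a, a + 5) for a in range(lo, hi, 5)]
    if open_end:
        bands.append((hi, None))
    return tuple(bands)


def band_label(band: AgeBand) -> str:
    lo, hi = band
    return f"{lo}+" if hi is None else f"{lo}-{hi - 1}"


def parse_band_label(label: str) -> AgeBand:
    label = label.strip()
    if label.endswith("+"):
        return (int(label[:-1]), None)
    lo, hi = label.split("-")
    return (int(lo), int(hi) + 1)


def band_midpoint(band: AgeBand) -> float:
    """Midpoint in completed years: [35,40) -> 37.0; open band lo+ -> lo+2."""
    lo, hi = band
    if hi is None:
        hi = lo + OPEN_BAND_WIDTH
    return (lo + hi - 1) / 2.0


def band_ages(band: AgeBand) -> range:
    lo, hi = band
    return range(lo, (lo + OPEN_BAND_WIDTH) if hi is None else hi)


def band_for_age(age: int, bands: Sequence[AgeBand]) -> Optional[AgeBand]:
    for lo, hi in bands:
        if age >= lo and (hi is None or age < hi):
            return (lo, hi)
    return None


def validate_bands(bands: Sequence[AgeBand]) -> None:
    """Bands must be ordered, contiguous and non-overlapping."""
    if not bands:
        raise ValidationError("age band list is empty")
    for i, (lo, hi) in enumerate(bands):
        if hi is None:
            if i != len(bands) - 1:
                raise ValidationError("open-ended band must be terminal")
            continue
        if hi <= lo:
            raise ValidationError(f"band [{lo},{hi}) is empty or reversed")
        if i + 1 < len(bands) and bands[i + 1][0] != hi:
            raise ValidationError(
                f"bands not contiguous at {band_label((lo, hi))} -> {band_label(bands[i + 1])}"
            )


def widen_bands(bands: Sequence[AgeBand], factor: int = 2) -> tuple[AgeBand, ...]:
    """Merge consecutive bands in groups of ``factor`` (5-year -> 10-year).

    A trailing remainder group (including the open band) is merged into one
    terminal band, so 85-89, 90-94, 95+ under factor 2 ends ... 85-94, 95+
    unless the count works out evenly.
    """
    validate_bands(bands)
    out: list[AgeBand] = []
    i = 0
    while i < len(bands):
        chunk = list(bands[i:i + factor])
        out.append((chunk[0][0], chunk[-1][1]))
        i += factor
    return tuple(out)


@dataclass(frozen=True)
class Mention:
    """One entity-axis cause mention: certificate part, line, position, ICD-10 code."""

    part: int
    line: int
    position: int
    code: str


@dataclass(frozen=True)
class DeathRecord:
    """One registered death with its underlying cause and all cause mentions.

    ``entity_mentions`` are the causes as written on the certificate (part 1
    chain plus part 2 contributory conditions); ``record_axis`` optionally
    carries the post-coding-rules cause list.  The underlying cause is always
    present among the entity mentions.
    """

    id: str
    year: int
    sex: str
    age: int
    ucod: str
    entity_mentions: tuple[Mention, ...]
    record_axis: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"record {self.id}: negative age {self.age}")
        if not self.entity_mentions:
            raise ValidationError(f"record {self.id}: no entity mentions")

    def mention_codes(self, axis: str = "entity") -> tuple[str, ...]:
        """Distinct mentioned codes on the requested axis, always including the UCOD."""
        if axis == "entity":
            codes = [m.code for m in self.entity_mentions]
        elif axis == "record":
            if self.record_axis is None:
                raise ValidationError(f"record {self.id}: record-axis data absent")
            codes = list(self.record_axis)
        else:
            raise ValueError(f"unknown axis {axis!r}")
        if self.ucod not in codes:
            codes.append(self.ucod)
        seen: dict[str, None] = {}
        for c in codes:
            seen.setdefault(c, None)
        return tuple(seen)


RECORD_COLUMNS = ["id", "year", "sex", "age", "ucod", "entity_mentions", "record_axis"]


def mentions_to_str(mentions: Iterable[Mention]) -> str:
    return ";".join(f"{m.part}:{m.line}:{m.position}:{m.code}" for m in mentions)


def mentions_from_str(s: str) -> tuple[Mention, ...]:
    if not s:
        return ()
    out = []
    for tok in s.split(";"):
        part, line, pos, code = tok.split(":")
        out.append(Mention(int(part), int(line), int(pos), code))
    return tuple(out)


def records_to_frame(records: Iterable[DeathRecord]) -> pd.DataFrame:
    """Flatten records into the canonical analysis frame (mentions serialized)."""
    rows = [
        (
            r.id,
            r.year,
            r.sex,
            r.age,
            r.ucod,
            mentions_to_str(r.entity_mentions),
            ";".join(r.record_axis) if r.record_axis is not None else "",
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[DeathRecord]:
    out = []
    for row in frame.itertuples(index=False):
        ra = getattr(row, "record_axis", "") or ""
        out.append(
            DeathRecord(
                id=str(row.id),
                year=int(row.year),
                sex=str(row.sex),
                age=int(row.age),
                ucod=str(row.ucod),
                entity_mentions=mentions_from_str(str(row.entity_mentions or "")),
                record_axis=tuple(ra.split(";")) if ra else None,
            )
        )
    return out


@dataclass
class PopulationTable:
    """Person-years by (year, sex, age band).

    ``frame`` columns: year, sex, age_lo, age_hi (NaN/None for the open
    band), count.  Counts must be strictly positive; bands contiguous.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = {"year", "sex", "age_lo", "age_hi", "count"} - set(f.columns)
        if missing:
            raise ValidationError(f"population table missing columns {sorted(missing)}")
        if (f["count"] <= 0).any():
            raise ValidationError("population counts must be > 0")
        validate_bands(self.age_groups)

    @property
    def age_groups(self) -> tuple[AgeBand, ...]:
        sub = self.frame[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
        return tuple(
            (int(lo), None if pd.isna(hi) else int(hi))
            for lo, hi in zip(sub["age_lo"], sub["age_hi"])
        )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["sex"].unique()))

    def regrouped(self, factor: int) -> "PopulationTable":
        """Sum adjacent bands (e.g. factor 2: 5-year -> 10-year groups)."""
        if factor == 1:
            return self
        old = self.age_groups
        new = widen_bands(old, factor)
        lo_map = {}
        for nb in new:
            for ob in old:
                if ob[0] >= nb[0] and (nb[1] is None or (ob[1] is not None and ob[1] <= nb[1])):
                    lo_map[ob[0]] = nb
        f = self.frame.copy()
        f["age_lo"], f["age_hi"] = zip(*[lo_map[int(lo)] for lo in f["age_lo"]])
        g = (
            f.groupby(["year", "sex", "age_lo"], as_index=False)
            .agg(age_hi=("age_hi", "first"), count=("count", "sum"))
        )
        return PopulationTable(g[["year", "sex", "age_lo", "age_hi", "count"]])


@dataclass
class StandardPopulation:
    """Fixed standard age weights used for direct standardization.

    ``frame`` columns: age_lo, age_hi, weight.  Weights are proportions and
    must sum to 1 (within 1e-9) over the full band list; they are
    renormalized on the fly when an age window restricts the band set.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = {"age_lo", "age_hi", "weight"} - set(f.columns)
        if missing:
            raise ValidationError(f"standard population missing columns {sorted(missing)}")
        if (f["weight"] < 0).any():
            raise ValidationError("standard weights must be >= 0")
        total = float(f["weight"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"standard weights sum to {total!r}, expected 1")
        validate_bands(self.age_groups)

    @property
    def age_groups(self) -> tuple[AgeBand, ...]:
        sub = self.frame[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
        return tuple(
            (int(lo), None if pd.isna(hi) else int(hi))
            for lo, hi in zip(sub["age_lo"], sub["age_hi"])
        )

    def weights_for(self, bands: Sequence[AgeBand]) -> pd.Series:
        """Renormalized weights for exactly the requested bands (by age_lo)."""
        own = {b[0]: w for b, w in zip(self.age_groups, self.frame.sort_values("age_lo")["weight"])}
        try:
            w = np.array([own[b[0]] for b in bands], dtype=float)
        except KeyError as e:
            raise ValidationError(f"standard population has no band starting at {e.args[0]}") from e
        total = w.sum()
        if total <= 0:
            raise ValidationError("standard weights sum to zero over requested bands")
        return pd.Series(w / total, index=[b[0] for b in bands])

    @classmethod
    def from_counts(cls, bands: Sequence[AgeBand], counts: Sequence[float]) -> "StandardPopulation":
        w = np.asarray(counts, dtype=float)
        w = w / w.sum()
        return cls(
            pd.DataFrame(
                {
                    "age_lo": [b[0] for b in bands],
                    "age_hi": [b[1] for b in bands],
                    "weight": w,
                }
            )
        )


@dataclass
class PrevalenceSurface:
    """Prevalence proportions by (year, sex, age band).

    ``frame`` columns: year, sex, age_lo, age_hi, prevalence in [0, 1].
    Emulates a grouped risk-factor prevalence product such as the 1980-2015
    obesity prevalence surface.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = {"year", "sex", "age_lo", "age_hi", "prevalence"} - set(f.columns)
        if missing:
            raise ValidationError(f"prevalence surface missing columns {sorted(missing)}")
        p = f["prevalence"]
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("prevalence values must lie in [0, 1]")
        validate_bands(self.age_groups)

    @property
    def age_groups(self) -> tuple[AgeBand, ...]:
        sub = self.frame[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
        return tuple(
            (int(lo), None if pd.isna(hi) else int(hi))
            for lo, hi in zip(sub["age_lo"], sub["age_hi"])
        )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["sex"].unique()))
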