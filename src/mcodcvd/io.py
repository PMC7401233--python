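"""Readers and writers for the delimited vital-statistics formats.

All files are UTF-8 CSV (RFC-4180 quoting via pandas) with a mandatory
header row:

* unit records:  ``id,year,sex,age,ucod,entity_mentions,record_axis`` where
  ``entity_mentions`` is a semicolon-joined list of ``part:line:position:code``
  tokens and ``record_axis`` a semicolon-joined code list (may be empty);
* population:    ``year,sex,age_lo,age_hi,count`` (empty ``age_hi`` = open band);
* weights:       ``age_lo,age_hi,weight``;
* prevalence:    ``year,sex,age_lo,age_hi,prevalence``.

Vendor fixed-width layouts (e.g. national public-use mortality files) are
supported through a user-supplied column-position map in
:class:`RecordLayout`; no year-specific layout is hardcoded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .types import (
    DeathRecord,
    Mention,
    PopulationTable,
    PrevalenceSurface,
    StandardPopulation,
    ValidationError,
    mentions_to_str,
    records_to_frame,
)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")


class ICDError(ValidationError):
    """Raised for a malformed ICD-10 code; the message names the offending value."""


def normalize_icd10(code: str) -> str:
    """Canonical ICD-10 shape: uppercase, dot stripped, letter + 2 digits (+ extensions).

    >>> normalize_icd10("I25.1")
    'I251'
    >>> normalize_icd10("e66")
    'E66'
    """
    if code is None:
        raise ICDError("ICD-10 code is missing")
    cleaned = str(code).strip().upper()
    if cleaned.count(".") > 1:
        raise ICDError(f"malformed ICD-10 code: {code!r}")
    cleaned = cleaned.replace(".", "")
    if not _ICD10_RE.match(cleaned):
        raise ICDError(f"malformed ICD-10 code: {code!r}")
    return cleaned


@dataclass(frozen=True)
class RowError:
    """One rejected input row: 0-based row number and the reason."""

    row: int
    message: str


@dataclass
class ReadResult:
    """Records parsed from a unit-record file plus the per-row error report.

    The reader never silently drops rows: ``len(records) + len(errors)``
    equals the number of data rows in the file.
    """

    records: list[DeathRecord]
    errors: list[RowError]

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


_DEFAULT_COLUMNS = {
    "id": "id",
    "year": "year",
    "sex": "sex",
    "age": "age",
    "ucod": "ucod",
    "entity_mentions": "entity_mentions",
    "record_axis": "record_axis",
}


@dataclass
class RecordLayout:
    """Maps the logical unit-record fields onto a concrete file layout.

    ``columns`` maps field name -> source column name (CSV).  For
    fixed-width vendor files supply ``colspecs`` as field name ->
    ``(start, stop)`` character positions (0-based, stop-exclusive); the
    file is then read with :func:`pandas.read_fwf`.  ``record_axis`` and
    ``id`` are optional fields: an absent ``id`` column autonumbers rows.
    """

    columns: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    colspecs: Optional[Mapping[str, tuple[int, int]]] = None


def _parse_mentions(raw: str) -> tuple[Mention, ...]:
    out = []
    for tok in raw.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        parts = tok.split(":")
        if len(parts) != 4:
            raise ValidationError(f"mention token {tok!r} is not part:line:position:code")
        part, line, pos, code = parts
        out.append(Mention(int(part), int(line), int(pos), normalize_icd10(code)))
    return tuple(out)


def _row_to_record(row: Mapping[str, object], row_id: str) -> DeathRecord:
    ucod = normalize_icd10(str(row["ucod"]))
    raw_mentions = str(row.get("entity_mentions") or "")
    mentions = list(_parse_mentions(raw_mentions))
    if ucod not in [m.code for m in mentions]:
        # UCOD is always a mention; place it on the bottom line of part 1.
        mentions.append(Mention(1, max([m.line for m in mentions if m.part == 1], default=0) + 1, 1, ucod))
    raw_axis = str(row.get("record_axis") or "").strip()
    record_axis = (
        tuple(normalize_icd10(c) for c in raw_axis.split(";") if c.strip()) if raw_axis else None
    )
    return DeathRecord(
        id=row_id,
        year=int(row["year"]),
        sex=str(row["sex"]).strip(),
        age=int(row["age"]),
        ucod=ucod,
        entity_mentions=tuple(mentions),
        record_axis=record_axis,
    )


def read_unit_records(
    path: str | Path,
    layout: Optional[RecordLayout] = None,
    max_error_rate: float = 0.01,
) -> ReadResult:
    """Read a unit-record death file, collecting row-level errors.

    Raises :class:`ValidationError` if a required column is missing or if
    the fraction of malformed rows exceeds ``max_error_rate``.
    """
    layout = layout or RecordLayout()
    path = Path(path)
    try:
        if layout.colspecs is not None:
            specs = list(layout.colspecs.items())
            raw = pd.read_fwf(
                path, colspecs=[s for _, s in specs], names=[n for n, _ in specs],
                dtype=str, keep_default_na=False,
            )
        else:
            raw = pd.read_csv(path, dtype=str, keep_default_na=False)
            rename = {src: dst for dst, src in layout.columns.items() if src in raw.columns}
            raw = raw.rename(columns=rename)
    except OSError as e:
        raise ValidationError(f"cannot read unit records from {path}: {e}") from e

    required = {"year", "sex", "age", "ucod", "entity_mentions"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"{path}: layout is missing required columns {sorted(missing)}")

    records: list[DeathRecord] = []
    errors: list[RowError] = []
    has_id = "id" in raw.columns
    for i, row in enumerate(raw.to_dict("records")):
        rid = str(row["id"]) if has_id and str(row.get("id", "")).strip() else f"row{i}"
        try:
            records.append(_row_to_record(row, rid))
        except (ValidationError, ValueError) as e:
            errors.append(RowError(i, str(e)))
    n = len(raw)
    if n and len(errors) / n > max_error_rate:
        raise ValidationError(
            f"{path}: {len(errors)}/{n} malformed rows exceeds the "
            f"{max_error_rate:.1%} tolerance; first error: {errors[0].message}"
        )
    return ReadResult(records, errors)


def write_unit_records(records, path: str | Path) -> None:
    """Write records (a sequence of DeathRecord or a canonical frame) as CSV."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def _band_cols_out(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    out["age_hi"] = out["age_hi"].astype("Int64")
    return out


def read_population(path: str | Path) -> PopulationTable:
    f = pd.read_csv(path)
    f["age_hi"] = pd.to_numeric(f["age_hi"], errors="coerce")
    return PopulationTable(f[["year", "sex", "age_lo", "age_hi", "count"]])


def write_population(pop: PopulationTable, path: str | Path) -> None:
    _band_cols_out(pop.frame).to_csv(path, index=False)


def read_weights(path: str | Path) -> StandardPopulation:
    f = pd.read_csv(path)
    f["age_hi"] = pd.to_numeric(f["age_hi"], errors="coerce")
    return StandardPopulation(f[["age_lo", "age_hi", "weight"]])


def write_weights(std: StandardPopulation, path: str | Path) -> None:
    _band_cols_out(std.frame).to_csv(path, index=False)


def read_prevalence(path: str | Path) -> PrevalenceSurface:
    f = pd.read_csv(path)
    f["age_hi"] = pd.to_numeric(f["age_hi"], errors="coerce")
    return PrevalenceSurface(f[["year", "sex", "age_lo", "age_hi", "prevalence"]])


def write_prevalence(surface: PrevalenceSurface, path: str | Path) -> None:
    _band_cols_out(surface.frame).to_csv(path, index=False)
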