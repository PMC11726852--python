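"""Readers and writers for event, index-surgery, and gold-label tables.

Files are delimited text (comma by default) with a header row, dates in
ISO-8601 at day resolution, UTF-8 encoded.  Registry extracts rarely share
column names, so a :class:`Dialect` can remap columns, change the delimiter
and translate local laterality vocabulary onto left/right/unspecified.
Malformed rows are never silently dropped: every reader returns the
accepted frame together with a line-numbered rejection report, and accepted
plus rejected always equals the input row count.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .causes import CauseLabel
from .codes import Code, Laterality, infer_kind, region_of

logger = logging.getLogger("reopcause")

EVENT_COLUMNS = ("patient_id", "date", "code", "laterality", "contact_id")
SURGERY_COLUMNS = ("fracture_id", "patient_id", "surgery_date", "procedure", "region", "laterality")
GOLD_COLUMNS = ("fracture_id", "true_cause", "source")

#: Common registry spellings accepted out of the box.
_LATERALITY_ALIASES = {
    "left": "left", "l": "left", "sin": "left", "sinister": "left",
    "right": "right", "r": "right", "dx": "right", "dexter": "right",
    "unspecified": "unspecified", "": "unspecified", "na": "unspecified",
    "none": "unspecified", "missing": "unspecified", "bilateral": "unspecified",
}


@dataclass(frozen=True)
class Dialect:
    """How a particular registry extract spells its tables."""

    delimiter: str = ","
    column_map: dict[str, str] = field(default_factory=dict)  # file column -> canonical
    laterality_map: dict[str, str] = field(default_factory=dict)  # file value -> canonical
    encoding: str = "utf-8"

    def to_canonical_laterality(self, value) -> str | None:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return "unspecified"
        key = str(value).strip().lower()
        if key in self.laterality_map:
            key = self.laterality_map[key].strip().lower()
        return _LATERALITY_ALIASES.get(key)


@dataclass(frozen=True)
class CodedEvent:
    """One dated, sided, coded hospital-contact row."""

    patient_id: str
    date: pd.Timestamp
    code: Code
    laterality: Laterality
    contact_id: str


@dataclass(frozen=True)
class IndexSurgery:
    """The primary fracture osteosynthesis anchoring 365-day follow-up."""

    fracture_id: str
    patient_id: str
    surgery_date: pd.Timestamp
    procedure: Code
    region: str
    laterality: Laterality


@dataclass(frozen=True)
class GoldLabel:
    fracture_id: str
    true_cause: CauseLabel
    source: str = "chart_review"


@dataclass
class IngestResult:
    """Accepted rows plus a line-numbered account of the rejected ones."""

    frame: pd.DataFrame
    rejections: list[tuple[int, str]]
    n_input: int

    @property
    def n_accepted(self) -> int:
        return len(self.frame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


class InputError(ValueError):
    """The input file cannot be used at all (e.g., missing columns)."""


def _read_raw(path: str | Path, dialect: Dialect, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=False,
        encoding=dialect.encoding,
    )
    if dialect.column_map:
        frame = frame.rename(columns=dialect.column_map)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    return frame


def _finish(frame: pd.DataFrame, keep: pd.Series, reasons: dict[int, str], path) -> IngestResult:
    rejections = sorted(reasons.items())
    for line, reason in rejections:
        logger.warning("%s line %d rejected: %s", path, line, reason)
    result = IngestResult(frame.loc[keep].reset_index(drop=True), rejections, len(keep))
    assert result.n_accepted + result.n_rejected == result.n_input
    return result


def _reject(reasons: dict[int, str], idx, header_offset: int, reason: str) -> None:
    for i in idx:
        reasons.setdefault(int(i) + header_offset, reason)


def read_events(path: str | Path, dialect: Dialect | None = None) -> IngestResult:
    """Read a coded-event table; returns accepted events + rejection report.

    Accepted frame columns: patient_id, date (datetime64), code (uppercase),
    kind ('procedure'/'diagnosis'), laterality, contact_id.
    """
    dialect = dialect or Dialect()
    frame = _read_raw(path, dialect, ("patient_id", "date", "code", "contact_id"))
    reasons: dict[int, str] = {}
    off = 2  # 1-based line numbers, after the header

    frame["code"] = frame["code"].str.strip().str.upper()
    frame["patient_id"] = frame["patient_id"].str.strip()
    dates = pd.to_datetime(frame["date"], format="ISO8601", errors="coerce")
    _reject(reasons, frame.index[dates.isna()], off, "unparseable date")
    _reject(reasons, frame.index[frame["code"] == ""], off, "empty code")
    _reject(reasons, frame.index[frame["patient_id"] == ""], off, "empty patient_id")
    badkind = frame["code"].ne("") & ~frame["code"].str.startswith(("K", "D"))
    _reject(reasons, frame.index[badkind], off, "code is neither procedure (K...) nor diagnosis (D...)")
    if "laterality" in frame.columns:
        lat = frame["laterality"].map(dialect.to_canonical_laterality)
        _reject(reasons, frame.index[lat.isna()], off, "unknown laterality value")
    else:
        lat = pd.Series("unspecified", index=frame.index)

    out = pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "date": dates,
            "code": frame["code"],
            "laterality": lat,
            "contact_id": frame["contact_id"].str.strip(),
        }
    )
    keep = ~out.index.isin([line - off for line, _ in reasons.items()])
    keep = pd.Series(keep, index=out.index)
    result = _finish(out, keep, reasons, path)
    result.frame["kind"] = [infer_kind(c).value for c in result.frame["code"]]
    return result


def read_index_surgeries(path: str | Path, dialect: Dialect | None = None) -> IngestResult:
    """Read the index-surgery table, checking procedure/region consistency."""
    dialect = dialect or Dialect()
    frame = _read_raw(path, dialect, ("fracture_id", "patient_id", "surgery_date", "procedure", "region"))
    reasons: dict[int, str] = {}
    off = 2

    frame["procedure"] = frame["procedure"].str.strip().str.upper()
    frame["region"] = frame["region"].str.strip().str.upper()
    dates = pd.to_datetime(frame["surgery_date"], format="ISO8601", errors="coerce")
    _reject(reasons, frame.index[dates.isna()], off, "unparseable surgery_date")
    _reject(reasons, frame.index[frame["procedure"] == ""], off, "empty procedure code")
    _reject(reasons, frame.index[~frame["procedure"].str.startswith("K")], off, "procedure must be a K... code")

    code_region = frame["procedure"].map(
        lambda c: region_of(c) if c.startswith("K") and len(c) >= 3 else None
    )
    inconsistent = code_region.notna() & (code_region != frame["region"])
    _reject(reasons, frame.index[inconsistent], off, "procedure code region differs from region column")
    dup = frame["fracture_id"].duplicated(keep="first")
    _reject(reasons, frame.index[dup], off, "duplicate fracture_id")

    if "laterality" in frame.columns:
        lat = frame["laterality"].map(dialect.to_canonical_laterality)
        _reject(reasons, frame.index[lat.isna()], off, "unknown laterality value")
    else:
        lat = pd.Series("unspecified", index=frame.index)

    out = pd.DataFrame(
        {
            "fracture_id": frame["fracture_id"].str.strip(),
            "patient_id": frame["patient_id"].str.strip(),
            "surgery_date": dates,
            "procedure": frame["procedure"],
            "region": frame["region"],
            "laterality": lat,
        }
    )
    keep = pd.Series(~out.index.isin([line - off for line in reasons]), index=out.index)
    return _finish(out, keep, reasons, path)


def read_gold_labels(path: str | Path, dialect: Dialect | None = None) -> IngestResult:
    dialect = dialect or Dialect()
    frame = _read_raw(path, dialect, ("fracture_id", "true_cause"))
    reasons: dict[int, str] = {}
    off = 2
    valid = {c.value for c in CauseLabel}
    cause = frame["true_cause"].str.strip().str.lower()
    _reject(reasons, frame.index[~cause.isin(valid)], off, "unknown cause label")
    dup = frame["fracture_id"].duplicated(keep="first")
    _reject(reasons, frame.index[dup], off, "duplicate fracture_id")
    out = pd.DataFrame(
        {
            "fracture_id": frame["fracture_id"].str.strip(),
            "true_cause": cause,
            "source": frame.get("source", pd.Series("chart_review", index=frame.index)),
        }
    )
    keep = pd.Series(~out.index.isin([line - off for line in reasons]), index=out.index)
    return _finish(out, keep, reasons, path)


def _write(frame: pd.DataFrame, path: str | Path, date_cols: tuple[str, ...], dialect: Dialect | None) -> None:
    dialect = dialect or Dialect()
    out = frame.copy()
    for col in date_cols:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=dialect.delimiter, index=False, encoding=dialect.encoding)


def write_events(frame: pd.DataFrame, path: str | Path, dialect: Dialect | None = None) -> None:
    cols = [c for c in EVENT_COLUMNS if c in frame.columns]
    _write(frame[cols], path, ("date",), dialect)


def write_index_surgeries(frame: pd.DataFrame, path: str | Path, dialect: Dialect | None = None) -> None:
    cols = [c for c in SURGERY_COLUMNS if c in frame.columns]
    _write(frame[cols], path, ("surgery_date",), dialect)


def write_gold_labels(frame: pd.DataFrame, path: str | Path, dialect: Dialect | None = None) -> None:
    cols = [c for c in GOLD_COLUMNS if c in frame.columns]
    _write(frame[cols], path, (), dialect)


def append_provenance(log_path: str | Path, record: dict) -> None:
    """Append one JSON-lines provenance record (config hash, seed, versions)."""
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
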