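"""Record I/O and analytic-sample construction.

Records are exchanged as JSONL (one JSON object per line) or CSV
(RFC 4180, UTF-8, header row).  Malformed rows are collected into an error
report rather than silently dropped; a file in which more than 10% of rows
fail to parse is rejected outright, since that usually indicates the wrong
dialect rather than scattered corruption.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "NarrativeRecord",
    "AnalyticSample",
    "ReadReport",
    "CorpusFormatError",
    "read_records",
    "write_records",
    "build_analytic_sample",
    "records_to_frame",
    "recode",
    "MIN_AGE",
    "ELIGIBLE_MANNERS",
]

MIN_AGE = 55
ELIGIBLE_MANNERS = frozenset({"suicide", "undetermined", "accidental_firearm"})

_SCALAR_FIELDS = (
    "id", "state", "year", "age", "sex", "race_eth", "marital", "manner",
    "means", "injury_location_code", "death_location_code", "narrative",
)
_INT_FIELDS = {"year", "age"}


class CorpusFormatError(ValueError):
    """Raised when a file is unreadable or mostly malformed."""


@dataclass
class NarrativeRecord:
    """One decedent record: structured fields plus the free-text narrative."""

    id: str
    state: str = ""
    year: int = 0
    age: int = 0
    sex: str = ""
    race_eth: str = ""
    marital: str = ""
    manner: str = ""
    means: str = ""
    injury_location_code: str = ""
    death_location_code: str = ""
    flags: Dict[str, bool] = field(default_factory=dict)
    narrative: str = ""
    race_dichotomy: Optional[str] = None
    extras: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {f: getattr(self, f) for f in _SCALAR_FIELDS}
        d["flags"] = dict(self.flags)
        if self.race_dichotomy is not None:
            d["race_dichotomy"] = self.race_dichotomy
        d.update(self.extras)
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "NarrativeRecord":
        if "id" not in d or d["id"] in (None, ""):
            raise CorpusFormatError("record missing id")
        known = set(_SCALAR_FIELDS) | {"flags", "race_dichotomy"}
        kwargs: Dict[str, object] = {}
        for f in _SCALAR_FIELDS:
            if f in d and d[f] is not None:
                kwargs[f] = int(d[f]) if f in _INT_FIELDS else str(d[f])
        flags = d.get("flags", {})
        if isinstance(flags, str):
            flags = json.loads(flags) if flags else {}
        if not isinstance(flags, dict):
            raise CorpusFormatError("flags must be a mapping")
        kwargs["flags"] = {k: bool(v) for k, v in flags.items()}
        if d.get("race_dichotomy") is not None:
            kwargs["race_dichotomy"] = str(d["race_dichotomy"])
        kwargs["extras"] = {k: v for k, v in d.items() if k not in known}
        rec = cls(**kwargs)  # type: ignore[arg-type]
        if rec.age < 0:
            raise CorpusFormatError(f"record {rec.id}: negative age")
        return rec


@dataclass
class ReadReport:
    """Parsed records plus a log of malformed rows (line number, message)."""

    records: List[NarrativeRecord]
    errors: List[Tuple[int, str]]


@dataclass
class AnalyticSample:
    """Records passing the analytic filters, with a per-reason exclusion log."""

    records: List[NarrativeRecord]
    exclusion_log: Dict[str, int]

    def __len__(self) -> int:
        return len(self.records)

    def narratives(self) -> Dict[str, str]:
        return {r.id: r.narrative for r in self.records}

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]


def read_records(path: str | Path, format: str = "jsonl") -> ReadReport:
    """Read records from ``path`` in the given format (``jsonl`` or ``csv``).

    Unknown fields are preserved in each record's ``extras`` map.  Raises
    :class:`CorpusFormatError` if the file cannot be read or if more than 10%
    of nonempty rows are malformed.
    """
    path = Path(path)
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CorpusFormatError(f"cannot read {path}: {exc}") from exc

    records: List[NarrativeRecord] = []
    errors: List[Tuple[int, str]] = []
    total = 0
    if format == "jsonl":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            total += 1
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise CorpusFormatError("line is not a JSON object")
                records.append(NarrativeRecord.from_dict(obj))
            except (json.JSONDecodeError, CorpusFormatError, ValueError) as exc:
                errors.append((lineno, str(exc)))
    else:
        reader = csv.DictReader(text.splitlines())
        for lineno, row in enumerate(reader, start=2):
            total += 1
            try:
                clean = {k: v for k, v in row.items() if k is not None and v != ""}
                records.append(NarrativeRecord.from_dict(clean))
            except (CorpusFormatError, ValueError) as exc:
                errors.append((lineno, str(exc)))

    if total and len(errors) / total > 0.10:
        raise CorpusFormatError(
            f"{len(errors)}/{total} rows malformed in {path}; wrong dialect?"
        )
    return ReadReport(records=records, errors=errors)


def write_records(
    records: Sequence[NarrativeRecord], path: str | Path, format: str = "jsonl"
) -> None:
    """Write records to ``path`` as JSONL or CSV (flags serialized as JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec.to_dict(), ensure_ascii=False) + "\n")
    elif format == "csv":
        extra_keys = sorted({k for r in records for k in r.extras})
        cols = list(_SCALAR_FIELDS) + ["flags", "race_dichotomy"] + extra_keys
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for rec in records:
                row = {f: getattr(rec, f) for f in _SCALAR_FIELDS}
                row["flags"] = json.dumps(rec.flags, sort_keys=True)
                row["race_dichotomy"] = rec.race_dichotomy or ""
                row.update(rec.extras)
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}")


def build_analytic_sample(records: Iterable[NarrativeRecord]) -> AnalyticSample:
    """Apply the analytic filters in fixed order: age, manner, narrative.

    Each excluded record is counted once, at the first filter it fails, so
    the log is deterministic and retained + excluded counts conserve the
    input count.
    """
    kept: List[NarrativeRecord] = []
    log = {"age": 0, "manner": 0, "narrative": 0}
    for rec in records:
        if rec.age < MIN_AGE:
            log["age"] += 1
        elif rec.manner not in ELIGIBLE_MANNERS:
            log["manner"] += 1
        elif not rec.narrative.strip():
            log["narrative"] += 1
        else:
            kept.append(rec)
    return AnalyticSample(records=kept, exclusion_log=log)


def records_to_frame(
    records: Sequence[NarrativeRecord],
    categories: Optional[Dict[str, str]] = None,
) -> "pd.DataFrame":
    """Tabularize records (flags expanded to columns) for analysis modules.

    ``categories`` optionally maps record id to a category value string,
    added as a ``category`` column.
    """
    import pandas as pd

    rows = []
    for rec in records:
        row: Dict[str, object] = {
            f: getattr(rec, f) for f in _SCALAR_FIELDS if f != "narrative"
        }
        row["race_dichotomy"] = rec.race_dichotomy
        row.update({k: bool(v) for k, v in rec.flags.items()})
        if categories is not None:
            row["category"] = categories.get(rec.id)
        rows.append(row)
    return pd.DataFrame(rows)


def recode(record: NarrativeRecord) -> NarrativeRecord:
    """Add the race dichotomy (non-Hispanic white vs other) in place.

    Missing or blank race strings recode to "other" with a logged warning.
    The original category string is left untouched.
    """
    raw = (record.race_eth or "").strip().lower()
    if not raw:
        logger.warning("record %s: missing race/ethnicity; recoded to 'other'", record.id)
        record.race_dichotomy = "other"
    elif raw == "non-hispanic white":
        record.race_dichotomy = "non-Hispanic white"
    else:
        record.race_dichotomy = "other"
    return record
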