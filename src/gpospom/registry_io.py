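"""Case-level registry I/O in a CSV dialect emulating a §21 KHEntgG extract.

German hospitals report one row per hospital case (stay) for billing: age,
sex, all coded ICD-10 diagnoses, all OPS procedures with dates, admission /
discharge dates and the coded discharge disposition.  The unit of analysis
throughout this package is the CASE, never the patient; an anonymized
patient tag may ride along as an opaque pass-through column but is not used.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .score_table import normalize_code

#: §21 KHEntgG discharge-reason prefix for in-hospital death.
DEFAULT_DEATH_CODES = frozenset({"07"})

REGISTRY_COLUMNS = [
    "case_id", "age", "sex", "icd_codes", "ops_codes", "ops_dates",
    "admission_date", "discharge_date", "discharge_reason",
]

SCORED_COLUMNS = [
    "case_id", "age", "sex", "score", "age_points", "comorbidity_points",
    "surgery_points", "surgery_group", "predicted_risk", "died",
]


class RegistryFormatError(ValueError):
    """Schema or integrity problem in a registry file."""


@dataclass(frozen=True)
class RegistryDialect:
    """CSV conventions for registry files.

    UTF-8, comma field separator, ISO-8601 dates; multi-valued code fields
    joined with ``list_separator`` (default ``"|"``).
    """

    list_separator: str = "|"
    encoding: str = "utf-8"


@dataclass
class CaseRecord:
    """One hospital case as extracted from the billing database."""

    case_id: str
    age: int | None
    sex: str  # "female" | "male" | "other"
    icd_codes: list[str] = field(default_factory=list)
    procedures: list[tuple[str, dt.date | None]] = field(default_factory=list)
    discharge_reason: str | None = None
    admission_date: dt.date | None = None
    discharge_date: dt.date | None = None


@dataclass(frozen=True)
class Outcome:
    died_in_hospital: bool


def derive_outcome(case: CaseRecord, death_codes: frozenset[str] | set[str] = DEFAULT_DEATH_CODES) -> Outcome:
    """In-hospital death iff the discharge reason is in the configured set.

    A missing discharge reason yields ``died_in_hospital=False``; such cases
    carry an incompleteness that the eligibility filter catches separately.
    """
    if case.discharge_reason is None:
        return Outcome(died_in_hospital=False)
    return Outcome(died_in_hospital=case.discharge_reason in death_codes)


def _parse_date(s: str) -> dt.date | None:
    return dt.date.fromisoformat(s) if s else None


def _split_list(raw: str, sep: str) -> list[str]:
    return [t for t in (tok.strip() for tok in raw.split(sep)) if t] if raw else []


def read_cases(path: str | Path, dialect: RegistryDialect = RegistryDialect()) -> list[CaseRecord]:
    """Read a registry CSV into :class:`CaseRecord` objects, in file order.

    Codes are normalized on ingest.  Missing mandatory columns raise a schema
    error; duplicate case ids raise an integrity error listing the offenders.
    """
    path = Path(path)
    records: list[CaseRecord] = []
    with path.open(newline="", encoding=dialect.encoding) as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REGISTRY_COLUMNS if c not in header]
        if missing:
            raise RegistryFormatError(f"registry {path.name} missing mandatory columns: {missing}")
        for row in reader:
            ops_codes = [normalize_code(c) for c in _split_list(row["ops_codes"], dialect.list_separator)]
            # dates split positionally (empty tokens = missing date)
            ops_dates_raw = (
                [t.strip() for t in row["ops_dates"].split(dialect.list_separator)]
                if row["ops_dates"].strip(dialect.list_separator + " ") else []
            )
            if ops_dates_raw and len(ops_dates_raw) != len(ops_codes):
                raise RegistryFormatError(
                    f"case {row['case_id']!r}: {len(ops_codes)} ops codes but "
                    f"{len(ops_dates_raw)} ops dates"
                )
            dates = [_parse_date(d) if d != "" else None for d in ops_dates_raw] or [None] * len(ops_codes)
            records.append(CaseRecord(
                case_id=row["case_id"],
                age=int(row["age"]) if row["age"] != "" else None,
                sex=row["sex"] or "other",
                icd_codes=[normalize_code(c) for c in _split_list(row["icd_codes"], dialect.list_separator)],
                procedures=list(zip(ops_codes, dates)),
                discharge_reason=row["discharge_reason"] or None,
                admission_date=_parse_date(row["admission_date"]),
                discharge_date=_parse_date(row["discharge_date"]),
            ))
    ids = [r.case_id for r in records]
    if any(not i for i in ids):
        raise RegistryFormatError("empty case_id encountered")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise RegistryFormatError(f"duplicate case ids: {sorted(set(dups))[:20]}")
    return records


def write_cases(cases: Iterable[CaseRecord], path: str | Path,
                dialect: RegistryDialect = RegistryDialect()) -> None:
    """Write cases in the registry dialect (inverse of :func:`read_cases`)."""
    path = Path(path)
    sep = dialect.list_separator
    with path.open("w", newline="", encoding=dialect.encoding) as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS)
        for c in cases:
            writer.writerow([
                c.case_id,
                "" if c.age is None else c.age,
                c.sex,
                sep.join(c.icd_codes),
                sep.join(code for code, _ in c.procedures),
                sep.join("" if d is None else d.isoformat() for _, d in c.procedures),
                "" if c.admission_date is None else c.admission_date.isoformat(),
                "" if c.discharge_date is None else c.discharge_date.isoformat(),
                c.discharge_reason or "",
            ])


def write_scored_cases(scored: Sequence, path: str | Path) -> None:
    """Write one row per scored case: id, demographics, score decomposition,
    assigned surgery group, predicted risk and outcome.

    Floats are written with full ``repr`` precision so a write→read round
    trip is bit-exact.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORED_COLUMNS)
        for s in scored:
            writer.writerow([
                s.case.case_id,
                "" if s.case.age is None else s.case.age,
                s.case.sex,
                s.score,
                s.age_points,
                s.comorbidity_points,
                s.surgery_points,
                s.surgery_group,
                "" if s.predicted_risk is None else repr(s.predicted_risk),
                int(s.outcome.died_in_hospital),
            ])


def read_scored_cases(path: str | Path) -> list[dict]:
    """Read a scored-cases CSV back into plain dicts (typed columns)."""
    path = Path(path)
    out: list[dict] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in SCORED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise RegistryFormatError(f"scored file {path.name} missing columns: {missing}")
        for row in reader:
            out.append({
                "case_id": row["case_id"],
                "age": int(row["age"]) if row["age"] != "" else None,
                "sex": row["sex"],
                "score": int(row["score"]),
                "age_points": int(row["age_points"]),
                "comorbidity_points": int(row["comorbidity_points"]),
                "surgery_points": int(row["surgery_points"]),
                "surgery_group": row["surgery_group"],
                "predicted_risk": float(row["predicted_risk"]) if row["predicted_risk"] != "" else None,
                "died": bool(int(row["died"])),
            })
    return out
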