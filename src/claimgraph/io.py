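"""Reading, validation and month-grouping of raw claims and demographics tables.

Claims arrive as delimited text with one row per billed event.  Everything
downstream operates on :class:`PatientTimeline` objects: a patient's
demographics plus a chronologically sorted sequence of typed code events.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CODE_TYPES = ("diagnosis", "procedure", "medication")


@dataclass(frozen=True, order=True)
class ClaimRecord:
    """One billed event: a dated, typed medical code."""

    service_date: dt.date
    code: str
    code_type: str

    def __post_init__(self) -> None:
        if self.code_type not in CODE_TYPES:
            raise ValueError(f"unknown code_type {self.code_type!r}")
        if not self.code or self.code != self.code.strip():
            raise ValueError(f"bad code {self.code!r}")


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    birth_year: int
    gender: str

    @property
    def valid(self) -> bool:
        current_year = dt.date.today().year
        return (
            1880 <= self.birth_year <= current_year
            and bool(self.gender)
            and self.gender == self.gender  # NaN guard
        )


@dataclass
class PatientTimeline:
    patient_id: str
    demographics: Demographics | None
    records: list[ClaimRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records.sort(key=lambda r: (r.service_date, r.code_type, r.code))

    @property
    def first_date(self) -> dt.date:
        return self.records[0].service_date

    @property
    def last_date(self) -> dt.date:
        return self.records[-1].service_date


@dataclass(frozen=True)
class MonthBucket:
    """Distinct (code, code_type) pairs a patient accrued in one calendar month."""

    month: tuple[int, int]
    codes: frozenset[tuple[str, str]]


@dataclass
class Dialect:
    """Column names and delimiter of the input tables."""

    delimiter: str = ","
    patient_id: str = "patient_id"
    service_date: str = "service_date"
    code: str = "code"
    code_type: str = "code_type"
    birth_year: str = "birth_year"
    gender: str = "gender"


@dataclass
class LoadReport:
    n_rows: int = 0
    n_bad_date: int = 0
    n_bad_type: int = 0
    n_bad_code: int = 0
    n_duplicates: int = 0
    n_no_demographics: int = 0
    n_no_claims: int = 0
    n_patients: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def read_claims(
    claims_path: str | Path,
    demographics_path: str | Path,
    dialect: Dialect | None = None,
) -> tuple[list[PatientTimeline], LoadReport]:
    """Load the two input tables into per-patient timelines.

    Only patients present in *both* tables are returned.  Rows with
    unparseable dates, unknown code types, or empty codes are dropped and
    counted in the report; exact duplicate rows are silently deduplicated.
    """
    d = dialect or Dialect()
    claims_path, demographics_path = Path(claims_path), Path(demographics_path)
    for p in (claims_path, demographics_path):
        if not p.exists():
            raise FileNotFoundError(p)

    claims = pd.read_csv(claims_path, sep=d.delimiter, dtype=str)
    demo = pd.read_csv(demographics_path, sep=d.delimiter, dtype=str)
    report = LoadReport(n_rows=len(claims))

    parsed = pd.to_datetime(claims[d.service_date], errors="coerce", format="mixed")
    bad_date = parsed.isna()
    report.n_bad_date = int(bad_date.sum())
    claims = claims[~bad_date].assign(_date=parsed[~bad_date].dt.date)

    bad_type = ~claims[d.code_type].isin(CODE_TYPES)
    report.n_bad_type = int(bad_type.sum())
    claims = claims[~bad_type]

    codes = claims[d.code].fillna("").str.strip()
    bad_code = codes == ""
    report.n_bad_code = int(bad_code.sum())
    claims = claims[~bad_code].assign(**{d.code: codes[~bad_code]})

    n_before = len(claims)
    claims = claims.drop_duplicates(subset=[d.patient_id, "_date", d.code, d.code_type])
    report.n_duplicates = n_before - len(claims)
    if report.n_duplicates:
        logger.info("deduplicated %d claim rows", report.n_duplicates)

    demo_by_id: dict[str, Demographics] = {}
    for row in demo.itertuples(index=False):
        rd = row._asdict() if hasattr(row, "_asdict") else dict(zip(demo.columns, row))
        pid = str(rd[d.patient_id])
        try:
            by = int(float(rd[d.birth_year]))
        except (TypeError, ValueError):
            continue
        gender = rd[d.gender]
        if pd.isna(gender) or not str(gender).strip():
            continue
        demo_by_id[pid] = Demographics(pid, by, str(gender).strip())

    timelines: list[PatientTimeline] = []
    claim_ids = set()
    for pid, grp in claims.groupby(d.patient_id, sort=True):
        pid = str(pid)
        claim_ids.add(pid)
        if pid not in demo_by_id:
            report.n_no_demographics += 1
            continue
        recs = [
            ClaimRecord(date, code, ctype)
            for date, code, ctype in grp[["_date", d.code, d.code_type]]
            .itertuples(index=False, name=None)
        ]
        timelines.append(PatientTimeline(pid, demo_by_id[pid], recs))
    report.n_no_claims = len(set(demo_by_id) - claim_ids)
    report.n_patients = len(timelines)

    if not timelines:
        raise ValueError("no valid patients after loading")
    return timelines, report


def group_month_level(
    timeline: PatientTimeline,
    window: tuple[dt.date, dt.date],
) -> list[MonthBucket]:
    """Bucket a timeline's records into calendar months inside ``[start, end)``.

    Months without records are absent; codes within a month follow set
    semantics on (code, code_type).
    """
    start, end = window
    by_month: dict[tuple[int, int], set[tuple[str, str]]] = {}
    for rec in timeline.records:
        if start <= rec.service_date < end:
            key = (rec.service_date.year, rec.service_date.month)
            by_month.setdefault(key, set()).add((rec.code, rec.code_type))
    return [MonthBucket(m, frozenset(by_month[m])) for m in sorted(by_month)]


def write_claims(
    timelines: Iterable[PatientTimeline],
    claims_path: str | Path,
    demographics_path: str | Path,
    dialect: Dialect | None = None,
) -> None:
    """Serialize timelines back to the two delimited tables (round-trip safe)."""
    d = dialect or Dialect()
    claim_rows, demo_rows = [], []
    for tl in timelines:
        for rec in tl.records:
            claim_rows.append(
                {
                    d.patient_id: tl.patient_id,
                    d.service_date: rec.service_date.isoformat(),
                    d.code: rec.code,
                    d.code_type: rec.code_type,
                }
            )
        if tl.demographics is not None:
            demo_rows.append(
                {
                    d.patient_id: tl.patient_id,
                    d.birth_year: tl.demographics.birth_year,
                    d.gender: tl.demographics.gender,
                }
            )
    pd.DataFrame(claim_rows).to_csv(claims_path, sep=d.delimiter, index=False)
    pd.DataFrame(demo_rows).to_csv(demographics_path, sep=d.delimiter, index=False)


def write_report(report: Mapping[str, object] | LoadReport, path: str | Path) -> None:
    rep = report.as_dict() if isinstance(report, LoadReport) else dict(report)
    with open(path, "w") as fh:
        for k, v in rep.items():
            fh.write(f"{k}\t{v}\n")
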