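"""Eligibility filtering, case classification, index-day sampling and
scenario-cohort construction.

A scenario is defined by the length of its index-selection window (1, 2 or
3 years).  For each eligible patient an index day is drawn uniformly from
the window immediately preceding the anchor date (first dementia evidence
for cases, last record for controls); the 3 years before the index day form
the feature window.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .io import MonthBucket, PatientTimeline, group_month_level

#: Diagnosis code prefixes (wildcards removed, dots ignored at match time)
#: and medication name substrings defining the dementia case cohort.
DEFAULT_DIAGNOSIS_PATTERNS = [
    "331.0", "G30.", "290.4", "F01.", "331.1", "G31.0",
    "331.82", "G31.83", "290.0", "290.1", "290.8", "290.9",
]
DEFAULT_MEDICATION_NAMES = [
    "aricept", "donepezil", "razadyne", "reminyl", "galantamine",
    "exelon", "rivastigmine", "namenda", "memantine", "acetylcholine",
]

MIN_AGE = 65
MIN_SPAN_YEARS = 3
MIN_CODES_PER_MONTH = 3
MIN_FEATURE_MONTHS = 2
FEATURE_WINDOW_YEARS = 3


def _strip_dots(code: str) -> str:
    return code.replace(".", "")


@dataclass
class CaseDefinition:
    diagnosis_patterns: list[str] = field(
        default_factory=lambda: list(DEFAULT_DIAGNOSIS_PATTERNS)
    )
    medication_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_MEDICATION_NAMES)
    )

    def __post_init__(self) -> None:
        if not self.diagnosis_patterns or not self.medication_names:
            raise ValueError("case definition lists must be non-empty")
        self.diagnosis_patterns = [
            _strip_dots(p.rstrip("*")) for p in self.diagnosis_patterns
        ]
        self.medication_names = [m.lower() for m in self.medication_names]

    @classmethod
    def from_file(cls, path: str) -> "CaseDefinition":
        """Read a two-section config: lines ``diagnosis<TAB>pattern`` and
        ``medication<TAB>name``."""
        diag, meds = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                kind, _, value = line.partition("\t")
                if kind == "diagnosis":
                    diag.append(value)
                elif kind == "medication":
                    meds.append(value)
        return cls(diag, meds)


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_id: int
    index_window_years: int
    feature_window_years: int = FEATURE_WINDOW_YEARS
    prediction_window_years: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.index_window_years < 1 or self.feature_window_years < 1:
            raise ValueError("window lengths must be >= 1 year")
        if self.prediction_window_years is None:
            object.__setattr__(
                self, "prediction_window_years", self.index_window_years
            )

    @classmethod
    def for_scenario(cls, scenario_id: int, rng_seed: int = 0) -> "ScenarioConfig":
        if scenario_id not in (1, 2, 3):
            raise ValueError("scenario_id must be 1, 2 or 3")
        return cls(scenario_id, index_window_years=scenario_id, rng_seed=rng_seed)


@dataclass
class LabeledPatient:
    patient_id: str
    label: int  # 1 = case, 0 = control
    anchor_date: dt.date
    index_day: dt.date
    feature_months: list[MonthBucket]
    age_at_index: int
    gender: str


@dataclass
class ScenarioCohort:
    scenario: ScenarioConfig
    patients: list[LabeledPatient]
    exclusion_report: dict[str, int]

    @property
    def n_cases(self) -> int:
        return sum(p.label for p in self.patients)

    @property
    def n_controls(self) -> int:
        return len(self.patients) - self.n_cases


def classify_adrd(
    timeline: PatientTimeline, case_def: CaseDefinition
) -> tuple[int, dt.date]:
    """Label a timeline and return its anchor date.

    Cases match a diagnosis-code prefix (dot-insensitive) or a medication
    name substring (case-insensitive); their anchor is the earliest
    qualifying record.  Controls anchor at their last record.
    """
    if not timeline.records:
        raise ValueError("empty timeline")
    qualifying: list[dt.date] = []
    for rec in timeline.records:
        if rec.code_type == "diagnosis":
            stripped = _strip_dots(rec.code)
            if any(stripped.startswith(p) for p in case_def.diagnosis_patterns):
                qualifying.append(rec.service_date)
        elif rec.code_type == "medication":
            low = rec.code.lower()
            if any(name in low for name in case_def.medication_names):
                qualifying.append(rec.service_date)
    if qualifying:
        return 1, min(qualifying)
    return 0, timeline.last_date


def apply_eligibility(
    timelines: list[PatientTimeline], case_def: CaseDefinition
) -> tuple[list[PatientTimeline], dict[str, int]]:
    """Apply the three eligibility filters in fixed order.

    (a) age >= 65 at anchor, (b) record span >= 3 years, (c) demographics
    present and valid.  Ordering is fixed so the exclusion report is
    deterministic.
    """
    report = {"input": len(timelines), "age": 0, "span": 0, "demographics": 0}
    eligible: list[PatientTimeline] = []
    for tl in timelines:
        _, anchor = classify_adrd(tl, case_def)
        if tl.demographics is not None:
            age = anchor.year - tl.demographics.birth_year
            if age < MIN_AGE:
                report["age"] += 1
                continue
        span_days = (tl.last_date - tl.first_date).days
        if span_days < MIN_SPAN_YEARS * 365:
            report["span"] += 1
            continue
        if tl.demographics is None or not tl.demographics.valid:
            report["demographics"] += 1
            continue
        eligible.append(tl)
    report["retained"] = len(eligible)
    return eligible, report


def _shift_years(day: dt.date, years: int) -> dt.date:
    try:
        return day.replace(year=day.year + years)
    except ValueError:  # Feb 29
        return day.replace(year=day.year + years, day=28)


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # stable per-patient substream: cohort content is order-independent
    digest = int.from_bytes(patient_id.encode("utf-8")[:8].ljust(8, b"\0"), "big")
    return np.random.default_rng(np.random.SeedSequence([seed, digest & 0x7FFFFFFF]))


def sample_index_day(
    anchor_date: dt.date,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
) -> dt.date:
    """Draw the index day uniformly (day resolution) from
    ``[anchor - index_window_years, anchor)``."""
    start = _shift_years(anchor_date, -scenario.index_window_years)
    n_days = (anchor_date - start).days
    if n_days <= 0:
        raise ValueError("anchor date precedes representable window")
    return start + dt.timedelta(days=int(rng.integers(0, n_days)))


def build_scenario_cohort(
    timelines: list[PatientTimeline],
    case_def: CaseDefinition,
    scenario: ScenarioConfig,
) -> ScenarioCohort:
    """Sample index days and extract labeled feature windows.

    Feature months with fewer than 3 distinct codes are dropped, then
    patients with fewer than 2 surviving months are excluded.
    """
    patients: list[LabeledPatient] = []
    report = {"input": len(timelines), "no_window": 0, "few_months": 0}
    for tl in timelines:
        label, anchor = classify_adrd(tl, case_def)
        rng = _patient_rng(scenario.rng_seed, tl.patient_id)
        try:
            index_day = sample_index_day(anchor, scenario, rng)
        except ValueError:
            report["no_window"] += 1
            continue
        window = (_shift_years(index_day, -scenario.feature_window_years), index_day)
        buckets = group_month_level(tl, window)
        buckets = [b for b in buckets if len(b.codes) >= MIN_CODES_PER_MONTH]
        if len(buckets) < MIN_FEATURE_MONTHS:
            report["few_months"] += 1
            continue
        assert index_day < anchor
        if label == 1:
            horizon = _shift_years(index_day, scenario.prediction_window_years)
            assert index_day < anchor <= horizon, "case anchor outside prediction window"
        patients.append(
            LabeledPatient(
                patient_id=tl.patient_id,
                label=label,
                anchor_date=anchor,
                index_day=index_day,
                feature_months=buckets,
                age_at_index=index_day.year - tl.demographics.birth_year,
                gender=tl.demographics.gender,
            )
        )
    report["retained"] = len(patients)
    return ScenarioCohort(scenario, patients, report)


def cohort_tables(cohort: ScenarioCohort):
    """Serialize a cohort as (patients table, long feature table) DataFrames."""
    import pandas as pd

    prows = [
        {
            "patient_id": p.patient_id,
            "label": p.label,
            "index_day": p.index_day.isoformat(),
            "age_at_index": p.age_at_index,
            "gender": p.gender,
        }
        for p in cohort.patients
    ]
    frows = [
        {
            "patient_id": p.patient_id,
            "month": f"{b.month[0]:04d}-{b.month[1]:02d}",
            "code": code,
            "code_type": ctype,
        }
        for p in cohort.patients
        for b in p.feature_months
        for code, ctype in sorted(b.codes)
    ]
    return pd.DataFrame(prows), pd.DataFrame(frows)
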