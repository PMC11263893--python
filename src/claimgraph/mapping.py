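"""Rollup of raw medical codes to a compact category vocabulary.

Diagnosis/procedure codes roll up CCS-style and drug codes AHFS-style via
longest-prefix matching against a user-supplied mapping table.  Only a toy
table ships with the package; full licensed crosswalks drop in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .cohort import ScenarioCohort
from .io import MonthBucket

UNMAPPED = "__UNMAPPED__"


def _strip_dots(code: str) -> str:
    return code.replace(".", "")


@dataclass
class MappingTable:
    """(code_type, source_pattern) -> category rollup rules."""

    entries: list[tuple[str, str, str, str]]
    _by_type: dict[str, list[tuple[str, str]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for ctype, pattern, cat_id, _label in self.entries:
            if not cat_id:
                raise ValueError("empty category_id")
            key = (ctype, _strip_dots(pattern))
            if key in seen:
                raise ValueError(f"duplicate mapping entry {key}")
            seen.add(key)
        self._by_type = {}
        for ctype, pattern, cat_id, _label in self.entries:
            self._by_type.setdefault(ctype, []).append((_strip_dots(pattern), cat_id))
        for rules in self._by_type.values():
            rules.sort(key=lambda r: -len(r[0]))  # longest prefix wins

    @property
    def labels(self) -> dict[str, str]:
        return {cat: label for _, _, cat, label in self.entries}

    @property
    def n_categories(self) -> int:
        return len({cat for _, _, cat, _ in self.entries})

    @classmethod
    def from_file(cls, path: str | Path, sep: str = ",") -> "MappingTable":
        df = pd.read_csv(path, sep=sep, dtype=str)
        entries = [
            (r.code_type, r.source_pattern, r.category_id, r.category_label)
            for r in df.itertuples(index=False)
        ]
        return cls(entries)

    def to_file(self, path: str | Path, sep: str = ",") -> None:
        pd.DataFrame(
            self.entries,
            columns=["code_type", "source_pattern", "category_id", "category_label"],
        ).to_csv(path, sep=sep, index=False)

    @classmethod
    def identity(cls, codes: list[tuple[str, str]]) -> "MappingTable":
        """Maps each (code, code_type) to itself; useful for idempotence checks."""
        return cls([(ct, c, c, c) for c, ct in sorted(set(codes))])


@dataclass
class Vocabulary:
    """Ordered category list with positions 0..|V|-1."""

    categories: list[tuple[str, str, str]]  # (category_id, code_type, label)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {cat: i for i, (cat, _, _) in enumerate(self.categories)}
        if len(self.index) != len(self.categories):
            raise ValueError("duplicate category_id in vocabulary")

    def __len__(self) -> int:
        return len(self.categories)

    def id_at(self, pos: int) -> str:
        return self.categories[pos][0]

    def label_at(self, pos: int) -> str:
        return self.categories[pos][2]


def map_code(code: str, code_type: str, table: MappingTable) -> str:
    """Longest matching prefix rule (dot-insensitive); UNMAPPED if none."""
    stripped = _strip_dots(code)
    for pattern, cat_id in table._by_type.get(code_type, ()):
        if stripped.startswith(pattern):
            return cat_id
    return UNMAPPED


def map_cohort(
    cohort: ScenarioCohort, table: MappingTable
) -> tuple[ScenarioCohort, Vocabulary, dict[str, int]]:
    """Replace every feature code by its rolled-up category.

    Duplicates within a month collapse after mapping; unmapped codes are
    dropped and counted.  Months are NOT re-filtered after rollup.
    """
    labels = table.labels
    n_total = 0
    n_unmapped = 0
    observed: set[tuple[str, str]] = set()
    mapped_patients = []
    for patient in cohort.patients:
        new_months = []
        for bucket in patient.feature_months:
            mapped: set[tuple[str, str]] = set()
            for code, ctype in bucket.codes:
                n_total += 1
                cat = map_code(code, ctype, table)
                if cat == UNMAPPED:
                    n_unmapped += 1
                    continue
                mapped.add((cat, ctype))
                observed.add((ctype, cat))
            if mapped:
                new_months.append(MonthBucket(bucket.month, frozenset(mapped)))
        mapped_patients.append(replace_months(patient, new_months))

    vocab = Vocabulary(
        [(cat, ctype, labels.get(cat, cat)) for ctype, cat in sorted(observed)]
    )
    report = {
        "codes_seen": n_total,
        "codes_unmapped": n_unmapped,
        "vocab_size": len(vocab),
    }
    if n_total and n_unmapped / n_total > 0.5:
        report["warning_high_unmapped"] = 1
    mapped_cohort = ScenarioCohort(cohort.scenario, mapped_patients, dict(cohort.exclusion_report))
    return mapped_cohort, vocab, report


def replace_months(patient, new_months):
    from dataclasses import replace as _dc_replace

    return _dc_replace(patient, feature_months=new_months)


def toy_mapping_table() -> MappingTable:
    """Small bundled crosswalk (~40 raw prefixes per type onto 12 categories)."""
    entries = []
    specs = {
        "diagnosis": ("DX", ["250", "401", "272", "414", "427", "428", "311",
                             "496", "530", "715", "780", "599"]),
        "procedure": ("PR", ["93000", "71020", "80053", "36415", "99213",
                             "99214", "45378", "66984", "77067", "70450",
                             "20610", "90832"]),
        "medication": ("RX", ["metformin", "lisinopril", "atorvastatin",
                              "amlodipine", "omeprazole", "sertraline",
                              "levothyroxine", "albuterol", "gabapentin",
                              "losartan", "furosemide", "warfarin"]),
    }
    for ctype, (prefix, roots) in specs.items():
        for i, root in enumerate(roots):
            cat = f"{prefix}{i:02d}"
            label = f"{ctype} category {root}"
            entries.append((ctype, root, cat, label))
            # a few sub-prefixes exercising longest-prefix resolution
            for suffix in ("0", "1", "9")[: 2 if i % 2 else 3]:
                entries.append((ctype, root + suffix, cat, label))
    return MappingTable(entries)
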