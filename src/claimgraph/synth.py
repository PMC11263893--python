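"""Synthetic longitudinal-claims generator with planted relational signal.

Every category has a patient-level activation (does this patient carry the
code at all) and a per-month inclusion rate given activation.  Planted risk
pairs are activated *jointly* in cases so that their within-month
co-occurrence rate is ``lift`` times the independent rate, while each
category's marginal prevalence is identical across groups; protective
pairs get the same treatment in controls.  Labels are realized by
appending a qualifying dementia diagnosis code to each case at its anchor
month, so the generated tables exercise the whole pipeline end to end.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClaimRecord, Demographics, PatientTimeline
from .mapping import MappingTable

RAW_VARIANTS = ("A", "B", "C")  # several raw codes roll up onto one category
ANCHOR_MONTH = (2019, 12)
ADRD_SEED_CODE = "G3001"  # matches the G30.* case-definition pattern

_TYPE_PREFIX = {"D": "diagnosis", "P": "procedure", "M": "medication"}


@dataclass
class SyntheticSpec:
    n_cases: int = 200
    n_controls: int = 200
    n_diagnosis: int = 10
    n_procedure: int = 8
    n_medication: int = 8
    baseline_rate: float = 0.35  # per-month inclusion prob given activation
    visit_prob: float = 0.9
    months_span: int = 54
    codes_per_month: int = 3  # minimum codes per active month (topped up)
    risk_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    protective_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    #: block-structured co-activation: (members_a, members_b, joint_prob,
    #: solo_prob); one random member per side fires, jointly more often in
    #: the lifted group, with block marginals matched across groups
    risk_blocks: list[tuple[list[str], list[str], float, float]] = field(
        default_factory=list
    )
    protective_blocks: list[tuple[list[str], list[str], float, float]] = field(
        default_factory=list
    )
    pair_marginal: float = 0.5  # activation marginal of pair categories
    noise_activation_range: tuple[float, float] = (0.25, 0.75)
    n_routine: int = 3  # always-active filler categories backing the top-up
    routine_rate: float = 0.9
    case_only_code: str | None = None
    case_only_rate: float = 0.6
    age_range: tuple[int, int] = (66, 90)
    gender_probs: tuple[float, float] = (0.55, 0.45)  # (F, M)
    confounding_strength: float = 0.0  # years added to case ages
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_diagnosis, self.n_procedure, self.n_medication) < 5:
            raise ValueError("vocab sizes must be >= 5")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must be in (0,1)")
        if self.months_span < 48:
            raise ValueError("months_span must be >= 48")
        for a, b, lift in self.risk_pairs + self.protective_pairs:
            if lift < 1.0:
                raise ValueError("pair lifts must be >= 1")
            if a == b:
                raise ValueError("pair categories must be distinct")
        if self.codes_per_month > len(self.categories):
            raise ValueError("codes_per_month exceeds vocabulary size")

    @property
    def categories(self) -> list[str]:
        return (
            [f"D{i:02d}" for i in range(self.n_diagnosis)]
            + [f"P{i:02d}" for i in range(self.n_procedure)]
            + [f"M{i:02d}" for i in range(self.n_medication)]
        )


@dataclass
class TruthRecord:
    spec: SyntheticSpec
    labels: dict[str, int]
    risk_pairs: list[tuple[str, str, float]]
    protective_pairs: list[tuple[str, str, float]]
    #: pair -> (case month-co-occurrence rate, control month-co-occurrence rate)
    month_cooccurrence: dict[tuple[str, str], tuple[float, float]]
    #: pair -> (case patient co-presence rate, control patient co-presence rate)
    patient_copresence: dict[tuple[str, str], tuple[float, float]]


def _months_back(anchor: tuple[int, int], k: int) -> tuple[int, int]:
    y, m = anchor
    total = y * 12 + (m - 1) - k
    return total // 12, total % 12 + 1


def mapping_for_spec(spec: SyntheticSpec) -> MappingTable:
    entries = []
    for cat in spec.categories:
        ctype = _TYPE_PREFIX[cat[0]]
        entries.append((ctype, cat, cat, f"{ctype} class {cat}"))
    return MappingTable(entries)


def _pair_activation(
    rng: np.random.Generator, n: int, m: float, lift: float, lifted: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Joint activation of a pair with marginals m; joint prob lift*m^2 when
    lifted (capped at m), independent otherwise."""
    if lifted:
        rho = min(lift * m * m, m)
        u = rng.random(n)
        both = u < rho
        a_only = (u >= rho) & (u < rho + (m - rho))
        b_only = (u >= rho + (m - rho)) & (u < rho + 2 * (m - rho))
        return both | a_only, both | b_only
    return rng.random(n) < m, rng.random(n) < m


def generate_cohort(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, MappingTable, TruthRecord]:
    """Emit (claims table, demographics table, mapping table, truth)."""
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    cats = spec.categories
    cat_idx = {c: i for i, c in enumerate(cats)}
    n_cat = len(cats)
    if spec.codes_per_month > n_cat:
        raise ValueError("codes_per_month exceeds vocabulary size")

    special = {spec.case_only_code} if spec.case_only_code else set()
    for a, b, _l in spec.risk_pairs + spec.protective_pairs:
        if a in special or b in special or a == b:
            raise ValueError("pair categories must be distinct and unshared")
        special.update((a, b))
    for mem_a, mem_b, rho, beta in spec.risk_blocks + spec.protective_blocks:
        members = list(mem_a) + list(mem_b)
        if len(set(members)) != len(members) or special & set(members):
            raise ValueError("block categories must be distinct and unshared")
        if not (0 < rho and rho + 2 * beta <= 1):
            raise ValueError("invalid block probabilities")
        special.update(members)
    missing = special - set(cats)
    if missing:
        raise ValueError(f"planted categories not in vocabulary: {missing}")
    noise = [c for c in cats if c not in special]
    if len(noise) <= spec.n_routine:
        raise ValueError("not enough non-planted categories for routine filler")
    routine, noise = noise[: spec.n_routine], noise[spec.n_routine :]
    noise_m = np.linspace(*spec.noise_activation_range, len(noise))

    n_total = spec.n_cases + spec.n_controls
    labels_arr = np.array([1] * spec.n_cases + [0] * spec.n_controls)
    # shuffle so patient id order carries no label information
    order = rng.permutation(n_total)
    labels_arr = labels_arr[order]
    ids = [f"S{i:06d}" for i in range(n_total)]

    # patient-level activation matrix
    activation = np.zeros((n_total, n_cat), dtype=bool)
    for c in routine:
        activation[:, cat_idx[c]] = True
    for c, m in zip(noise, noise_m):
        activation[:, cat_idx[c]] = rng.random(n_total) < m
    for pairs, lifted_label in ((spec.risk_pairs, 1), (spec.protective_pairs, 0)):
        for a, b, lift in pairs:
            in_group = labels_arr == lifted_label
            for group_mask, lifted in ((in_group, True), (~in_group, False)):
                act_a, act_b = _pair_activation(
                    rng, int(group_mask.sum()), spec.pair_marginal, lift, lifted
                )
                activation[group_mask, cat_idx[a]] = act_a
                activation[group_mask, cat_idx[b]] = act_b
    for blocks, lifted_label in (
        (spec.risk_blocks, 1), (spec.protective_blocks, 0)
    ):
        for mem_a, mem_b, rho, beta in blocks:
            mu = rho + beta  # block marginal, equal across groups
            lifted = labels_arr == lifted_label
            u = rng.random(n_total)
            fire_a = np.where(lifted, u < rho + beta, u < mu)
            v = np.where(lifted, u, rng.random(n_total))
            fire_b = np.where(
                lifted,
                (u < rho) | ((u >= rho + beta) & (u < rho + 2 * beta)),
                v < mu,
            )
            pick_a = rng.integers(0, len(mem_a), size=n_total)
            pick_b = rng.integers(0, len(mem_b), size=n_total)
            for j, c in enumerate(mem_a):
                activation[:, cat_idx[c]] |= fire_a & (pick_a == j)
            for j, c in enumerate(mem_b):
                activation[:, cat_idx[c]] |= fire_b & (pick_b == j)
    if spec.case_only_code:
        activation[:, cat_idx[spec.case_only_code]] = labels_arr == 1

    monthly_rate = np.full(n_cat, spec.baseline_rate)
    for c in routine:
        monthly_rate[cat_idx[c]] = spec.routine_rate
    if spec.case_only_code:
        monthly_rate[cat_idx[spec.case_only_code]] = spec.case_only_rate

    S = spec.months_span
    month_keys = [_months_back(ANCHOR_MONTH, k) for k in range(S - 1, -1, -1)]
    anchor_date = dt.date(ANCHOR_MONTH[0], ANCHOR_MONTH[1], 15)

    claim_rows: list[tuple[str, str, str, str]] = []
    demo_rows = []
    labels: dict[str, int] = {}
    pair_stats = {
        (a, b): np.zeros(4)  # case co-months, case months, ctrl co-months, ctrl months
        for a, b, _l in spec.risk_pairs + spec.protective_pairs
    }
    pair_present = {k: np.zeros(4) for k in pair_stats}

    for p in range(n_total):
        pid = ids[p]
        label = int(labels_arr[p])
        labels[pid] = label

        active_months = rng.random(S) < spec.visit_prob
        occur = (
            active_months[:, None]
            & activation[p][None, :]
            & (rng.random((S, n_cat)) < monthly_rate[None, :])
        )
        # top up sparse visit months from the routine categories only, so the
        # per-patient category union is unaffected
        counts = occur.sum(axis=1)
        for s in np.nonzero((counts > 0) & (counts < spec.codes_per_month))[0]:
            for c in routine:
                if counts[s] >= spec.codes_per_month:
                    break
                if not occur[s, cat_idx[c]]:
                    occur[s, cat_idx[c]] = True
                    counts[s] += 1

        months_idx, cats_occ = np.nonzero(occur)
        days = rng.integers(1, 28, size=len(months_idx))
        variants = rng.integers(0, len(RAW_VARIANTS), size=len(months_idx))
        for row in range(len(months_idx)):
            y, mo = month_keys[months_idx[row]]
            cat = cats[cats_occ[row]]
            claim_rows.append(
                (
                    pid,
                    f"{y:04d}-{mo:02d}-{days[row]:02d}",
                    cat + RAW_VARIANTS[variants[row]],
                    _TYPE_PREFIX[cat[0]],
                )
            )
        if label == 1:
            claim_rows.append(
                (pid, anchor_date.isoformat(), ADRD_SEED_CODE, "diagnosis")
            )

        offset = spec.confounding_strength if label == 1 else 0.0
        age = float(rng.uniform(*spec.age_range)) + offset
        gender = "F" if rng.random() < spec.gender_probs[0] else "M"
        demo_rows.append((pid, ANCHOR_MONTH[0] - int(age), gender))

        # realized-signal bookkeeping
        base = 0 if label == 1 else 2
        for (a, b), acc in pair_stats.items():
            ia, ib = cat_idx[a], cat_idx[b]
            acc[base] += int((occur[:, ia] & occur[:, ib]).sum())
            acc[base + 1] += int(active_months.sum())
            pair_present[(a, b)][base] += int(occur[:, ia].any() and occur[:, ib].any())
            pair_present[(a, b)][base + 1] += 1

    claims = pd.DataFrame(
        claim_rows, columns=["patient_id", "service_date", "code", "code_type"]
    )
    demo = pd.DataFrame(demo_rows, columns=["patient_id", "birth_year", "gender"])

    month_co = {
        k: (v[0] / max(v[1], 1), v[2] / max(v[3], 1)) for k, v in pair_stats.items()
    }
    pat_co = {
        k: (v[0] / max(v[1], 1), v[2] / max(v[3], 1)) for k, v in pair_present.items()
    }
    truth = TruthRecord(
        spec, labels, list(spec.risk_pairs), list(spec.protective_pairs),
        month_co, pat_co,
    )
    return claims, demo, mapping_for_spec(spec), truth


def timelines_from_frames(
    claims: pd.DataFrame, demo: pd.DataFrame
) -> list[PatientTimeline]:
    """Build timelines directly from generated frames (no CSV round trip)."""
    demo_by_id = {
        str(r.patient_id): Demographics(str(r.patient_id), int(r.birth_year), r.gender)
        for r in demo.itertuples(index=False)
    }
    timelines = []
    for pid, grp in claims.groupby("patient_id", sort=True):
        pid = str(pid)
        recs = [
            ClaimRecord(dt.date.fromisoformat(r.service_date), r.code, r.code_type)
            for r in grp.drop_duplicates(
                subset=["service_date", "code", "code_type"]
            ).itertuples(index=False)
        ]
        timelines.append(PatientTimeline(pid, demo_by_id.get(pid), recs))
    return timelines


PRESETS = ("separable", "pair_interaction", "confounded", "null")


def preset(name: str, **overrides) -> SyntheticSpec:
    """Canonical generator settings used by the test and acceptance suites."""
    if name == "separable":
        spec = SyntheticSpec(
            n_cases=200, n_controls=200,
            n_diagnosis=8, n_procedure=6, n_medication=6,
            case_only_code="D00",
        )
    elif name == "pair_interaction":
        blk = 8
        spec = SyntheticSpec(
            n_cases=1000, n_controls=1000,
            n_diagnosis=30, n_procedure=25, n_medication=24,
            risk_pairs=[("D16", "P08", 1.3)],
            protective_pairs=[("D17", "M08", 1.3)],
            risk_blocks=[
                ([f"D{i:02d}" for i in range(blk)],
                 [f"P{i:02d}" for i in range(blk)], 0.45, 0.05)
            ],
            protective_blocks=[
                ([f"D{i:02d}" for i in range(8, 8 + blk)],
                 [f"M{i:02d}" for i in range(blk)], 0.45, 0.05)
            ],
            noise_activation_range=(0.03, 0.12),
        )
    elif name == "confounded":
        spec = SyntheticSpec(
            n_cases=150, n_controls=450,
            n_diagnosis=8, n_procedure=6, n_medication=6,
            case_only_code="D00", confounding_strength=6.0,
            age_range=(66, 84),
        )
    elif name == "null":
        spec = SyntheticSpec(
            n_cases=200, n_controls=200,
            n_diagnosis=8, n_procedure=6, n_medication=6,
            risk_pairs=[("D02", "P03", 1.0)],
            protective_pairs=[("D05", "M04", 1.0)],
        )
    else:
        raise ValueError(f"unknown preset {name!r}; options: {PRESETS}")
    for k, v in overrides.items():
        if not hasattr(spec, k):
            raise ValueError(f"unknown SyntheticSpec field {k!r}")
        setattr(spec, k, v)
    return spec
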