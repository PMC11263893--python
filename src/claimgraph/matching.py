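"""Test hold-out, 1:1 propensity matching on age and gender, and the 10%
subset cohort."""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .cohort import LabeledPatient, ScenarioCohort


@dataclass
class SplitResult:
    test_ids: set[str]
    train_pool_ids: set[str]


@dataclass
class MatchedCohort:
    pairs: list[tuple[str, str]]  # (case_id, control_id)
    propensity_scores: dict[str, float]

    @property
    def patient_ids(self) -> list[str]:
        out = []
        for case_id, control_id in self.pairs:
            out.append(case_id)
            out.append(control_id)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def holdout_split(
    cohort: ScenarioCohort,
    fraction: float = 0.20,
    rng: np.random.Generator | None = None,
) -> SplitResult:
    """Label-stratified uniform split reserving ``fraction`` for testing."""
    rng = rng or np.random.default_rng(0)
    if not cohort.patients:
        raise ValueError("empty cohort")
    test_ids: set[str] = set()
    pool_ids: set[str] = set()
    for label in (0, 1):
        ids = sorted(p.patient_id for p in cohort.patients if p.label == label)
        if len(ids) < 2:
            raise ValueError(f"class {label} has fewer than 2 members")
        perm = rng.permutation(len(ids))
        n_test = int(round(fraction * len(ids)))
        for rank, idx in enumerate(perm):
            (test_ids if rank < n_test else pool_ids).add(ids[idx])
    return SplitResult(test_ids, pool_ids)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def propensity_match(
    train_pool: list[LabeledPatient],
    rng: np.random.Generator | None = None,
    caliper: float | str | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching on logit propensity.

    The propensity model is a logistic regression of case status on
    standardized age and one-hot gender.  Cases are processed in descending
    score order; each takes the unused control nearest in logit score.
    ``caliper`` (off by default) drops pairs further apart than the given
    logit distance; ``"auto"`` uses 0.2 pooled-SD of the logit, the usual
    rule of thumb.
    """
    cases = [p for p in train_pool if p.label == 1]
    controls = [p for p in train_pool if p.label == 0]
    if not cases or not controls:
        raise ValueError("both classes required for matching")

    everyone = cases + controls
    age = np.array([p.age_at_index for p in everyone], dtype=float)
    age_std = (age - age.mean()) / (age.std() or 1.0)
    genders = sorted({p.gender for p in everyone})
    onehot = np.array(
        [[1.0 if p.gender == g else 0.0 for g in genders[1:]] for p in everyone]
    )
    X = np.column_stack([age_std] + ([onehot] if onehot.size else []))
    y = np.array([p.label for p in everyone])

    model = LogisticRegression(max_iter=1000)
    model.fit(X, y)
    scores = model.predict_proba(X)[:, 1]
    logits = _logit(scores)
    prop = {p.patient_id: float(s) for p, s in zip(everyone, scores)}
    if caliper == "auto":
        caliper = 0.2 * float(np.std(logits))

    case_order = sorted(
        range(len(cases)), key=lambda i: (-logits[i], cases[i].patient_id)
    )
    # controls sorted by logit for O(log n) nearest-neighbor lookup
    ctrl = sorted(
        ((logits[len(cases) + j], controls[j].patient_id) for j in range(len(controls))),
    )
    ctrl_logits = [c[0] for c in ctrl]
    ctrl_ids = [c[1] for c in ctrl]
    used = [False] * len(ctrl)

    pairs: list[tuple[str, str]] = []
    for i in case_order:
        target = logits[i]
        pos = bisect.bisect_left(ctrl_logits, target)
        best, best_d = -1, np.inf
        lo, hi = pos - 1, pos
        while lo >= 0 and used[lo]:
            lo -= 1
        while hi < len(ctrl) and used[hi]:
            hi += 1
        # expand outward past used entries until both frontiers are worse
        while lo >= 0 or hi < len(ctrl):
            cand = []
            if lo >= 0:
                cand.append((abs(ctrl_logits[lo] - target), lo))
            if hi < len(ctrl):
                cand.append((abs(ctrl_logits[hi] - target), hi))
            d, j = min(cand)
            if d >= best_d:
                break
            best, best_d = j, d
            if j == lo:
                lo -= 1
                while lo >= 0 and used[lo]:
                    lo -= 1
            else:
                hi += 1
                while hi < len(ctrl) and used[hi]:
                    hi += 1
        if best < 0:
            continue
        if caliper is not None and best_d > caliper:
            continue
        used[best] = True
        pairs.append((cases[i].patient_id, ctrl_ids[best]))

    if not pairs:
        raise ValueError("no matches possible")
    return MatchedCohort(sorted(pairs), prop)


def make_subset(
    matched: MatchedCohort,
    fraction: float = 0.10,
    rng: np.random.Generator | None = None,
) -> MatchedCohort:
    """Uniform sample of matched *pairs* (preserves exact 1:1 balance)."""
    rng = rng or np.random.default_rng(0)
    if not matched.pairs:
        raise ValueError("empty matched cohort")
    n = int(round(fraction * len(matched.pairs)))
    if n == 0:
        raise ValueError("subset fraction yields zero pairs")
    idx = sorted(rng.choice(len(matched.pairs), size=n, replace=False))
    pairs = [matched.pairs[i] for i in idx]
    kept = {pid for pair in pairs for pid in pair}
    return MatchedCohort(
        pairs, {k: v for k, v in matched.propensity_scores.items() if k in kept}
    )


def standardized_mean_difference(
    values_a: np.ndarray, values_b: np.ndarray
) -> float:
    """SMD = (mean_a - mean_b) / pooled SD; the usual covariate-balance metric."""
    va, vb = np.asarray(values_a, float), np.asarray(values_b, float)
    pooled = np.sqrt((va.var(ddof=1) + vb.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return float((va.mean() - vb.mean()) / pooled)


def pairs_table(matched: MatchedCohort):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "case_id": c,
                "control_id": k,
                "case_score": matched.propensity_scores.get(c, float("nan")),
                "control_score": matched.propensity_scores.get(k, float("nan")),
            }
            for c, k in matched.pairs
        ]
    )
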