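"""Tree-ensemble baselines on binary occurrence features, and the AUROC
metric shared by every model.

The gradient-boosting baseline is LightGBM-style gbdt (300 trees, 31
leaves, learning rate 0.1) realized with scikit-learn's histogram gradient
booster, since that is the closest pre-installed equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier

from .cohort import LabeledPatient
from .mapping import Vocabulary

BASELINES = ("rf", "lgbm")


@dataclass
class FeatureTable:
    matrix: np.ndarray  # patients x |V|, binary occurrence
    patient_ids: list[str]
    labels: np.ndarray


@dataclass
class EvalReport:
    model: str
    scenario_id: int
    cohort_name: str  # matched | subset
    auroc: float
    n_test: int


def build_feature_table(
    patients: list[LabeledPatient], vocab: Vocabulary, counts: bool = False
) -> FeatureTable:
    """cell (p, c) = 1 iff category c occurs in any feature month of p
    (month counts instead when ``counts=True``)."""
    X = np.zeros((len(patients), len(vocab)))
    for row, patient in enumerate(patients):
        for bucket in patient.feature_months:
            for code, _ctype in bucket.codes:
                col = vocab.index[code]
                if counts:
                    X[row, col] += 1
                else:
                    X[row, col] = 1.0
    return FeatureTable(
        X,
        [p.patient_id for p in patients],
        np.array([p.label for p in patients]),
    )


def fit_baseline(table: FeatureTable, which: str, seed: int = 0):
    """RF (100 trees) or gbdt (300 trees, 31 leaves, lr 0.1), seeded."""
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class labels")
    if which == "rf":
        clf = RandomForestClassifier(
            n_estimators=100, min_samples_split=2, min_samples_leaf=1,
            random_state=seed, n_jobs=1,
        )
    elif which == "lgbm":
        clf = HistGradientBoostingClassifier(
            max_iter=300, max_leaf_nodes=31, learning_rate=0.1,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown baseline {which!r}")
    clf.fit(table.matrix, labels)
    return clf


def evaluate_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-formula AUROC with midrank tie handling:
    (sum of positive midranks - n+(n+ + 1)/2) / (n+ * n-)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
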