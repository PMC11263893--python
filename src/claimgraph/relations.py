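"""Case-vs-control relation importance from per-patient edge weights.

Each patient's directed edge-weight matrix is symmetrized, scattered into
global vocabulary coordinates, averaged within the case and control groups
(zeros counted for patients lacking a pair), and differenced:
``W = mean(A+) - mean(A-)``.  Positive entries mark code-pair relations
pushing predictions toward case status, negative entries away from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import Vocabulary
from .model import EdgeWeightMatrix


@dataclass
class AlignedAdjacency:
    patient_id: str
    label: int
    matrix: np.ndarray  # |V| x |V|, symmetric, zeros off the patient's node set


@dataclass
class RelationImportanceMatrix:
    W: np.ndarray
    vocab: Vocabulary
    n_cases: int
    n_controls: int


@dataclass
class RankedRelation:
    rank: int
    category_i: str
    category_j: str
    weight: float


def symmetrize(A: np.ndarray) -> np.ndarray:
    """(A + A^T) / 2 — removes edge directionality."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return (A + A.T) / 2.0


def align_to_vocab(
    A_sym: np.ndarray, node_map: list[int], vocab: Vocabulary
) -> np.ndarray:
    """Scatter a patient-local matrix into |V| x |V| vocabulary coordinates."""
    n = len(vocab)
    node_map = list(node_map)
    if len(node_map) != A_sym.shape[0]:
        raise ValueError("node_map length mismatch")
    if any(p < 0 or p >= n for p in node_map):
        raise ValueError("node_map position out of vocabulary range")
    out = np.zeros((n, n))
    pos = np.asarray(node_map)
    out[np.ix_(pos, pos)] = A_sym
    return out


def align_edge_weights(
    ewm: EdgeWeightMatrix, label: int, vocab: Vocabulary
) -> AlignedAdjacency:
    return AlignedAdjacency(
        ewm.patient_id, label, align_to_vocab(symmetrize(ewm.matrix),
                                              ewm.vocab_positions, vocab)
    )


def group_mean(matrices: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean over all patients in a group (zeros included)."""
    if not matrices:
        raise ValueError("empty group")
    return np.mean(np.stack(matrices), axis=0)


def weight_difference(
    mean_pos: np.ndarray, mean_neg: np.ndarray, vocab: Vocabulary,
    n_cases: int, n_controls: int,
) -> RelationImportanceMatrix:
    if mean_pos.shape != mean_neg.shape:
        raise ValueError("group mean shapes differ")
    W = mean_pos - mean_neg
    np.testing.assert_allclose(W, W.T, atol=1e-10)
    W = (W + W.T) / 2.0  # exact symmetry despite float noise
    np.fill_diagonal(W, 0.0)
    return RelationImportanceMatrix(W, vocab, n_cases, n_controls)


def relation_importance(
    edge_weights: list[EdgeWeightMatrix],
    labels: dict[str, int],
    vocab: Vocabulary,
    conditional_mean: bool = False,
) -> RelationImportanceMatrix:
    """Full pipeline: symmetrize -> align -> group means -> difference.

    ``conditional_mean=True`` divides each entry by the number of patients
    in the group whose graphs contain both codes, instead of the full group
    size (off by default; changes the frequency weighting of W).
    """
    pos, neg = [], []
    pos_cnt = np.zeros((len(vocab), len(vocab)))
    neg_cnt = np.zeros((len(vocab), len(vocab)))
    for ewm in edge_weights:
        aligned = align_edge_weights(ewm, labels[ewm.patient_id], vocab)
        present = np.zeros((len(vocab), len(vocab)))
        p = np.asarray(ewm.vocab_positions)
        present[np.ix_(p, p)] = 1.0
        if aligned.label == 1:
            pos.append(aligned.matrix)
            pos_cnt += present
        else:
            neg.append(aligned.matrix)
            neg_cnt += present
    if not pos or not neg:
        raise ValueError("both groups required")
    if conditional_mean:
        sum_pos = np.sum(np.stack(pos), axis=0)
        sum_neg = np.sum(np.stack(neg), axis=0)
        mean_pos = np.divide(sum_pos, pos_cnt, out=np.zeros_like(sum_pos),
                             where=pos_cnt > 0)
        mean_neg = np.divide(sum_neg, neg_cnt, out=np.zeros_like(sum_neg),
                             where=neg_cnt > 0)
    else:
        mean_pos, mean_neg = group_mean(pos), group_mean(neg)
    return weight_difference(mean_pos, mean_neg, vocab, len(pos), len(neg))


def top_k_relations(
    rim: RelationImportanceMatrix, k: int, sign: str = "positive"
) -> list[RankedRelation]:
    """Top-k unordered pairs (i<j); ties broken lexicographically."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    W, vocab = rim.W, rim.vocab
    n = W.shape[0]
    pairs = [
        (W[i, j], vocab.id_at(i), vocab.id_at(j))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    if k > len(pairs):
        import warnings

        warnings.warn(f"k={k} exceeds {len(pairs)} pairs; returning all")
        k = len(pairs)
    reverse = sign == "positive"
    pairs.sort(key=lambda t: ((-t[0] if reverse else t[0]), t[1], t[2]))
    return [
        RankedRelation(rank=r + 1, category_i=ci, category_j=cj, weight=float(w))
        for r, (w, ci, cj) in enumerate(pairs[:k])
    ]


def ranked_table(rim: RelationImportanceMatrix, k: int = 5) -> pd.DataFrame:
    rows = []
    for sign in ("positive", "negative"):
        for rel in top_k_relations(rim, k, sign):
            i, j = rim.vocab.index[rel.category_i], rim.vocab.index[rel.category_j]
            rows.append(
                {
                    "sign": sign,
                    "rank": rel.rank,
                    "category_i": rel.category_i,
                    "label_i": rim.vocab.label_at(i),
                    "category_j": rel.category_j,
                    "label_j": rim.vocab.label_at(j),
                    "weight": rel.weight,
                    "no_effect": rel.weight == 0.0,
                }
            )
    return pd.DataFrame(rows)


def matrix_table(rim: RelationImportanceMatrix) -> pd.DataFrame:
    ids = [rim.vocab.id_at(i) for i in range(len(rim.vocab))]
    return pd.DataFrame(rim.W, index=ids, columns=ids)
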