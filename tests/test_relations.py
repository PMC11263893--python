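import numpy as np
import pytest

from claimgraph.mapping import Vocabulary
from claimgraph.model import EdgeWeightMatrix
from claimgraph.relations import (align_to_vocab, group_mean,
                                  relation_importance, symmetrize,
                                  top_k_relations, weight_difference)


def vocab(n):
    return Vocabulary([(f"K{i}", "diagnosis", f"cat {i}") for i in range(n)])


class TestSymmetrize:
    def test_two_by_two(self):
        assert np.array_equal(symmetrize([[0, 2], [4, 0]]), [[0, 3], [3, 0]])

    def test_symmetric_fixed_point(self, rng):
        A = rng.random((4, 4))
        A = A + A.T
        assert np.allclose(symmetrize(A), A)

    def test_matches_elementwise_oracle(self, rng):
        A = rng.random((6, 6))
        S = symmetrize(A)
        for i in range(6):
            for j in range(6):
                assert np.isclose(S[i, j], (A[i, j] + A[j, i]) / 2)

    def test_non_square_fatal(self):
        with pytest.raises(ValueError):
            symmetrize(np.zeros((2, 3)))


class TestAlign:
    def test_two_node_patient_in_five_vocab(self):
        A = symmetrize([[0.0, 0.4], [0.6, 0.0]])
        out = align_to_vocab(A, [1, 3], vocab(5))
        assert out.shape == (5, 5)
        assert out[1, 3] == out[3, 1] == 0.5
        assert np.count_nonzero(out) == 2

    def test_full_vocab_identity_placement(self, rng):
        A = symmetrize(rng.random((4, 4)))
        out = align_to_vocab(A, [0, 1, 2, 3], vocab(4))
        assert np.allclose(out, A)

    def test_scatter_gather_round_trip(self, rng):
        A = symmetrize(rng.random((3, 3)))
        np.fill_diagonal(A, 0)
        positions = [0, 2, 4]
        out = align_to_vocab(A, positions, vocab(6))
        back = out[np.ix_(positions, positions)]
        assert np.array_equal(back, A)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            align_to_vocab(np.zeros((2, 2)), [0, 9], vocab(5))


class TestGroupMean:
    def test_single_matrix_is_itself(self, rng):
        A = rng.random((3, 3))
        assert np.allclose(group_mean([A]), A)

    def test_two_matrices(self):
        m = group_mean([np.array([[0., 1.], [1., 0.]]),
                        np.array([[0., 3.], [3., 0.]])])
        assert np.array_equal(m, [[0, 2], [2, 0]])

    def test_matches_accumulation_oracle(self, rng):
        mats = [rng.random((4, 4)) for _ in range(50)]
        acc = np.zeros((4, 4))
        for m in mats:
            acc += m
        assert np.allclose(group_mean(mats), acc / 50)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            group_mean([])


class TestWeightDifference:
    def test_identical_groups_zero(self, rng):
        m = symmetrize(rng.random((4, 4)))
        rim = weight_difference(m, m.copy(), vocab(4), 2, 2)
        assert np.all(rim.W == 0)

    def test_group_swap_antisymmetry(self, rng):
        a = symmetrize(rng.random((4, 4)))
        b = symmetrize(rng.random((4, 4)))
        w1 = weight_difference(a, b, vocab(4), 1, 1).W
        w2 = weight_difference(b, a, vocab(4), 1, 1).W
        assert np.allclose(w1, -w2)

    def test_hand_built_three_by_three(self):
        cases = [
            np.array([[0, 1, 0], [1, 0, 2], [0, 2, 0.]]),
            np.array([[0, 3, 0], [3, 0, 0], [0, 0, 0.]]),
        ]
        controls = [
            np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0.]]),
            np.array([[0, 0, 1], [0, 0, 2], [1, 2, 0.]]),
        ]
        rim = weight_difference(group_mean(cases), group_mean(controls),
                                vocab(3), 2, 2)
        expected = np.array([[0, 2, -1], [2, 0, 0], [-1, 0, 0.]])
        assert np.allclose(rim.W, expected)

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            weight_difference(np.zeros((2, 2)), np.zeros((3, 3)), vocab(2), 1, 1)


class TestTopK:
    def test_single_nonzero_pair(self):
        W = np.zeros((4, 4))
        W[1, 2] = W[2, 1] = 0.7
        from claimgraph.relations import RelationImportanceMatrix

        rim = RelationImportanceMatrix(W, vocab(4), 1, 1)
        top = top_k_relations(rim, 1, "positive")
        assert (top[0].category_i, top[0].category_j) == ("K1", "K2")
        assert top[0].rank == 1

    def test_matches_enumeration_oracle(self, rng):
        from claimgraph.relations import RelationImportanceMatrix

        W = symmetrize(rng.standard_normal((10, 10)))
        np.fill_diagonal(W, 0)
        rim = RelationImportanceMatrix(W, vocab(10), 1, 1)
        for sign, reverse in (("positive", True), ("negative", False)):
            got = top_k_relations(rim, 5, sign)
            pairs = sorted(
                ((W[i, j], f"K{i}", f"K{j}") for i in range(10)
                 for j in range(i + 1, 10)),
                key=lambda t: -t[0] if reverse else t[0],
            )
            assert [(r.category_i, r.category_j) for r in got] == [
                (p[1], p[2]) for p in pairs[:5]
            ]

    def test_all_zero_flagged(self):
        from claimgraph.relations import RelationImportanceMatrix, ranked_table

        rim = RelationImportanceMatrix(np.zeros((3, 3)), vocab(3), 1, 1)
        table = ranked_table(rim, k=2)
        assert table["no_effect"].all()

    def test_k_too_large_returns_all(self):
        from claimgraph.relations import RelationImportanceMatrix

        rim = RelationImportanceMatrix(np.zeros((3, 3)), vocab(3), 1, 1)
        with pytest.warns(UserWarning):
            assert len(top_k_relations(rim, 99)) == 3


def random_edge_weights(rng, n_vocab, n_patients, label_prefix):
    out = []
    for i in range(n_patients):
        size = int(rng.integers(2, n_vocab + 1))
        positions = sorted(rng.choice(n_vocab, size=size, replace=False).tolist())
        A = rng.random((size, size))
        np.fill_diagonal(A, 0)
        out.append(EdgeWeightMatrix(f"{label_prefix}{i}", A, positions))
    return out


class TestPipelineProperties:
    def _naive_reference(self, edge_weights, labels, n_vocab):
        """Triple-loop re-computation of W, independent of the pipeline."""
        sums = {1: np.zeros((n_vocab, n_vocab)), 0: np.zeros((n_vocab, n_vocab))}
        counts = {1: 0, 0: 0}
        for ewm in edge_weights:
            lbl = labels[ewm.patient_id]
            counts[lbl] += 1
            n = len(ewm.vocab_positions)
            for i in range(n):
                for j in range(n):
                    p = ewm.vocab_positions[i]
                    q = ewm.vocab_positions[j]
                    sums[lbl][p, q] += (ewm.matrix[i, j] + ewm.matrix[j, i]) / 2
        return sums[1] / counts[1] - sums[0] / counts[0]

    def test_equivalence_on_random_instances(self, rng):
        for _ in range(60):
            n_vocab = int(rng.integers(2, 7))
            cases = random_edge_weights(rng, n_vocab, int(rng.integers(1, 9)), "c")
            ctrls = random_edge_weights(rng, n_vocab, int(rng.integers(1, 9)), "k")
            labels = {e.patient_id: 1 for e in cases}
            labels.update({e.patient_id: 0 for e in ctrls})
            rim = relation_importance(cases + ctrls, labels, vocab(n_vocab))
            ref = self._naive_reference(cases + ctrls, labels, n_vocab)
            assert np.allclose(rim.W, ref, atol=1e-12)

    def test_scale_equivariance(self, rng):
        n_vocab = 5
        ews = random_edge_weights(rng, n_vocab, 6, "c") + \
            random_edge_weights(rng, n_vocab, 6, "k")
        labels = {e.patient_id: 1 if e.patient_id[0] == "c" else 0 for e in ews}
        w1 = relation_importance(ews, labels, vocab(n_vocab)).W
        scaled = [EdgeWeightMatrix(e.patient_id, 3.5 * e.matrix,
                                   e.vocab_positions) for e in ews]
        w2 = relation_importance(scaled, labels, vocab(n_vocab)).W
        assert np.allclose(w2, 3.5 * w1)

    def test_group_swap_antisymmetry_end_to_end(self, rng):
        n_vocab = 4
        ews = random_edge_weights(rng, n_vocab, 5, "c") + \
            random_edge_weights(rng, n_vocab, 5, "k")
        labels = {e.patient_id: 1 if e.patient_id[0] == "c" else 0 for e in ews}
        flipped = {pid: 1 - lbl for pid, lbl in labels.items()}
        w1 = relation_importance(ews, labels, vocab(n_vocab)).W
        w2 = relation_importance(ews, flipped, vocab(n_vocab)).W
        assert np.allclose(w1, -w2)

    def test_conditional_mean_option(self, rng):
        n_vocab = 4
        ews = random_edge_weights(rng, n_vocab, 5, "c") + \
            random_edge_weights(rng, n_vocab, 5, "k")
        labels = {e.patient_id: 1 if e.patient_id[0] == "c" else 0 for e in ews}
        w_full = relation_importance(ews, labels, vocab(n_vocab)).W
        w_cond = relation_importance(ews, labels, vocab(n_vocab),
                                     conditional_mean=True).W
        assert w_cond.shape == w_full.shape
        assert np.allclose(w_cond, w_cond.T)
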