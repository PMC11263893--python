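import datetime as dt

import numpy as np
import pytest

from claimgraph.cohort import LabeledPatient
from claimgraph.io import MonthBucket
from claimgraph.mapping import Vocabulary
from claimgraph.model import (VGNN, EdgeWeightMatrix, ModelConfig, PatientGraph,
                              build_patient_graph, combined_loss)
from claimgraph.nn import Tensor


def vocab5():
    return Vocabulary([(f"K{i}", "diagnosis", f"cat {i}") for i in range(5)])


def labeled(months, pid="P", label=0):
    buckets = [
        MonthBucket((2019, i + 1), frozenset((c, "diagnosis") for c in codes))
        for i, codes in enumerate(months)
    ]
    return LabeledPatient(pid, label, dt.date(2019, 12, 1), dt.date(2019, 6, 1),
                          buckets, 75, "F")


def tiny_model(vocab_size=5, dim=4, seed=0, **kw):
    cfg = ModelConfig(embed_dim=dim, rng_seed=seed, dropout=kw.pop("dropout", 0.0),
                      **kw)
    return VGNN(vocab_size, cfg)


class TestBuildGraph:
    def test_union_over_months(self):
        p = labeled([["K0", "K1", "K2"], ["K1", "K3"]])
        g = build_patient_graph(p, vocab5())
        assert g.nodes == [0, 1, 2, 3]
        n = g.n_code_nodes
        assert n * (n - 1) == 12  # complete digraph over code nodes

    def test_single_month(self):
        g = build_patient_graph(labeled([["K0", "K1", "K2"]]), vocab5())
        assert g.n_code_nodes == 3 and g.n_nodes == 4

    def test_node_order_stable(self):
        p1 = labeled([["K3", "K1"], ["K0"]])
        p2 = labeled([["K0"], ["K1", "K3"]])
        assert build_patient_graph(p1, vocab5()).nodes == \
            build_patient_graph(p2, vocab5()).nodes

    def test_fewer_than_two_nodes_rejected(self):
        with pytest.raises(ValueError):
            build_patient_graph(labeled([["K0"]]), vocab5())


class TestEncode:
    def test_uniform_attention_when_scores_zero(self):
        m = tiny_model()
        for k in ("a_src0", "a_dst0", "a_src1", "a_dst1"):
            m.params[k].data[:] = 0.0
        g = PatientGraph("P", 0, [0, 2, 4])
        idx, mask, vpos = m._pad([g])
        N = idx.shape[1]
        valid = mask[:, :, None] & mask[:, None, :] & ~np.eye(N, dtype=bool)
        h = Tensor(m.params["embed"].data[idx])
        alpha, _ = m._attention(h, m.params["W0"], m.params["a_src0"],
                                m.params["a_dst0"], valid)
        expected = np.where(valid[0], 1.0 / (N - 1), 0.0)
        assert np.allclose(alpha.data[0], expected)

    def test_three_node_forward_matches_loop_oracle(self):
        m = tiny_model(dim=3, seed=2)
        g = PatientGraph("P", 0, [1, 3])  # 2 code nodes + virtual = 3 nodes
        states = m.encode(g)

        # independent step-by-step re-computation with explicit loops
        def leaky(x):
            return np.where(x > 0, x, 0.2 * x)

        def elu(x):
            return np.where(x > 0, x, np.exp(x) - 1)

        h = np.stack([m.params["embed"].data[i] for i in (1, 3, 5)])
        for layer in (0, 1):
            W = m.params[f"W{layer}"].data
            a_s = m.params[f"a_src{layer}"].data[:, 0]
            a_d = m.params[f"a_dst{layer}"].data[:, 0]
            Wh = np.stack([W.T @ h[i] for i in range(3)])
            new = np.zeros_like(h)
            for i in range(3):
                scores = {}
                for j in range(3):
                    if j != i:
                        scores[j] = leaky(a_s @ Wh[i] + a_d @ Wh[j])
                zmax = max(scores.values())
                exps = {j: np.exp(s - zmax) for j, s in scores.items()}
                total = sum(exps.values())
                agg = sum(exps[j] / total * Wh[j] for j in scores)
                new[i] = elu(agg) + h[i]
            h = new
        assert np.allclose(states, h, atol=1e-12)

    def test_permutation_equivariance(self):
        m = tiny_model(dim=6, seed=1)
        nodes = [0, 2, 3]
        perm = [1, 2, 0]  # reorder code nodes, virtual stays last
        idx1 = np.array([[0, 2, 3, 5]])
        idx2 = np.array([[2, 3, 0, 5]])
        mask = np.ones((1, 4), dtype=bool)
        vpos = np.array([3])
        out1 = m._forward(idx1, mask, vpos)
        out2 = m._forward(idx2, mask, vpos)
        full_perm = perm + [3]
        assert np.allclose(out1["states"].data[0][full_perm],
                           out2["states"].data[0], atol=1e-10)
        A1 = out1["A"].data[0]
        A2 = out2["A"].data[0]
        assert np.allclose(A1[np.ix_(full_perm, full_perm)], A2, atol=1e-10)
        assert np.isclose(out1["prob"].data[0], out2["prob"].data[0])


class TestVariational:
    def test_standard_normal_kl_zero(self):
        m = tiny_model(dim=2)
        m.params["W_mu"].data[:] = 0; m.params["b_mu"].data[:] = 0
        m.params["W_lv"].data[:] = 0; m.params["b_lv"].data[:] = 0
        _, kl = m.variational(np.ones((3, 2)))
        assert kl == 0.0

    def test_single_node_unit_mean_kl_half(self):
        m = tiny_model(vocab_size=2, dim=1)
        m.params["W_mu"].data[:] = 0; m.params["b_mu"].data[:] = 1.0
        m.params["W_lv"].data[:] = 0; m.params["b_lv"].data[:] = 0.0
        _, kl = m.variational(np.zeros((1, 1)))
        assert np.isclose(kl, 0.5)

    def test_closed_form_matches_monte_carlo(self, rng):
        mu = rng.normal(size=4)
        logvar = rng.normal(scale=0.5, size=4)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * rng.standard_normal((100_000, 4))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi) + logvar)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi))
        mc = (log_q - log_p).sum(axis=1).mean()
        closed = 0.5 * np.sum(mu**2 + sigma**2 - logvar - 1.0)
        assert abs(mc - closed) / abs(closed) < 0.02

    def test_eval_mode_returns_mu(self):
        m = tiny_model(dim=3)
        states = np.random.default_rng(1).normal(size=(4, 3))
        z1, _ = m.variational(states, mode="eval")
        z2, _ = m.variational(states, mode="eval")
        assert np.array_equal(z1, z2)


class TestDecodeAndPredict:
    def graph(self):
        return PatientGraph("P", 1, [0, 1, 3, 4])

    def test_edge_rows_sum_to_one(self):
        m = tiny_model()
        idx, mask, vpos = m._pad([self.graph()])
        out = m._forward(idx, mask, vpos)
        A = out["A"].data[0]
        assert np.allclose(A.sum(axis=1), 1.0)

    def test_zero_diagonal(self):
        m = tiny_model()
        ewm = m.extract_edge_weights(self.graph())
        assert np.all(np.diag(ewm.matrix) == 0)

    def test_weights_non_negative(self):
        m = tiny_model()
        assert np.all(m.extract_edge_weights(self.graph()).matrix >= 0)

    def test_extract_dimension_and_determinism(self):
        m = tiny_model()
        e1 = m.extract_edge_weights(self.graph())
        e2 = m.extract_edge_weights(self.graph())
        assert e1.matrix.shape == (4, 4)
        assert np.array_equal(e1.matrix, e2.matrix)
        assert e1.vocab_positions == [0, 1, 3, 4]

    def test_zero_output_weights_give_half(self):
        m = tiny_model()
        m.params["w_out"].data[:] = 0.0
        m.params["b_out"].data[:] = 0.0
        assert m.predict_proba(self.graph()) == 0.5

    def test_eval_repeat_bit_identical(self):
        m = tiny_model(seed=5)
        p1 = m.predict_proba(self.graph())
        p2 = m.predict_proba(self.graph())
        assert p1 == p2
        assert 0.0 < p1 < 1.0


class TestLoss:
    def test_log2_at_half(self):
        assert np.isclose(combined_loss(0.5, 1, 0.0, 0.002), np.log(2))

    def test_lambda_zero_is_pure_bce(self):
        assert np.isclose(combined_loss(0.8, 0, 123.0, 0.0), -np.log(0.2))

    def test_arithmetic_example(self):
        # -log 0.9 + 0.002 * 10
        assert np.isclose(combined_loss(0.9, 1, 10.0, 0.002),
                          -np.log(0.9) + 0.02)

    def test_rejects_boundary_probability(self):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1, 0.0, 0.002)


def separable_graphs(n=80, seed=0):
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n):
        label = i % 2
        nodes = set(rng.choice(np.arange(1, 6), size=3, replace=False).tolist())
        if label:
            nodes.add(0)
        graphs.append(PatientGraph(str(i), label, sorted(nodes)))
    return graphs


class TestTraining:
    def test_loss_decreases_on_strong_signal(self):
        graphs = separable_graphs()
        m = VGNN(6, ModelConfig(embed_dim=8, epochs=20, learning_rate=0.01,
                                rng_seed=0))
        m.fit(graphs)
        assert m.training_log[19]["total"] < m.training_log[0]["total"]
        assert len(m.training_log) == 20

    def test_same_seed_identical_final_loss(self):
        graphs = separable_graphs()
        cfg = dict(embed_dim=8, epochs=5, learning_rate=0.01, rng_seed=42)
        m1 = VGNN(6, ModelConfig(**cfg)).fit(graphs)
        m2 = VGNN(6, ModelConfig(**cfg)).fit(graphs)
        assert m1.training_log[-1]["total"] == m2.training_log[-1]["total"]

    def test_large_kl_weight_shrinks_means(self):
        graphs = separable_graphs()
        norms = {}
        for lam in (0.002, 10.0):
            m = VGNN(6, ModelConfig(embed_dim=8, epochs=30, learning_rate=0.01,
                                    kl_weight=lam, rng_seed=0))
            m.fit(graphs)
            idx, mask, vpos = m._pad(graphs[:32])
            out = m._forward(idx, mask, vpos)
            mu = out["mu"].data[mask]
            norms[lam] = float(np.linalg.norm(mu, axis=1).mean())
        assert norms[10.0] < norms[0.002]

    def test_save_load_round_trip(self, tmp_path):
        graphs = separable_graphs()
        m = VGNN(6, ModelConfig(embed_dim=8, epochs=2, rng_seed=0)).fit(graphs)
        m.save(tmp_path / "ck.npz", tmp_path / "cfg.json")
        again = VGNN.load(tmp_path / "ck.npz", tmp_path / "cfg.json")
        g = graphs[0]
        assert again.predict_proba(g) == m.predict_proba(g)


class TestGradientCheck:
    def test_full_model_matches_finite_differences(self):
        m = tiny_model(vocab_size=3, dim=3, seed=1)
        g = PatientGraph("P", 1, [0, 2])  # 3 nodes with virtual
        idx, mask, vpos = m._pad([g])
        labels = np.array([1.0])
        eps = np.random.default_rng(9).standard_normal((1, 3, 3))

        def loss_value():
            out = m._forward(idx, mask, vpos, labels=labels, training=True,
                             eps=eps)
            return float(out["loss"].data)

        out = m._forward(idx, mask, vpos, labels=labels, training=True, eps=eps)
        for p in m.params.values():
            p.grad = None
        out["loss"].backward()
        h = 1e-6
        for name, p in m.params.items():
            analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                fp = loss_value()
                flat[i] = orig - h
                fm = loss_value()
                flat[i] = orig
                num = (fp - fm) / (2 * h)
                ana = analytic.reshape(-1)[i]
                denom = max(abs(num), abs(ana), 1e-8)
                if abs(num) > 1e-10 or abs(ana) > 1e-10:
                    assert abs(num - ana) / denom < 1e-4, (name, i, num, ana)
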