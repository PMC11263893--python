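"""Variationally regularized encoder-decoder graph attention classifier.

Each patient is a fully connected directed graph over the rolled-up code
categories seen in their feature window, plus one virtual readout node.
Two additive-attention encoder layers update node states; per-node Gaussian
heads regularize them toward a standard normal (closed-form KL penalty); a
decoder attention pass yields normalized edge weights — the raw material of
the relation-importance explanation — and the virtual node's final state
feeds a sigmoid output layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cohort import LabeledPatient
from .mapping import Vocabulary
from .nn import Tensor


@dataclass
class ModelConfig:
    embed_dim: int = 64
    n_graph_layers: int = 2
    n_heads: int = 1
    dropout: float = 0.1
    kl_weight: float = 0.002
    learning_rate: float = 0.0001
    batch_size: int = 128
    epochs: int = 200
    optimizer: str = "adam"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embed_dim, self.n_graph_layers, self.batch_size, self.epochs) <= 0:
            raise ValueError("config values must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


@dataclass
class PatientGraph:
    """Node list in vocabulary order plus an appended virtual readout node."""

    patient_id: str
    label: int
    nodes: list[int]  # vocabulary positions of code nodes (sorted, unique)

    @property
    def n_code_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:  # including the virtual node
        return len(self.nodes) + 1


@dataclass
class EdgeWeightMatrix:
    patient_id: str
    matrix: np.ndarray  # code nodes only, rows ~ attention over out-edges
    vocab_positions: list[int]


def build_patient_graph(patient: LabeledPatient, vocab: Vocabulary) -> PatientGraph:
    """Union of mapped categories over all feature months, in vocab order."""
    positions = sorted(
        {vocab.index[code] for b in patient.feature_months for code, _t in b.codes}
    )
    if len(positions) < 2:
        raise ValueError(f"patient {patient.patient_id}: fewer than 2 code nodes")
    return PatientGraph(patient.patient_id, patient.label, positions)


def combined_loss(p: float, label: int, kl_total: float, lam: float) -> float:
    """BCE(p, y) + lambda * KL  for a single prediction."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must be in (0,1)")
    bce = -(label * np.log(p) + (1 - label) * np.log(1.0 - p))
    return float(bce + lam * kl_total)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape[-2:]) if len(shape) > 1 else shape[0] + 1
    scale = np.sqrt(6.0 / fan)
    return rng.uniform(-scale, scale, size=shape)


class VGNN:
    """The four-module model: encoder graph, variational regularization,
    decoder graph and a fully connected output layer."""

    def __init__(self, vocab_size: int, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.vocab_size = vocab_size
        self.virtual_index = vocab_size  # embedding row |V| is the virtual node
        d = self.config.embed_dim
        rng = np.random.default_rng(self.config.rng_seed)
        p: dict[str, Tensor] = {}
        p["embed"] = Tensor(_glorot(rng, (vocab_size + 1, d)), requires_grad=True)
        for layer in range(self.config.n_graph_layers):
            p[f"W{layer}"] = Tensor(_glorot(rng, (d, d)), requires_grad=True)
            p[f"a_src{layer}"] = Tensor(_glorot(rng, (d, 1)), requires_grad=True)
            p[f"a_dst{layer}"] = Tensor(_glorot(rng, (d, 1)), requires_grad=True)
        p["W_mu"] = Tensor(_glorot(rng, (d, d)), requires_grad=True)
        p["b_mu"] = Tensor(np.zeros(d), requires_grad=True)
        p["W_lv"] = Tensor(_glorot(rng, (d, d)), requires_grad=True)
        # start with small sampling noise so early gradients are not drowned
        p["b_lv"] = Tensor(np.full(d, -4.0), requires_grad=True)
        p["W_dec"] = Tensor(_glorot(rng, (d, d)), requires_grad=True)
        p["a_dec_src"] = Tensor(_glorot(rng, (d, 1)), requires_grad=True)
        p["a_dec_dst"] = Tensor(_glorot(rng, (d, 1)), requires_grad=True)
        p["w_out"] = Tensor(_glorot(rng, (d, 1)), requires_grad=True)
        p["b_out"] = Tensor(np.zeros(1), requires_grad=True)
        self.params = p
        self.training_log: list[dict[str, float]] = []

    # -- batching ----------------------------------------------------------
    def _pad(self, graphs: list[PatientGraph]):
        n_max = max(g.n_nodes for g in graphs)
        B = len(graphs)
        idx = np.zeros((B, n_max), dtype=np.int64)
        mask = np.zeros((B, n_max), dtype=bool)
        vpos = np.zeros(B, dtype=np.int64)
        for b, g in enumerate(graphs):
            idx[b, : g.n_code_nodes] = g.nodes
            idx[b, g.n_code_nodes] = self.virtual_index
            mask[b, : g.n_nodes] = True
            vpos[b] = g.n_nodes - 1
        return idx, mask, vpos

    def _attention(self, h: Tensor, W: Tensor, a_src: Tensor, a_dst: Tensor,
                   valid: np.ndarray) -> tuple[Tensor, Tensor]:
        """One additive-attention pass; returns (alpha, Wh).

        score(i->j) = LeakyReLU(a_src^T Wh_i + a_dst^T Wh_j), rows of alpha
        normalized by softmax over each node's neighborhood.
        """
        Wh = h @ W  # (B,N,d)
        s = Wh @ a_src  # (B,N,1)
        t = Wh @ a_dst
        e = nn.leaky_relu(s + nn.swap_last2(t), slope=0.2)  # (B,N,N)
        alpha = nn.masked_softmax(e, valid)
        return alpha, Wh

    def _forward(
        self,
        idx: np.ndarray,
        mask: np.ndarray,
        vpos: np.ndarray,
        labels: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        eps: np.ndarray | None = None,
    ) -> dict:
        cfg = self.config
        B, N = idx.shape
        valid = mask[:, :, None] & mask[:, None, :] & ~np.eye(N, dtype=bool)

        h = nn.gather_rows(self.params["embed"], idx)  # (B,N,d)
        for layer in range(cfg.n_graph_layers):
            alpha, Wh = self._attention(
                h, self.params[f"W{layer}"], self.params[f"a_src{layer}"],
                self.params[f"a_dst{layer}"], valid,
            )
            # residual keeps each node's own identity alongside its
            # neighborhood aggregate (there are no self-edges)
            h = nn.elu(alpha @ Wh) + h
            if training and cfg.dropout > 0 and rng is not None:
                h = nn.dropout(h, cfg.dropout, rng)

        mu = h @ self.params["W_mu"] + self.params["b_mu"]
        logvar = h @ self.params["W_lv"] + self.params["b_lv"]
        m3 = Tensor(mask[:, :, None].astype(float))
        var = nn.exp(logvar)
        kl_terms = (mu * mu + var - logvar - 1.0) * m3
        kl = nn.tsum(nn.tsum(kl_terms, axis=2), axis=1) * 0.5  # (B,)

        if training:
            if eps is None:
                eps = rng.standard_normal(mu.shape)
            z = mu + nn.exp(logvar * 0.5) * Tensor(eps)
        else:
            z = mu

        A, Wz = self._attention(
            z, self.params["W_dec"], self.params["a_dec_src"],
            self.params["a_dec_dst"], valid,
        )
        hdec = nn.elu(A @ Wz) + z
        g = nn.select_rows(hdec, np.arange(B), vpos)  # (B,d)
        logits = nn.tsum(g @ self.params["w_out"], axis=1) + self.params["b_out"]
        prob = nn.sigmoid(logits)

        out = {"mu": mu, "logvar": logvar, "kl": kl, "A": A, "z": z,
               "states": hdec, "graph_repr": g, "logits": logits, "prob": prob}
        if labels is not None:
            bce = nn.bce_with_logits(logits, labels.astype(float))
            out["bce"] = bce
            out["loss"] = nn.mean(bce + kl * cfg.kl_weight)
        return out

    # -- public operations -------------------------------------------------
    def encode(self, graph: PatientGraph) -> np.ndarray:
        """Eval-mode encoder states for one graph (code + virtual nodes)."""
        idx, mask, vpos = self._pad([graph])
        cfg = self.config
        valid = mask[:, :, None] & mask[:, None, :] & ~np.eye(mask.shape[1], dtype=bool)
        h = nn.gather_rows(self.params["embed"], idx)
        for layer in range(cfg.n_graph_layers):
            alpha, Wh = self._attention(
                h, self.params[f"W{layer}"], self.params[f"a_src{layer}"],
                self.params[f"a_dst{layer}"], valid,
            )
            h = nn.elu(alpha @ Wh) + h
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError("non-finite encoder states")
        return h.data[0]

    def variational(
        self,
        states: np.ndarray,
        rng: np.random.Generator | None = None,
        mode: str = "eval",
    ) -> tuple[np.ndarray, float]:
        """Gaussian heads over node states; returns (sampled states, KL)."""
        h = Tensor(states)
        mu = (h @ self.params["W_mu"] + self.params["b_mu"]).data
        logvar = (h @ self.params["W_lv"] + self.params["b_lv"]).data
        kl = 0.5 * float(np.sum(mu**2 + np.exp(logvar) - logvar - 1.0))
        if mode == "train":
            eps = (rng or np.random.default_rng()).standard_normal(mu.shape)
            return mu + np.exp(0.5 * logvar) * eps, kl
        return mu, kl

    def predict_proba(self, graph: PatientGraph) -> float:
        """Deterministic eval-mode probability of case status."""
        idx, mask, vpos = self._pad([graph])
        out = self._forward(idx, mask, vpos, training=False)
        return float(out["prob"].data[0])

    def predict_proba_many(self, graphs: list[PatientGraph],
                           batch_size: int = 256) -> np.ndarray:
        probs = np.empty(len(graphs))
        for lo in range(0, len(graphs), batch_size):
            chunk = graphs[lo : lo + batch_size]
            idx, mask, vpos = self._pad(chunk)
            out = self._forward(idx, mask, vpos, training=False)
            probs[lo : lo + len(chunk)] = out["prob"].data
        return probs

    def extract_edge_weights(self, graph: PatientGraph) -> EdgeWeightMatrix:
        """Eval-mode decoder attention, virtual node rows/cols removed."""
        idx, mask, vpos = self._pad([graph])
        out = self._forward(idx, mask, vpos, training=False)
        n = graph.n_code_nodes
        A = out["A"].data[0][:n, :n].copy()
        return EdgeWeightMatrix(graph.patient_id, A, list(graph.nodes))

    def fit(self, graphs: list[PatientGraph], verbose: bool = False) -> "VGNN":
        """Seeded mini-batch Adam training on labeled graphs."""
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed + 1)
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        labels = np.array([g.label for g in graphs], dtype=float)
        order = np.arange(len(graphs))
        for epoch in range(cfg.epochs):
            rng.shuffle(order)
            ep_bce = ep_kl = ep_total = 0.0
            n_batches = 0
            for lo in range(0, len(graphs), cfg.batch_size):
                sel = order[lo : lo + cfg.batch_size]
                batch = [graphs[i] for i in sel]
                idx, mask, vpos = self._pad(batch)
                out = self._forward(
                    idx, mask, vpos, labels=labels[sel], training=True, rng=rng
                )
                loss = out["loss"]
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"NaN loss at epoch {epoch}, batch {n_batches}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_bce += float(out["bce"].data.mean())
                ep_kl += float(out["kl"].data.mean())
                ep_total += float(loss.data)
                n_batches += 1
            entry = {
                "epoch": epoch,
                "bce": ep_bce / n_batches,
                "kl": ep_kl / n_batches,
                "total": ep_total / n_batches,
            }
            self.training_log.append(entry)
            if verbose and epoch % 10 == 0:
                print(f"epoch {epoch}: total={entry['total']:.4f}")
        return self

    # -- persistence -------------------------------------------------------
    def save(self, checkpoint: str | Path, config_path: str | Path) -> None:
        np.savez(checkpoint, **{k: v.data for k, v in self.params.items()},
                 vocab_size=np.array(self.vocab_size))
        Path(config_path).write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, checkpoint: str | Path, config_path: str | Path) -> "VGNN":
        cfg = ModelConfig(**json.loads(Path(config_path).read_text()))
        data = np.load(checkpoint if str(checkpoint).endswith(".npz")
                       else str(checkpoint) + ".npz")
        model = cls(int(data["vocab_size"]), cfg)
        for k in model.params:
            model.params[k] = Tensor(data[k], requires_grad=True)
        return model
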