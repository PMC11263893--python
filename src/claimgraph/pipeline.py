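"""End-to-end orchestration: cohort -> mapping -> split/match -> models ->
relation importance.  Shared by the CLI, the test suite and the acceptance
script."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines as bl
from .cohort import (CaseDefinition, ScenarioCohort, ScenarioConfig,
                     apply_eligibility, build_scenario_cohort)
from .mapping import MappingTable, Vocabulary, map_cohort
from .matching import MatchedCohort, holdout_split, make_subset, propensity_match
from .model import VGNN, ModelConfig, build_patient_graph
from .relations import RelationImportanceMatrix, relation_importance
from .synth import timelines_from_frames


@dataclass
class ScenarioData:
    cohort: ScenarioCohort  # mapped
    vocab: Vocabulary
    test_ids: set[str]
    matched: MatchedCohort
    subset: MatchedCohort
    reports: dict = field(default_factory=dict)

    def patients_by_id(self):
        return {p.patient_id: p for p in self.cohort.patients}


def prepare_scenario(
    claims: pd.DataFrame,
    demo: pd.DataFrame,
    mapping: MappingTable,
    scenario_id: int,
    seed: int,
    case_def: CaseDefinition | None = None,
    subset_fraction: float = 0.10,
    test_fraction: float = 0.20,
    caliper: float | str | None = None,
) -> ScenarioData:
    """Run preprocessing through matching for one scenario."""
    case_def = case_def or CaseDefinition()
    timelines = timelines_from_frames(claims, demo)
    eligible, excl = apply_eligibility(timelines, case_def)
    scenario = ScenarioConfig.for_scenario(scenario_id, rng_seed=seed)
    cohort = build_scenario_cohort(eligible, case_def, scenario)
    mapped, vocab, map_report = map_cohort(cohort, mapping)

    rng = np.random.default_rng(seed)
    split = holdout_split(mapped, fraction=test_fraction, rng=rng)
    by_id = {p.patient_id: p for p in mapped.patients}
    pool = [by_id[pid] for pid in sorted(split.train_pool_ids)]
    matched = propensity_match(pool, rng=rng, caliper=caliper)
    subset = make_subset(matched, fraction=subset_fraction, rng=rng)
    return ScenarioData(
        mapped, vocab, split.test_ids, matched, subset,
        reports={"eligibility": excl, "cohort": cohort.exclusion_report,
                 "mapping": map_report},
    )


def _graphs_for(data: ScenarioData, ids: list[str]):
    by_id = data.patients_by_id()
    graphs, kept = [], []
    for pid in ids:
        try:
            graphs.append(build_patient_graph(by_id[pid], data.vocab))
            kept.append(pid)
        except ValueError:  # fewer than 2 mapped code nodes
            continue
    return graphs, kept


def train_vgnn(
    data: ScenarioData, cohort_name: str = "matched",
    config: ModelConfig | None = None,
) -> VGNN:
    matched = data.matched if cohort_name == "matched" else data.subset
    graphs, _ = _graphs_for(data, matched.patient_ids)
    model = VGNN(len(data.vocab), config or ModelConfig())
    model.fit(graphs)
    return model


def evaluate_on_test(data: ScenarioData, model) -> float:
    """AUROC of a model on the reserved natural-mix test set."""
    by_id = data.patients_by_id()
    test_ids = sorted(data.test_ids)
    if isinstance(model, VGNN):
        graphs, kept = _graphs_for(data, test_ids)
        scores = model.predict_proba_many(graphs)
        labels = np.array([by_id[p].label for p in kept])
    else:  # sklearn-style classifier on occurrence features
        patients = [by_id[p] for p in test_ids]
        table = bl.build_feature_table(patients, data.vocab)
        scores = model.predict_proba(table.matrix)[:, 1]
        labels = table.labels
    return bl.evaluate_auroc(scores, labels)


def train_baseline(data: ScenarioData, which: str, cohort_name: str, seed: int):
    matched = data.matched if cohort_name == "matched" else data.subset
    by_id = data.patients_by_id()
    patients = [by_id[pid] for pid in matched.patient_ids]
    table = bl.build_feature_table(patients, data.vocab)
    return bl.fit_baseline(table, which, seed=seed)


def explain(data: ScenarioData, model: VGNN,
            conditional_mean: bool = False) -> RelationImportanceMatrix:
    """Relation-importance matrix from the matched training cohort."""
    by_id = data.patients_by_id()
    graphs, kept = _graphs_for(data, data.matched.patient_ids)
    edge_weights = [model.extract_edge_weights(g) for g in graphs]
    labels = {pid: by_id[pid].label for pid in kept}
    return relation_importance(edge_weights, labels, data.vocab,
                               conditional_mean=conditional_mean)


def run_grid(
    claims: pd.DataFrame,
    demo: pd.DataFrame,
    mapping: MappingTable,
    scenario_ids: list[int],
    seed: int,
    model_config: ModelConfig | None = None,
    top_k: int = 5,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """The scenario x {matched, subset} x {vgnn, rf, lgbm} AUROC grid plus
    per-scenario ranked relation tables."""
    from .relations import ranked_table

    rows = []
    relation_tables: dict[int, pd.DataFrame] = {}
    for sid in scenario_ids:
        data = prepare_scenario(claims, demo, mapping, sid, seed)
        for cohort_name in ("matched", "subset"):
            cfg = model_config or ModelConfig()
            cfg = ModelConfig(**{**vars(cfg), "rng_seed": seed + sid})
            vgnn = train_vgnn(data, cohort_name, cfg)
            rows.append(
                {
                    "scenario": sid, "cohort": cohort_name, "model": "vgnn",
                    "auroc": evaluate_on_test(data, vgnn),
                    "n_test": len(data.test_ids),
                }
            )
            if cohort_name == "matched":
                relation_tables[sid] = ranked_table(explain(data, vgnn), k=top_k)
            for which in bl.BASELINES:
                clf = train_baseline(data, which, cohort_name, seed=seed + sid)
                rows.append(
                    {
                        "scenario": sid, "cohort": cohort_name, "model": which,
                        "auroc": evaluate_on_test(data, clf),
                        "n_test": len(data.test_ids),
                    }
                )
    return pd.DataFrame(rows), relation_tables
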