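# claimgraph

Self-explainable graph-attention risk prediction on medical-claims code
graphs, with a relation-importance method that explains *which code-pair
relationships* drive the prediction.

The pipeline targets dementia (ADRD) risk prediction from administrative
claims: cohort construction with index-date windowing, rollup of raw codes
to compact CCS-/AHFS-style categories, 1:1 age/gender propensity matching,
a variationally regularized encoder–decoder graph attention classifier over
per-patient fully connected code graphs, tree-ensemble baselines, and a
case-vs-control mean weight-difference matrix ranking code-pair relations.
A synthetic claims generator with planted co-occurrence signal makes every
stage testable without access to any real claims data.

## Components

| Module | Purpose |
| --- | --- |
| `claimgraph.io` | Read/validate/month-group claims + demographics tables |
| `claimgraph.cohort` | Eligibility filters, case classification, index-day sampling, scenario cohorts |
| `claimgraph.mapping` | Longest-prefix rollup of raw codes to category vocabularies |
| `claimgraph.matching` | 20% test hold-out, 1:1 propensity matching (age, gender), 10% subset cohort |
| `claimgraph.nn` | Minimal reverse-mode autodiff over numpy (float64) |
| `claimgraph.model` | The graph model: 2 attention encoder layers, per-node Gaussian regularization (KL to standard normal), decoder attention producing edge weights, sigmoid readout |
| `claimgraph.relations` | Symmetrize → align → group means → weight difference → ranked relation pairs |
| `claimgraph.baselines` | Random forest + gradient-boosted trees on binary occurrence features; rank-formula AUROC |
| `claimgraph.synth` | Synthetic cohort generator with planted risk/protective pairs and block co-activation |
| `claimgraph.pipeline` / `claimgraph.cli` | End-to-end orchestration and command-line interface |

The model and its training loop are pure numpy (no deep-learning framework
required); gradients are exact reverse-mode and are finite-difference
checked in the test suite.  The gradient-boosting baseline uses
scikit-learn's `HistGradientBoostingClassifier` configured LightGBM-style
(300 trees, 31 leaves, learning rate 0.1).

## CLI

```bash
# generate a synthetic cohort with planted relational signal
claimgraph simulate --preset pair_interaction --seed 1 --outdir work/

# cohort -> mapping -> matching -> training -> explanation, per scenario
claimgraph build-cohort --claims work/claims.csv --demographics work/demographics.csv \
    --mappings work/mapping.csv --scenario 1 --seed 1 --outdir work/
claimgraph train   --claims work/claims.csv --demographics work/demographics.csv \
    --mappings work/mapping.csv --scenario 1 --seed 1 --outdir work/
claimgraph explain --claims work/claims.csv --demographics work/demographics.csv \
    --mappings work/mapping.csv --scenario 1 --seed 1 --outdir work/

# the full grid: 3 scenarios x {matched, subset} x {vgnn, rf, lgbm},
# plus per-scenario top-5 positive/negative relation tables
claimgraph full-run --claims work/claims.csv --demographics work/demographics.csv \
    --mappings work/mapping.csv --seed 1 --outdir work/
```

Scenarios 1–3 use index-selection/prediction windows of 1, 2 and 3 years
with a 3-year feature window.  Every command writes a JSON metadata sidecar
(seed, input digests) so artifacts are reproducible.  A user-editable case
definition (diagnosis wildcards + medication names) ships in
`examples/case_definition.tsv` and is passed with `--case-definition`.

Real claims data plugs in as two delimited tables (claims: patient_id,
service_date, code, code_type; demographics: patient_id, birth_year,
gender) plus a code-mapping table (code_type, source_pattern, category_id,
category_label).  Only a toy mapping ships; licensed CCS/AHFS crosswalks
drop in with the same format.

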