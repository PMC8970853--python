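# icuprior

Prior-distribution estimation for ICU-monitored variables.

The pipeline fits a per-patient multivariate Gaussian hidden Markov model
(Baum–Welch EM, scaled forward–backward smoothing, posterior decoding) to
vital-sign time series, validates the decoded hidden states against a
rule-based circulatory-failure label (MAP ≤ 65 mmHg, or vasoactive/inotropic
drugs present with lactate > 2 mmol/l) via per-patient AUC, tests the fitted
state-conditional emission parameters for association with basic clinical
covariates (Welch t-test for sex, correlation test for age/weight/height/BMI),
and forecasts those parameters as terminal-node quantile intervals of a
conditional inference tree, scored by coverage rate and relative interval
width on a held-out patient split.

Real ICU data is request-only, so the package ships a seeded synthetic-cohort
simulator (`icuprior.simulate`) with the same statistical structure:
covariate-dependent per-patient emission parameters, persistent two-state
Markov switching, and MAP/lactate/drug channels tied to the hidden state.

## Layout

| module | role |
| --- | --- |
| `icuprior.simulate` | synthetic cohorts with known ground truth |
| `icuprior.cohort` | data model, CSV I/O, rule labeler, patient filters |
| `icuprior.hmm` | Gaussian HMM: EM fitting, smoothing, state alignment |
| `icuprior.evaluate` | per-patient ROC/AUC of decoded states vs. rule labels |
| `icuprior.association` | parameter-vs-covariate significance table |
| `icuprior.tree` | p-value-guided conditional inference tree |
| `icuprior.forecast` | leaf quantile intervals, coverage and relative width |
| `icuprior.cli` | `icuprior` command-line interface and pipeline runner |

## CLI

Each stage is a subcommand exchanging plain CSV/JSON:

```bash
icuprior simulate --out data/ --seed 1 --n-patients 200
icuprior label    --series data/series.csv --out data/labels.csv
icuprior fit-hmm  --series data/series.csv --profiles data/profiles.csv \
                  --states 2 --seed 1 --out params.csv,posteriors.csv
icuprior evaluate --posteriors posteriors.csv --labels data/labels.csv --out auc.csv
icuprior test-assoc --params params.csv --profiles data/profiles.csv --out assoc.csv
icuprior tree     --params params.csv --profiles data/profiles.csv \
                  --response hr:mu:1 --alpha 0.1 --max-depth 5 --out tree.json
icuprior forecast --params params.csv --profiles data/profiles.csv \
                  --levels 0.5,0.8,0.84,0.95 --split-seed 1 --out curve.csv
```

or run everything from one config:

```bash
icuprior pipeline --config pipeline.yaml
```

```yaml
# pipeline.yaml
seed: 1
simulate: {n_patients: 200, t_range: [50, 150]}
hmm: {n_states: 2, emission: diagonal, restarts: 3}
association: {alpha: 0.01}
tree: {alpha: 0.1, max_depth: 5, min_leaf: 20}
forecast: {levels: [0.5, 0.8, 0.84, 0.95], split_seed: 1}
out_dir: pipeline_out
```

The pipeline writes `labels.csv`, `params.csv`, `posteriors.csv`, `auc.csv`
(+ histogram bins), `assoc.csv`, one `tree_*.json` per parameter response,
`curve.csv` / `curve_avg.csv`, and a `manifest.json` of content hashes;
identical configs produce byte-identical artifacts.

## Conventions

- States are 1-based in every file; after alignment, state 1 is the
  failure-aligned state (lower fitted mean on the reference variable, `map`
  by default).
- A nominal interval level `c` maps to symmetric quantile levels
  `((1-c)/2, (1+c)/2)`, so 80% → (0.1, 0.9); empirical quantiles use linear
  interpolation between order statistics.
- Relative interval width divides by the 0.95−0.05 quantile span of the
  training-set response column, making widths unit-free.
- Coverage/width curves are evaluated out-of-sample on a seeded 70/30
  patient-level split.

## Validation report

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline anchors from scratch: the perfect-ranking and
random-score AUC values, the 80% → 0.9 upper-quantile mapping, and the
held-out coverage (nominal 84%) and average relative width (nominal 80%)
of tree-based quantile intervals on seeded synthetic cohorts.
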