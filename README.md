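# bridgenet

Symptom-network analysis for ordinal questionnaire data: estimate a
regularized partial-correlation network over the items of two clinical
instruments, find the symptoms most central to the network, and find the
*bridge* symptoms that connect the two disorders' symptom clusters — with
bootstrap machinery to say how much of any of it you should believe.

The package is aimed at psychometric / psychiatric-epidemiology analyses
of the kind applied to eating-disorder (ED) and autism-trait (ASD)
questionnaires: ~100 respondents, 22 seven-point Likert items plus 65
four-point Likert items, a few reverse-coded items, and a sprinkle of
missing cells. Since item-level clinical data of this kind are typically
not shareable, a synthetic-data generator with known ground truth stands
in for them, and every stage of the pipeline is validated against that
ground truth.

## The model

Item responses are treated as monotone observations of a latent Gaussian
vector with sparse precision matrix Θ. The conditional-dependence network
is estimated by the graphical lasso,

maximize  log det Θ − tr(SΘ) − ρ Σ_{i≠j} |Θ_ij|,

where S is the (default Spearman) item correlation matrix and the L1
penalty ρ is chosen along a log-spaced path by minimizing the extended
BIC, −n(log det Θ − tr SΘ) + E log n + 4 E γ log p, with hyperparameter
γ = 0.25 by default (E = edge count). Edge weights are the regularized
partial correlations W_ij = −Θ_ij/√(Θ_ii Θ_jj).

On top of the network:

- **Expected influence**: EI1(i) = Σ_j W_ij and the two-step variant
  EI2(i) = EI1(i) + Σ_j W_ij·EI1(j) — signed centrality that keeps the
  direction of associations.
- **Bridge expected influence**: the same sums restricted to edges that
  cross the community partition (instrument membership), identifying the
  symptoms that link the two clusters. Z-scores are reported alongside.
- **Redundant-item screening**: before estimation, pairs of items whose
  correlation profiles with every other item are statistically
  indistinguishable (dependent-correlation tests sharing a variable, with
  a minimum inter-item correlation gate) are treated as duplicate
  measures of one construct and one member is dropped.
- **Bootstrap accuracy and stability**: nonparametric bootstrap CIs for
  edges, case-dropping bootstrap and the correlation-stability (CS)
  coefficient for centrality orders, and paired bootstrapped difference
  tests (α = 0.05) between nodes.

## Worked example

Run the bundled study-like preset (87 items, 101 respondents, 200
bootstrap replicates; about two minutes on one core):

```python
from bridgenet import study_like_config, run_pipeline

report = run_pipeline(study_like_config(seed=1, output_dir="demo_run"))
print(report.to_json())
```

Printed output (abridged):

```json
{
  "n": 101,
  "items_entered": 87,
  "items_retained": 75,
  "removed_items": ["ASD60", "ASD31", "..."],
  "selected_lambda": 0.5594,
  "gamma": 0.25,
  "edge_count": 4,
  "cs_ei": 0.5,
  "cs_bridge_ei": 0.0,
  "n_significant_ei_pairs": 0,
  "top_nodes": {"ei1": ["ASD33", "ASD01", "ASD02"], "...": ["..."]}
}
```

Reading it: the redundancy screen dropped 12 of 87 items as
near-duplicates; at n = 101 the EBIC-selected network keeps only 4 edges
(planted partial correlations of 0.2–0.4 are weak at this sample size, so
the penalized fit is conservative — real clinical items are usually more
strongly coupled); the EI ordering tolerates dropping 50% of the sample
(CS = 0.5, above the customary 0.25 floor), while the bridge-EI ordering
is not stable enough to interpret (CS = 0), and no node pair differs
significantly in EI. The output directory holds the resolved config, the
generated data, correlation matrix, redundancy report, edge list,
adjacency matrix, GraphML export, centrality table, bootstrap CIs, and
stability samples — every number in the report can be recomputed from
them.

The same stages are available as CLI subcommands
(`bridgenet simulate | reduce | estimate | centrality | run`).

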