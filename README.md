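# symptomnet

Symptom-network analysis of insomnia questionnaire data: regularized
partial-correlation networks with EBIC model selection, centrality and
predictability, bootstrap stability, permutation-based network comparison,
and the accompanying cohort descriptive statistics — driven by a
synthetic-cohort generator with known ground truth, so the whole pipeline
is testable without any external data.

## Who this is for

Researchers analyzing ordinal symptom scales (here the 7-item Insomnia
Severity Index, ISI, each item scored 0–4) who want the standard
psychometric-network workflow as a reproducible, scriptable Python
pipeline rather than an interactive R session: estimate which symptoms are
conditionally associated, which are most central, how stable those
conclusions are under resampling, and whether two groups share a network.

## The model

Symptoms are nodes of a Gaussian graphical model; an edge is the partial
correlation between two items conditional on all others,
`ρ_ij = −K_ij / √(K_ii K_jj)` where `K` is the precision matrix.  Ordinal
items are first Gaussianized by the nonparanormal (rank) transform, then
`K` is estimated by the graphical lasso,

&nbsp;&nbsp;`max_K  log det K − tr(SK) − λ Σ_{i≠j} |K_ij|`,

with the penalty `λ` chosen by the extended Bayesian information
criterion `EBIC = −2L + E log n + 4γ E log p` (γ = 0.5) along a
100-value path.  Node importance is expected influence
`EI(i) = Σ_j w_ij`; predictability is the share of a node's variance
explained by its neighbors; stability is summarized by the
correlation-stability (CS) coefficient of a case-dropping bootstrap; and
group networks are compared with a permutation test of the maximum edge
difference (M) and global strength difference (S).

The synthetic generator draws cohorts from a latent Gaussian copula whose
precision matrix carries a known sparse graph, discretizes items through
calibrated thresholds (hitting a target prevalence of sum-score ≥ 8), and
adds covariates and symptom-linked outcome scales (depression, anxiety,
fatigue, quality of life).  See `docs/methods.md` for all modeling
choices.

## Worked example

```python
from symptomnet import (generate_cohort, npn_transform, select_network,
                        centrality_table, prevalence_with_ci)
from symptomnet.io import ITEM_COLUMNS
from symptomnet.cohort import ISI_LABELS

cohort = generate_cohort(n=1101, target_prevalence=0.189, seed=1)
n_pos = int((cohort.isi_total >= 8).sum())
pct, lo, hi = prevalence_with_ci(n_pos, len(cohort)).as_percent()
print(f"insomnia symptoms: {n_pos}/1101 = {pct}% (95% CI {lo}-{hi}%)")

data = npn_transform(cohort[ITEM_COLUMNS], variable_labels=list(ISI_LABELS))
net, path = select_network(data)
print(f"selected lambda = {net.lambda_selected:.4f}, edges = {net.edge_count}")

cent = centrality_table(data, net)
print("top-3 expected influence:", ", ".join(cent.top_nodes(3)))
print(f"mean predictability = {cent.mean_predictability:.3f}")
```

Output:

```
insomnia symptoms: 197/1101 = 17.9% (95% CI 15.7-20.3%)
selected lambda = 0.0073, edges = 21
top-3 expected influence: ISI7, ISI1, ISI2
mean predictability = 0.574
```

The simulated cohort lands near the 18.9% prevalence target (binomial
noise at n = 1101); the EBIC-selected network keeps all 21 pairwise
edges of the strongly intercorrelated item set; the most central symptoms
are distress (ISI7), sleep onset (ISI1) and sleep maintenance (ISI2) —
the generator's planted hubs; and on average 57% of each node's variance
is explained by its neighbors.

The same workflow is available from the shell:

```bash
symptomnet simulate --n 1101 --seed 1 --out cohort.csv
symptomnet run-all --seed 1 --out results_dir
```

`run-all` writes the cohort, a descriptive-statistics JSON (prevalence,
group tests, covariate-adjusted QoL comparison, logistic correlates), edge
lists for the original / age-adjusted / QoL-flow networks, the centrality
table, bootstrap and case-dropping summaries, the gender network
comparison, and a manifest recording every seed, setting and timing.

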