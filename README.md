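# m6ascore

Consensus subtyping and PCA-based m⁶A scoring of prostate-cancer
expression cohorts.

N6-methyladenosine (m⁶A) is the most common mRNA modification,
deposited, removed and read by a panel of 21 regulator genes (writers
METTL3, METTL14, RBM15, RBM15B, WTAP, KIAA1429, CBLL1, ZC3H13; erasers
ALKBH5, FTO; readers YTHDC1/2, YTHDF1/2/3, IGF2BP1, HNRNPA2B1, HNRNPC,
FMR1, LRPPRC, ELAVL1). Their joint expression pattern stratifies
prostate tumors into subtypes with different recurrence risk, and a
low-dimensional summary of the metastasis-associated regulators
predicts metastasis. `m6ascore` implements that analysis end to end
for anyone who has a gene-by-sample expression matrix and clinical
annotations:

* **Regulator screen** — Mann-Whitney U (tumor vs normal) and
  Student's t (metastatic vs non-metastatic) per gene at raw p < α.
* **Consensus clustering** — average-linkage hierarchical clustering
  on d = 1 − Pearson r, resampled over 1000 iterations (80%
  subsamples); the number of clusters k is chosen from the consensus-CDF
  delta-area Δ(k) with threshold 0.2; clusters are validated by
  silhouette widths and the SigClust Monte-Carlo test.
* **DEG signature** — pairwise per-gene t-tests between subtypes,
  |log2FC| > 2 and Benjamini-Hochberg q < 0.05, de-duplicated union.
* **m⁶A score** — per sample, the sum of its coordinates on the first
  two principal components of the z-scored metastasis-associated
  regulator signature,

  &nbsp;&nbsp;&nbsp;&nbsp;score(s) = PC1(s) + PC2(s),

  with each component oriented so that it correlates non-positively
  with mean signature expression (low score ⇔ high aggregate regulator
  expression ⇔ metastasis-prone).
* **Outcome evaluation** — one-way ANOVA, Spearman/Pearson
  correlation, Kaplan-Meier curves with log-rank tests, ROC/AUC, and a
  rank-based stemness index scored against a supplied signature-weight
  vector.

A seeded synthetic-cohort generator (`m6ascore.simulate`) produces
expression, clinical and ground-truth tables with the structure the
analysis assumes — tumor/normal shifts in 18 of the 21 regulators,
three latent subtypes elevating disjoint regulator blocks, a logistic
metastasis label driven by a 7-regulator subset, subtype-linked Gleason
grades, and censored survival with a subtype-dependent recurrence
hazard — so the whole pipeline is testable without external data. See
`docs/methods.md` for the model details and limitations.

## Worked example

```python
from m6ascore import (SimConfig, simulate_cohort, run_pipeline)

expr, clinical, truth = simulate_cohort(SimConfig(seed=1))
result = run_pipeline(expr, clinical, seed=11)
print(result.k_selection.chosen_k, result.metastasis_signature)
print({k: round(v, 4) for k, v in result.evaluation.items()})
```

prints

```
3 ['CBLL1', 'ZC3H13', 'YTHDF3', 'IGF2BP1', 'HNRNPA2B1', 'HNRNPC', 'FMR1', 'LRPPRC', 'ELAVL1']
{'chosen_k': 3.0, 'n_selected_regulators': 21.0, 'n_signature_genes': 13.0,
 'n_metastasis_regulators': 9.0, 'mean_silhouette': 0.9949,
 'metastasis_auc': 0.6898, 'gleason_anova_p': 0.0026, 'subtype_anova_p': 0.0,
 'rfs_logrank_p': 0.0002, 'os_logrank_p': 0.932}
```

Reading: the delta-area rule picks k = 3 subtypes; all 21 regulators
differ between tumor and normal tissue in this draw and 9 of them are
associated with metastasis; the resulting score separates metastatic
from non-metastatic tumors with AUC 0.69 and differs across Gleason
grades and subtypes; recurrence-free survival differs between subtypes
(log-rank p ≈ 2e-4) while overall survival does not (p ≈ 0.93) —
exactly the structure the generator encodes.

The same workflow is available from the shell:

```bash
m6ascore simulate --seed 3 --out-dir cohort/
m6ascore run --expr cohort/expr.tsv --clinical cohort/clinical.tsv --out-dir results/
```

plus stepwise commands (`screen`, `cluster`, `signature`, `score`,
`evaluate`) for chaining with other tools.

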