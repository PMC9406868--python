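# Methods

`m6ascore` re-implements, as a tested and reusable pipeline, a bulk-RNA
expression analysis of prostate cancer built around the 21 canonical
N6-methyladenosine (m⁶A) regulator genes (8 writers, 2 erasers, 11
readers): screening regulators between tissue groups, discovering
expression subtypes by resampled consensus clustering, validating the
clusters, extracting a between-subtype differential-expression
signature, computing a PCA-based per-sample m⁶A score, and evaluating
that score against metastasis, tumor grade, survival and stemness. A
seeded synthetic-cohort generator provides data with the statistical
structure the analysis assumes, so every stage can be validated against
known ground truth.

## Data model and ingest

Expression is a genes × samples matrix of non-negative FPKM-like
values, read from TSV and log2(x+1)-transformed on ingest (the
transform refuses matrices with negative entries, which are taken to be
already on log scale; a pseudocount of 1 is the default). Clinical
annotations carry, per sample: tissue (tumor/normal), metastasis status
(yes/no/unknown), Gleason score (6–10), and right-censored overall
(OS) and recurrence-free (RFS) survival in months. Missing clinical
fields are empty strings on disk and NaN in memory; unknown metastasis
labels are excluded from contrasts, never imputed. Gene rows are
z-scored (sample standard deviation, n−1) before PCA; zero-variance
rows are a hard error naming the genes.

## Synthetic cohort generator

The generator draws, by default, 150 tumors and 30 normals over the 21
regulator genes plus 500 null background genes. Per-gene baselines are
uniform on [2, 8] log2 units with Gaussian noise σ = 1. Structure is
layered on top:

* **Tumor vs normal**: τ = 1 log2 unit added to a designated subset of
  18 regulators in tumors.
* **Subtypes**: K = 3 latent tumor subtypes (uniform proportions); the
  regulator panel is partitioned into K contiguous blocks and each
  subtype elevates its own block by δ = 2 log2 units. Disjoint blocks
  guarantee identifiable clusters at a known effect size.
* **Metastasis**: Bernoulli with logit = β₀ + β·(mean z of the last
  block's 7 regulators), β₀ = −1, β = 1 per z-unit. The z here is the
  generator's own standardization (baseline and noise σ), so the label
  depends on expression only through that gene set. Tying the
  metastasis genes to the last subtype's block makes the
  metastasis-prone subtype also the poor-prognosis one.
* **Gleason**: cumulative-logit over grades 6–10 with baseline
  marginal (0.25, 0.35, 0.20, 0.12, 0.08) and subtype shifts
  (0, 0.5, 2.0), so the last subtype is almost entirely grade ≥ 8.
* **Survival**: exponential event times at baseline hazard 0.02/month
  with per-subtype hazard ratios — RFS (1, 1, 2.5), OS all 1, so
  subtypes differ in recurrence but not overall survival — censored
  uniformly on [0, 120] months. These scales give roughly 60% observed
  events at the default cohort size, enough for the log-rank power the
  tests assert.

What the generator deliberately does **not** emulate: real marginal
expression distributions, library-size or batch effects, probe-level
noise, gene–gene correlation beyond the block structure, and
non-exponential hazards. Passing tests therefore demonstrate that the
pipeline's statistics behave as designed under their own model
assumptions — not that the biological conclusions transfer to any real
cohort.

## Regulator screening

Tumor vs normal uses the two-sided Mann-Whitney U test (exact
enumeration when n₁+n₂ ≤ 12 without ties, else tie-corrected normal
approximation with continuity correction); metastatic vs
non-metastatic uses Student's t, pooled variance by default with a
Welch flag. Screening keeps genes at raw p < α = 0.05 with no
multiple-testing correction — a deliberate reproduction of the
screening convention this pipeline follows; FDR control is applied
only in the DEG-signature stage.

## Consensus clustering

Samples are clustered on d = 1 − Pearson r (over genes) by
average-linkage (UPGMA) hierarchical clustering, delegated to
`scipy.cluster.hierarchy` with the tree cut by `cut_tree`, so exactly k
clusters result even with tied merge heights. Consensus runs 1000
iterations, each subsampling 80% of samples without replacement;
because the correlation distance between two samples does not depend on
which other samples are drawn, the full distance matrix is computed
once and sub-indexed per iteration, and one tree per iteration is cut
at every k (all k therefore share identical subsamples). The consensus
C_ij is co-clustering count over co-sampling count; never co-sampled
pairs get C = 0 with a warning.

k is selected from the per-k area A(k) under the empirical CDF of
off-diagonal consensus values: Δ(2) = A(2), Δ(k) = (A(k) −
A(k−1))/A(k−1) for k > 2, and the chosen k is the largest k ≥ 3 with
Δ(k) ≥ 0.2, falling back to k = 2. Final labels come from clustering
the consensus matrix itself at distance 1 − C, renumbered 1..k by
decreasing cluster size. Silhouette widths use the standard Rousseeuw
definition s = (b − a)/max(a, b) on any supplied distance (the pipeline
uses the consensus distance); singletons get 0.

## SigClust

The pairwise cluster-significance test compares the observed cluster
index CI — the best 2-means within-cluster sum of squares over the
total sum of squares, with 10 random restarts of a vectorized Lloyd
iteration — against CI values of Monte-Carlo draws from a zero-mean
Gaussian null. The null covariance is diagonal in the eigenbasis with
λ_j = max(eigenvalue_j of the *Ledoit-Wolf shrunk* sample covariance,
σ²_bg), σ²_bg being the squared MAD of all centered entries divided by
0.6745². Raw sample eigenvalues are dispersed around the population
spectrum (Marchenko-Pastur), so an unshrunk null is systematically more
anisotropic than the data and the test becomes badly conservative at
the dimensions used here (n = 40, d = 10: mean null p ≈ 0.79);
Ledoit-Wolf shrinkage restores calibration (KS uniformity p ≈ 0.07
over 200 null replicates) while keeping full power at a 6σ cluster
separation. p-values use the add-one-in estimator
(1 + #{CI_null ≤ CI_obs})/(n_sim + 1), bounded away from 0.

## DEG signature

For every unordered subtype pair, per-gene pooled two-sample t-tests on
log2 values with log2FC = difference of group means;
Benjamini-Hochberg within each comparison; significance = |log2FC| > 2
and q < 0.05 (both thresholds configurable — the fold-change cutoff is
read literally as 2 log2 units). The signature is the sorted,
de-duplicated union across comparisons. Plain t-tests stand in for
moderated (empirical-Bayes) ones; at ~50 samples per subtype the
moderation is immaterial and the controlled quantity — signature FDR —
is what the acceptance suite measures.

## The m⁶A score

Signature gene rows are z-scored and the top-2 eigenvectors of the
resulting gene-gene covariance are taken as loadings; a sample's score
is the sum of its PC1 and PC2 coordinates. PCA signs are fixed by an
orientation rule: each component is flipped so that its coordinates
correlate ≤ 0 with the mean z-scored signature expression. High
aggregate regulator expression thus maps to a low score, reproducing
the published conventions (metastatic samples score lower; the score is
inversely correlated with most regulators) deterministically. Scoring
a new cohort refits the PCA by default (appropriate across platforms);
`mode="project"` applies a frozen model with its stored centering.

Known limitation: the orientation guarantee binds through the *mean* of
the signature genes. If the signature mixes genes from several subtype
blocks, the leading components can align with between-block contrasts
nearly orthogonal to that mean, and the metastasis direction of the
summed score is no longer guaranteed (observed in a minority of
simulated screens). With the metastasis-associated gene set itself the
direction held in every seed tested.

## Outcome statistics

One-way ANOVA (scipy), Spearman/Pearson correlation (Spearman default;
both exposed since either convention appears in this literature),
Kaplan-Meier product-limit curves and the multi-group log-rank χ² test
(lifelines), and empirical ROC/AUC (scikit-learn) with an explicit
risk-direction argument defaulting to "low score = positive class".
AUC equals the tie-corrected U/(n₁n₂) identically. The stemness index
scores each sample by the Spearman correlation between a supplied
per-gene weight vector and the sample's expression over overlapping
genes (≥ 3 required), min-max scaled to [0, 1] across the cohort;
training of such weight vectors is out of scope, and tests use
synthetic weights tied to the generator's truth labels.

## Numerical and design choices

* Subsample fraction 0.8 per consensus iteration; iterations default
  to 1000.
* The relative (not absolute) delta-area rule with threshold 0.2; the
  fallback to k = 2 when nothing at k ≥ 3 passes.
* Merge-tie behavior follows scipy's deterministic nearest-neighbor
  chain; real-valued distances make ties measure-zero, and tests
  compare partitions against a brute-force UPGMA oracle on tie-free
  instances.
* Monte-Carlo problem sizes in tests (20-seed grids, 200 SigClust
  replicates at n_sim = 199, 50 FDR replicates at 2000 genes) were
  chosen to keep each statistical assertion's Monte-Carlo error well
  inside its tolerance at modest runtime.
* Scores/labels/weights with zero variance, empty contrast groups,
  missing signature genes, and invalid generator configs all raise
  errors naming the offending entity rather than propagating NaN.
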