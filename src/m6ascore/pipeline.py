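"""End-to-end orchestration of the m6A subtyping and scoring analysis.

Mirrors the published workflow: screen regulators tumor-vs-normal, run
resampled consensus clustering of tumors on the selected regulators,
pick k by the delta-area rule, validate clusters (silhouette, pairwise
SigClust), extract the pairwise DEG signature between subtypes, screen
regulators for metastasis association, fit the PCA score on that
signature, and evaluate the score against metastasis, Gleason grade and
survival.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import (
    ConsensusResult,
    DistanceMatrix,
    KSelection,
    SubtypeAssignment,
    assign_subtypes,
    consensus_sweep,
    select_k,
    sigclust,
    silhouette_widths,
)
from .data import CohortAnnotations, ExpressionMatrix
from .deg import pairwise_deg_signature
from .evaluate import logrank_test, one_way_anova, roc_auc
from .score import fit_score_model, compute_scores
from .screen import screen_regulators
from .simulate import M6A_REGULATORS

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    tumor_normal_screen: pd.DataFrame
    selected_regulators: list[str]
    consensus: dict[int, ConsensusResult]
    k_selection: KSelection
    assignment: SubtypeAssignment
    deg_table: pd.DataFrame
    signature: list[str]
    metastasis_screen: pd.DataFrame | None
    metastasis_signature: list[str]
    score_model: object | None
    scores: pd.Series | None
    evaluation: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    expr: ExpressionMatrix,
    ann: CohortAnnotations,
    regulators=M6A_REGULATORS,
    alpha: float = 0.05,
    k_min: int = 2,
    k_max: int = 6,
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    delta_threshold: float = 0.2,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    sigclust_sims: int = 200,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis on one cohort. See the module docstring."""
    regulators = [g for g in regulators if g in expr.gene_ids]
    ann.check_paired(expr)
    rng = np.random.default_rng(seed)

    # 1. regulator screen: tumor vs normal (Mann-Whitney), raw p < alpha
    tn = screen_regulators(expr, ann, regulators, "tumor_vs_normal", alpha)
    selected = list(tn.loc[tn["selected"], "gene_id"])
    if len(selected) < 2:
        raise ValueError("fewer than 2 regulators passed the tumor-vs-normal screen")

    # 2. consensus clustering of tumors on the selected regulators
    tumors = ann.samples_where(ann.df["tissue"] == "tumor")
    tumor_expr = expr.subset(genes=selected, samples=tumors)
    sweep = consensus_sweep(
        tumor_expr,
        range(k_min, k_max + 1),
        n_iter=n_iter,
        subsample_fraction=subsample_fraction,
        seed=int(rng.integers(2**31 - 1)),
    )
    ksel = select_k(sweep, delta_threshold)
    assignment = assign_subtypes(sweep[ksel.chosen_k])

    # 3. validation: silhouette on the consensus distance, pairwise SigClust
    cons = sweep[ksel.chosen_k].consensus
    dcons = 1.0 - cons
    dcons = np.clip((dcons + dcons.T) / 2.0, 0.0, None)
    np.fill_diagonal(dcons, 0.0)
    labels = assignment.labels
    assignment.silhouette = silhouette_widths(
        DistanceMatrix(list(tumor_expr.sample_ids), dcons), labels.to_numpy()
    )
    assignment.sigclust_p = {}
    for a, b in itertools.combinations(sorted(labels.unique()), 2):
        pair = list(labels.index[labels.isin([a, b])])
        lab = labels.loc[pair].to_numpy()
        if min((lab == a).sum(), (lab == b).sum()) < 3:
            continue
        assignment.sigclust_p[(int(a), int(b))] = sigclust(
            expr.subset(genes=selected, samples=pair),
            labels=lab,
            n_sim=sigclust_sims,
            seed=int(rng.integers(2**31 - 1)),
        )

    # 4. pairwise DEG signature between subtypes, whole transcriptome
    full_tumor = expr.subset(samples=tumors)
    deg_table, signature = pairwise_deg_signature(
        full_tumor, labels, lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold
    )

    # 5. metastasis screen (Student's t) on regulators that passed step 1
    met_counts = ann.df["metastasis"].value_counts()
    met_screen = None
    met_signature: list[str] = []
    if met_counts.get("yes", 0) >= 2 and met_counts.get("no", 0) >= 2:
        met_screen = screen_regulators(expr, ann, selected, "metastatic_vs_not", alpha)
        met_signature = list(met_screen.loc[met_screen["selected"], "gene_id"])

    # 6. PCA score on the metastasis signature (refit on this cohort)
    model = None
    scores = None
    evaluation: dict[str, float] = {
        "chosen_k": float(ksel.chosen_k),
        "n_selected_regulators": float(len(selected)),
        "n_signature_genes": float(len(signature)),
        "n_metastasis_regulators": float(len(met_signature)),
        "mean_silhouette": float(assignment.silhouette.mean()),
    }
    if len(met_signature) >= 2:
        model = fit_score_model(full_tumor, met_signature)
        scores = compute_scores(model, full_tumor)

        tdf = ann.df.set_index("sample_id").loc[tumors]
        known = tdf["metastasis"].isin(["yes", "no"])
        if known.sum() >= 3 and tdf.loc[known, "metastasis"].nunique() == 2:
            y = (tdf.loc[known, "metastasis"] == "yes").astype(int).to_numpy()
            roc = roc_auc(scores.loc[known[known].index].to_numpy(), y, "low_is_positive")
            evaluation["metastasis_auc"] = roc.auc
        gl = tdf["gleason"].dropna()
        groups = [scores.loc[gl.index[gl == g]].to_numpy() for g in sorted(gl.unique())]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) >= 2:
            f, p = one_way_anova(groups)
            evaluation["gleason_anova_p"] = p
        sub_groups = [scores.loc[labels.index[labels == s]].to_numpy() for s in sorted(labels.unique())]
        f, p = one_way_anova([g for g in sub_groups if g.size >= 2])
        evaluation["subtype_anova_p"] = p

    # 7. survival by subtype
    tdf = ann.df.set_index("sample_id").loc[tumors]
    for stem, name in (("rfs", "rfs_logrank_p"), ("os", "os_logrank_p")):
        ok = tdf[f"{stem}_time"].notna() & tdf[f"{stem}_event"].notna()
        if ok.sum() >= 3:
            chi2, p = logrank_test(
                tdf.loc[ok, f"{stem}_time"].to_numpy(),
                tdf.loc[ok, f"{stem}_event"].to_numpy().astype(int),
                labels.loc[tdf.index[ok]].to_numpy(),
            )
            evaluation[name] = p

    return PipelineResult(
        tumor_normal_screen=tn,
        selected_regulators=selected,
        consensus=sweep,
        k_selection=ksel,
        assignment=assignment,
        deg_table=deg_table,
        signature=signature,
        metastasis_screen=met_screen,
        metastasis_signature=met_signature,
        score_model=model,
        scores=scores,
        evaluation=evaluation,
    )
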