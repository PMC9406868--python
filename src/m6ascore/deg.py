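"""Pairwise differential expression between subtypes and signature extraction.

For every unordered pair of subtypes, each gene gets a pooled two-sample
t-test on log2 expression; log2 fold change is the plain difference of
group means (the matrix is already on log2 scale). p-values are
Benjamini-Hochberg adjusted within each pairwise comparison, and a gene
is significant when |log2FC| exceeds the fold-change cutoff and the
adjusted p (q) is under the FDR cutoff. The signature is the
de-duplicated union of significant genes across comparisons.

Plain t-tests stand in for moderated (empirical-Bayes shrunk) ones: at
the cohort sizes this pipeline targets the moderation has little effect,
and the quantity under control here is the FDR of the signature.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix

__all__ = ["bh_adjust", "pairwise_deg_signature"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_t_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled two-sample t-test per row. Returns (t, p)."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p


def pairwise_deg_signature(
    m: ExpressionMatrix,
    labels,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise subtype DEG tables and the de-duplicated signature list.

    ``labels`` maps every sample in ``m`` to a subtype (a pandas Series
    indexed by sample_id, or an array aligned with ``m.sample_ids``).
    Returns (deg_table, signature): the table has one row per gene per
    comparison with log2_fc, p_value, q_value and the significance flag;
    the signature is the sorted union of significant genes.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(m.sample_ids)
        if labels.isna().any():
            raise ValueError("labels missing for some samples in the matrix")
        labels = labels.to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_samples:
        raise ValueError("labels length must match number of samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 subtypes")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"subtypes with fewer than 2 samples: {list(small)}")
    tables = []
    signature: set[str] = set()
    for ga, gb in itertools.combinations(sorted(uniq), 2):
        a = m.values[:, labels == ga]
        b = m.values[:, labels == gb]
        t, p = _row_t_test(a, b)
        q = bh_adjust(p)
        lfc = a.mean(axis=1) - b.mean(axis=1)
        sig = (np.abs(lfc) > lfc_threshold) & (q < fdr_threshold)
        tables.append(
            pd.DataFrame(
                {
                    "gene_id": m.gene_ids,
                    "comparison": f"{ga}_vs_{gb}",
                    "log2_fc": lfc,
                    "t": t,
                    "p_value": p,
                    "q_value": q,
                    "significant": sig,
                }
            )
        )
        signature.update(np.asarray(m.gene_ids)[sig])
    return pd.concat(tables, ignore_index=True), sorted(signature)
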