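"""Per-gene two-group screening of m6A regulators.

Tumor vs. normal uses the Mann-Whitney U test; metastatic vs.
non-metastatic uses Student's t (pooled by default). No multiple-testing
correction is applied at this stage — genes are kept at raw p < α, the
convention of the screening step this reproduces; FDR control lives in
the DEG signature stage (:mod:`m6ascore.deg`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortAnnotations, ExpressionMatrix

__all__ = ["mann_whitney_u", "students_t", "screen_regulators"]


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs (x_i, y_j) with x_i > y_j plus half-ties. The p-value
    is by exact enumeration when n_x + n_y <= 12 and there are no ties,
    else by the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u needs non-empty samples")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def students_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test, pooled variance by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("students_t needs at least 2 values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


CONTRASTS = ("tumor_vs_normal", "metastatic_vs_not")


def _contrast_groups(
    ann: CohortAnnotations, contrast: str
) -> tuple[list[str], list[str], tuple[str, str]]:
    df = ann.df
    if contrast == "tumor_vs_normal":
        g1 = ann.samples_where(df["tissue"] == "tumor")
        g2 = ann.samples_where(df["tissue"] == "normal")
        names = ("tumor", "normal")
    elif contrast == "metastatic_vs_not":
        g1 = ann.samples_where(df["metastasis"] == "yes")
        g2 = ann.samples_where(df["metastasis"] == "no")
        names = ("metastatic", "non-metastatic")
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    for g, name in zip((g1, g2), names):
        if not g:
            raise ValueError(f"contrast group {name!r} is empty")
    return g1, g2, names


def screen_regulators(
    m: ExpressionMatrix,
    ann: CohortAnnotations,
    regulators,
    contrast: str = "tumor_vs_normal",
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Screen each regulator gene between the two contrast groups.

    Returns a DataFrame with one row per regulator: gene_id, statistic
    (U or t), p_value, direction (sign of group-1 minus group-2 mean) and
    selected (p < alpha). Samples with unknown labels are excluded.
    """
    regulators = list(regulators)
    ann.check_paired(m)
    g1, g2, _ = _contrast_groups(ann, contrast)
    sub = m.subset(genes=regulators)
    i1 = sub.sample_index(g1)
    i2 = sub.sample_index(g2)
    rows = []
    for gi, gene in enumerate(sub.gene_ids):
        x = sub.values[gi, i1]
        y = sub.values[gi, i2]
        if contrast == "tumor_vs_normal":
            stat, p = mann_whitney_u(x, y)
        else:
            stat, p = students_t(x, y, welch=welch)
        rows.append(
            {
                "gene_id": gene,
                "statistic": stat,
                "p_value": p,
                "direction": int(np.sign(x.mean() - y.mean())),
                "selected": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
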