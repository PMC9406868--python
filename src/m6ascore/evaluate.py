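"""Outcome statistics: ANOVA, correlations, survival, ROC, stemness.

Thin, contract-checked wrappers over scipy / lifelines / scikit-learn,
plus the rank-based stemness index. The survival and ROC containers keep
the quantities the analysis reports (at-risk tables, sensitivity /
specificity per threshold) rather than bare p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "SurvivalCurve",
    "RocCurve",
    "one_way_anova",
    "rank_correlation",
    "km_estimate",
    "logrank_test",
    "roc_auc",
    "stemness_index",
]


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA F test across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if all(np.var(g, ddof=1) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman (default) or Pearson correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    times: np.ndarray       # distinct observed times (events and censorings)
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; censored-only data yields the constant 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = np.unique(times)
    table = kmf.event_table.loc[grid]
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square test across two or more groups, (g−1) df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise ValueError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class RocCurve:
    """Empirical ROC over all score thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels, risk_direction: str = "low_is_positive") -> RocCurve:
    """ROC curve and AUC of a score against binary labels.

    ``risk_direction`` states which end of the score marks the positive
    class; the default follows the m6A-score convention that metastatic
    samples have *lower* scores. The AUC equals the tie-corrected rank
    statistic U/(n1·n2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    if risk_direction == "low_is_positive":
        s = -scores
    elif risk_direction == "high_is_positive":
        s = scores
    else:
        raise ValueError(f"unknown risk_direction {risk_direction!r}")
    fpr, tpr, thr = roc_curve(labels, s, drop_intermediate=False)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(labels, s)),
    )


def stemness_index(m, weights) -> pd.DataFrame:
    """Per-sample stemness: rank correlation with a signature weight vector.

    ``weights`` is a mapping / Series of per-gene weights (a trained
    stem-cell expression signature). The raw index of a sample is the
    Spearman correlation between the weights and the sample's expression
    over the overlapping genes (at least 3 required); the cohort is then
    min-max scaled to [0, 1]. Returns a DataFrame with ``raw`` and
    ``scaled`` columns indexed by sample.
    """
    weights = pd.Series(weights, dtype=float)
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    overlap = [g for g in m.gene_ids if g in weights.index]
    if len(overlap) < 3:
        raise ValueError(f"only {len(overlap)} genes overlap the weight vector; need >= 3")
    sub = m.subset(genes=overlap)
    w = weights.loc[overlap].to_numpy()
    raw = np.array(
        [stats.spearmanr(w, sub.values[:, j]).statistic for j in range(sub.n_samples)]
    )
    span = raw.max() - raw.min()
    if span == 0:
        raise ValueError("all samples have identical raw stemness; cannot min-max scale")
    scaled = (raw - raw.min()) / span
    return pd.DataFrame(
        {"raw": raw, "scaled": scaled}, index=pd.Index(sub.sample_ids, name="sample_id")
    )
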