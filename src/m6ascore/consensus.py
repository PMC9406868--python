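"""Resampled consensus clustering with k-selection and cluster validation.

Samples are clustered on regulator expression by agglomerative
average-linkage (UPGMA) hierarchical clustering under the correlation
distance d = 1 − Pearson r. Stability is assessed by consensus over
resampled iterations (default 1000 at subsample fraction 0.8): the
consensus C_ij is the fraction of co-sampled iterations in which samples
i and j landed in the same cluster. The number of clusters is chosen from
the per-k CDF of consensus values via the relative delta-area rule, and
clusters are validated by silhouette widths and the SigClust Monte-Carlo
test of pairwise cluster significance against a single-Gaussian null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .data import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "ConsensusResult",
    "KSelection",
    "SubtypeAssignment",
    "correlation_distance",
    "hclust_average",
    "build_consensus",
    "consensus_sweep",
    "consensus_cdf_area",
    "select_k",
    "select_k_from_areas",
    "assign_subtypes",
    "silhouette_widths",
    "sigclust",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(self.matrix)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be zero")


def correlation_distance(m: ExpressionMatrix) -> DistanceMatrix:
    """d_ij = 1 − Pearson correlation of sample profiles over genes."""
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes per sample profile")
    sd = m.values.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance sample profile: {[m.sample_ids[i] for i in bad]}")
    r = np.corrcoef(m.values.T)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.sample_ids), d)


def _upgma_linkage(d: np.ndarray) -> np.ndarray:
    return linkage(squareform(d, checks=False), method="average")


def hclust_average(d: DistanceMatrix, k: int) -> np.ndarray:
    """UPGMA tree cut into k clusters; returns labels 1..k (tree order)."""
    n = len(d.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if n == 1:
        return np.array([1])
    z = _upgma_linkage(d.matrix)
    return cut_tree(z, n_clusters=k).ravel() + 1


@dataclass
class ConsensusResult:
    """Consensus of resampled clusterings at a single k.

    ``consensus[i, j]`` = connectivity_counts / indicator_counts, the
    fraction of iterations sampling both i and j in which they
    co-clustered; the diagonal is fixed at 1.
    """

    k: int
    sample_ids: list[str]
    connectivity_counts: np.ndarray
    indicator_counts: np.ndarray
    consensus: np.ndarray
    n_iterations: int
    subsample_fraction: float
    seed: int | None


def consensus_sweep(
    m: ExpressionMatrix,
    k_values,
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
) -> dict[int, ConsensusResult]:
    """Consensus matrices for several k sharing one resampling stream.

    Each iteration draws ⌈fraction·n⌉ samples without replacement,
    clusters them by correlation-distance UPGMA, and cuts the same tree
    at every requested k; all k therefore see identical subsamples.
    """
    k_values = sorted(int(k) for k in k_values)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if min(k_values) < 2:
        raise ValueError("k must be >= 2")
    n = m.n_samples
    size = int(np.ceil(subsample_fraction * n))
    if size < max(k_values):
        raise ValueError("subsample smaller than the largest k")
    dist = correlation_distance(m).matrix
    rng = np.random.default_rng(seed)
    indicator = np.zeros((n, n), dtype=np.int64)
    connect = {k: np.zeros((n, n), dtype=np.int64) for k in k_values}
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        block = np.ix_(idx, idx)
        indicator[block] += 1
        z = _upgma_linkage(dist[block])
        cuts = cut_tree(z, n_clusters=k_values)
        for col, k in enumerate(k_values):
            lab = cuts[:, col]
            connect[k][block] += lab[:, None] == lab[None, :]
    never = (indicator == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{never.sum() // 2} sample pairs never co-sampled; their consensus is set to 0",
            stacklevel=2,
        )
    results = {}
    for k in k_values:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(indicator > 0, connect[k] / np.maximum(indicator, 1), 0.0)
        np.fill_diagonal(c, 1.0)
        results[k] = ConsensusResult(
            k=k,
            sample_ids=list(m.sample_ids),
            connectivity_counts=connect[k],
            indicator_counts=indicator,
            consensus=c,
            n_iterations=n_iter,
            subsample_fraction=subsample_fraction,
            seed=seed,
        )
    return results


def build_consensus(
    m: ExpressionMatrix,
    k: int,
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Consensus matrix at a single k (see :func:`consensus_sweep`)."""
    return consensus_sweep(m, [k], n_iter, subsample_fraction, seed)[k]


def consensus_cdf_area(c: ConsensusResult) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries on [0, 1]."""
    n = len(c.sample_ids)
    vals = np.sort(c.consensus[np.triu_indices(n, k=1)])
    m_ = vals.size
    ecdf = np.arange(1, m_ + 1) / m_
    edges = np.append(vals, 1.0)
    return float(np.sum(np.diff(edges) * ecdf) + vals[0] * 0.0)


@dataclass
class KSelection:
    """Delta-area summary of a consensus sweep."""

    k_values: list[int]
    areas: list[float]
    deltas: list[float]
    chosen_k: int
    delta_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "area": self.areas, "delta": self.deltas})


def select_k_from_areas(k_values, areas, delta_threshold: float = 0.2) -> KSelection:
    """Relative delta-area rule on precomputed CDF areas.

    Δ(2) = A(2); Δ(k) = (A(k) − A(k−1))/A(k−1) for k > 2. The chosen k is
    the largest k ≥ 3 with Δ(k) ≥ threshold, falling back to 2.
    """
    k_values = [int(k) for k in k_values]
    if len(k_values) < 2:
        raise ValueError("need at least two k values")
    if k_values[0] != 2 or k_values != list(range(2, 2 + len(k_values))):
        raise ValueError("k values must be consecutive starting at 2")
    areas = [float(a) for a in areas]
    deltas = [areas[0]]
    for prev, cur in zip(areas, areas[1:]):
        deltas.append((cur - prev) / prev if prev > 0 else np.inf)
    passing = [k for k, d in zip(k_values, deltas) if k >= 3 and d >= delta_threshold]
    chosen = max(passing) if passing else 2
    return KSelection(k_values, areas, deltas, chosen, delta_threshold)


def select_k(results: dict[int, ConsensusResult], delta_threshold: float = 0.2) -> KSelection:
    """Apply the delta-area rule to a consensus sweep (k consecutive from 2)."""
    ks = sorted(results)
    areas = [consensus_cdf_area(results[k]) for k in ks]
    return select_k_from_areas(ks, areas, delta_threshold)


@dataclass
class SubtypeAssignment:
    """Final subtype labels with optional validation statistics."""

    labels: pd.Series  # sample_id -> 1..k, renumbered by decreasing size
    silhouette: pd.Series | None = None
    sigclust_p: dict[tuple[int, int], float] | None = None


def assign_subtypes(c: ConsensusResult, k: int | None = None) -> SubtypeAssignment:
    """Cluster the consensus matrix itself (distance 1 − C) at k.

    Labels are renumbered 1..k in decreasing cluster size (ties broken by
    first appearance in the tree cut).
    """
    k = c.k if k is None else int(k)
    d = 1.0 - c.consensus
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    raw = hclust_average(DistanceMatrix(list(c.sample_ids), d), k)
    sizes = pd.Series(raw).value_counts()  # sorts by count desc, then by appearance
    order = list(sizes.index)
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series(
        [remap[v] for v in raw], index=pd.Index(c.sample_ids, name="sample_id"), name="subtype"
    )
    return SubtypeAssignment(labels=labels)


def silhouette_widths(d: DistanceMatrix, labels) -> pd.Series:
    """Per-sample silhouette width s_i = (b_i − a_i) / max(a_i, b_i).

    a_i is the mean distance to the sample's own cluster, b_i the
    smallest mean distance to any other cluster. Singleton clusters and
    degenerate a_i = b_i = 0 cases get s_i = 0.
    """
    labels = np.asarray(labels)
    dm = d.matrix
    n = dm.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match distance matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    mean_to = np.empty((n, uniq.size))
    counts = np.empty(uniq.size)
    for j, g in enumerate(uniq):
        mask = labels == g
        counts[j] = mask.sum()
        mean_to[:, j] = dm[:, mask].sum(axis=1) / mask.sum()
    s = np.zeros(n)
    for i in range(n):
        j = int(np.where(uniq == labels[i])[0][0])
        nc = counts[j]
        if nc == 1:
            continue
        a = mean_to[i, j] * nc / (nc - 1)  # exclude self (distance 0)
        b = np.min(np.delete(mean_to[i], j))
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return pd.Series(s, index=pd.Index(d.sample_ids, name="sample_id"), name="silhouette")


def _two_means_ci(data: np.ndarray, rng: np.random.Generator, n_restarts: int = 10) -> float:
    """Cluster index: min over restarts of 2-means WSS over total SS.

    ``data`` is samples × features. Lloyd's algorithm from random pairs
    of points, vectorized across restarts.
    """
    n, d = data.shape
    centered = data - data.mean(axis=0)
    tss = float(np.sum(centered**2))
    if tss == 0:
        return 1.0
    init = np.array([rng.choice(n, size=2, replace=False) for _ in range(n_restarts)])
    centers = data[init]  # (R, 2, d)
    assign = np.zeros((n_restarts, n), dtype=int)
    for _ in range(100):
        # squared distances (R, 2, n)
        diff = data[None, None, :, :] - centers[:, :, None, :]
        d2 = np.einsum("rcnd,rcnd->rcn", diff, diff)
        new_assign = d2.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c_ in (0, 1):
            mask = assign == c_  # (R, n)
            cnt = mask.sum(axis=1)
            ok = cnt > 0
            sums = mask.astype(float) @ data  # (R, d)
            centers[ok, c_, :] = sums[ok] / cnt[ok, None]
    diff = data[None, None, :, :] - centers[:, :, None, :]
    d2 = np.einsum("rcnd,rcnd->rcn", diff, diff)
    wss = d2.min(axis=1).sum(axis=1)  # (R,)
    return float(wss.min() / tss)


def sigclust(
    m: ExpressionMatrix,
    labels=None,
    n_sim: int = 1000,
    seed: int | None = None,
    n_restarts: int = 10,
) -> float:
    """Monte-Carlo significance of a 2-cluster split vs. a Gaussian null.

    The observed statistic is the cluster index CI = (best 2-means
    within-cluster sum of squares) / (total sum of squares about the
    grand mean), over the pooled samples of the two clusters. The null is
    a zero-mean Gaussian with diagonal covariance λ_j = max(eigenvalue_j
    of the Ledoit-Wolf shrunk sample covariance, σ²_bg), where σ²_bg is
    the squared MAD of all centered matrix entries divided by 0.6745².
    Shrinkage corrects the finite-sample dispersion of raw eigenvalues,
    which otherwise makes the null more anisotropic than the data and
    the test badly conservative. The p-value is the add-one-in
    Monte-Carlo estimate (1 + #{CI_null ≤ CI_obs})/(n_sim + 1).
    """
    from sklearn.covariance import LedoitWolf

    data = m.values.T  # samples × genes
    n, d = data.shape
    if labels is not None:
        labels = np.asarray(labels)
        uniq, cnt = np.unique(labels, return_counts=True)
        if uniq.size != 2:
            raise ValueError("sigclust compares exactly two clusters")
        if cnt.min() < 2:
            raise ValueError("each cluster needs at least 2 samples")
    if n < 4:
        raise ValueError("sigclust needs at least 4 samples")
    rng = np.random.default_rng(seed)
    ci_obs = _two_means_ci(data, rng, n_restarts)
    centered = data - data.mean(axis=0)
    mad = np.median(np.abs(centered - np.median(centered)))
    sigma2_bg = (mad / 0.6745) ** 2
    cov = LedoitWolf().fit(data).covariance_
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))
    lam = np.sqrt(np.maximum(eig, sigma2_bg))
    hits = 0
    for _ in range(n_sim):
        null = rng.normal(size=(n, d)) * lam[None, :]
        if _two_means_ci(null, rng, n_restarts) <= ci_obs:
            hits += 1
    return (1 + hits) / (n_sim + 1)
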