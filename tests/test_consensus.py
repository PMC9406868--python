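import numpy as np
import pytest

from m6ascore import (
    DistanceMatrix,
    ExpressionMatrix,
    assign_subtypes,
    build_consensus,
    consensus_sweep,
    correlation_distance,
    hclust_average,
    select_k,
    select_k_from_areas,
    sigclust,
    silhouette_widths,
)
from m6ascore.consensus import KSelection, consensus_cdf_area
from conftest import two_block_matrix
from oracles import silhouette_brute, upgma_labels, upgma_merge_heights


# ---------------------------------------------------------------- distance
def test_correlation_distance_hand_values():
    m = ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["a", "b", "c"],
        np.array([[1.0, 3.0, 1.0], [2.0, 2.0, 3.0], [3.0, 1.0, 2.0]]),
    )
    d = correlation_distance(m).matrix
    assert d[0, 0] == 0
    assert d[0, 1] == pytest.approx(2.0)       # (1,2,3) vs (3,2,1): r = -1
    assert d[0, 2] == pytest.approx(0.5)       # (1,2,3) vs (1,3,2): r = 1/2
    assert np.allclose(d, d.T)


def test_correlation_distance_identical_profiles_zero():
    m = ExpressionMatrix(["g1", "g2"], ["a", "b"], np.array([[1.0, 1.0], [2.0, 2.0]]))
    assert correlation_distance(m).matrix[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_correlation_distance_flat_profile_named():
    m = ExpressionMatrix(["g1", "g2"], ["ok", "flat"], np.array([[1.0, 4.0], [2.0, 4.0]]))
    with pytest.raises(ValueError, match="flat"):
        correlation_distance(m)


# ---------------------------------------------------------------- UPGMA
def test_hclust_hand_example():
    d = np.array([[0, 1, 5.0], [1, 0, 6.0], [5, 6, 0]])
    dm = DistanceMatrix(["A", "B", "C"], d)
    labels = hclust_average(dm, 2)
    assert labels[0] == labels[1] != labels[2]
    heights, _ = upgma_merge_heights(d)
    assert heights == [1.0, 5.5]  # {A,B} to C averages to 5.5


def test_hclust_boundaries():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 4))
    d = np.abs(x - x.T)
    np.fill_diagonal(d, 0)
    dm = DistanceMatrix(list("abcd"), d)
    assert len(set(hclust_average(dm, 4))) == 4
    assert len(set(hclust_average(dm, 1))) == 1
    with pytest.raises(ValueError):
        hclust_average(dm, 5)


def test_hclust_matches_brute_force_upgma():
    """Partition at every k agrees with a naive O(n^3) UPGMA on random matrices."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = 7
        x = rng.uniform(0.1, 2.0, (n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        for k in range(1, n + 1):
            ours = hclust_average(dm, k)
            oracle = upgma_labels(d, k)
            # compare partitions up to label permutation
            pairs_ours = (ours[:, None] == ours[None, :])
            pairs_oracle = (oracle[:, None] == oracle[None, :])
            assert np.array_equal(pairs_ours, pairs_oracle)


# ---------------------------------------------------------------- consensus
def test_consensus_two_blocks_perfect():
    m = two_block_matrix()
    res = build_consensus(m, k=2, n_iter=50, subsample_fraction=0.8, seed=0)
    block = np.array([0] * 5 + [1] * 5)
    same = block[:, None] == block[None, :]
    sampled = res.indicator_counts > 0
    off = ~np.eye(10, dtype=bool)
    assert np.all(res.consensus[same & off & sampled] == 1.0)
    assert np.all(res.consensus[~same & sampled] == 0.0)


def test_consensus_full_fraction_indicator():
    m = two_block_matrix()
    res = build_consensus(m, k=2, n_iter=20, subsample_fraction=1.0, seed=1)
    off = ~np.eye(10, dtype=bool)
    assert np.all(res.indicator_counts[off] == 20)


def test_consensus_deterministic_and_valid():
    m = two_block_matrix(seed=3)
    a = build_consensus(m, k=3, n_iter=30, seed=5)
    b = build_consensus(m, k=3, n_iter=30, seed=5)
    assert np.array_equal(a.consensus, b.consensus)
    assert np.all((a.consensus >= 0) & (a.consensus <= 1))
    assert np.allclose(a.consensus, a.consensus.T)
    assert np.all(np.diag(a.consensus) == 1.0)
    assert np.all(a.connectivity_counts <= a.indicator_counts)


def test_consensus_sweep_consistent_with_single_k():
    m = two_block_matrix(seed=4)
    sweep = consensus_sweep(m, [2, 3], n_iter=25, seed=9)
    single = build_consensus(m, 2, n_iter=25, seed=9)
    assert np.array_equal(sweep[2].consensus, single.consensus)


# ---------------------------------------------------------------- k selection
def test_select_k_from_areas_hand_example():
    sel = select_k_from_areas([2, 3, 4], [0.5, 0.7, 0.72])
    assert sel.deltas[0] == pytest.approx(0.5)
    assert sel.deltas[1] == pytest.approx(0.4)
    assert sel.deltas[2] == pytest.approx(0.72 / 0.7 - 1)
    assert sel.chosen_k == 3


def test_select_k_fallback_to_two():
    sel = select_k_from_areas([2, 3, 4], [0.6, 0.66, 0.70])
    assert sel.chosen_k == 2


def test_select_k_requires_consecutive_from_two():
    with pytest.raises(ValueError):
        select_k_from_areas([3, 4], [0.5, 0.6])
    with pytest.raises(ValueError):
        select_k_from_areas([2], [0.5])


def test_cdf_area_of_binary_consensus():
    """All-zero off-diagonal consensus has CDF area 1 (mass at 0)."""
    m = two_block_matrix()
    res = build_consensus(m, k=2, n_iter=40, subsample_fraction=1.0, seed=2)
    # perfectly separable: entries are exactly 0 or 1
    n11 = 2 * (5 * 4 // 2)  # within-block pairs, both triangles /2
    area = consensus_cdf_area(res)
    frac_zero = 1 - n11 / (10 * 9 // 2)
    assert area == pytest.approx(frac_zero, abs=1e-12)


# ---------------------------------------------------------------- assignment
def test_assign_subtypes_recovers_blocks():
    m = two_block_matrix(n_per_block=6, seed=8)
    res = build_consensus(m, k=2, n_iter=40, seed=3)
    asg = assign_subtypes(res)
    labels = asg.labels.to_numpy()
    assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
    assert labels[0] != labels[-1]


def test_assign_subtypes_renumbers_by_size():
    rng = np.random.default_rng(0)
    base = rng.normal(size=8)
    cols = [base + rng.normal(0, 1e-6, 8) for _ in range(7)]
    cols += [-base + rng.normal(0, 1e-6, 8) for _ in range(3)]
    m = ExpressionMatrix(
        [f"g{i}" for i in range(8)], [f"s{i}" for i in range(10)], np.column_stack(cols)
    )
    res = build_consensus(m, k=2, n_iter=30, seed=1)
    labels = assign_subtypes(res).labels.to_numpy()
    assert np.all(labels[:7] == 1) and np.all(labels[7:] == 2)


# ---------------------------------------------------------------- silhouette
def test_silhouette_duplicate_blocks_all_one():
    m = two_block_matrix()
    d = correlation_distance(m)
    labels = np.array([1] * 5 + [2] * 5)
    s = silhouette_widths(d, labels)
    assert np.all(s.to_numpy() > 0.999)


def test_silhouette_equidistant_zero():
    d = np.array([[0, 1, 1.0], [1, 0, 1], [1, 1, 0]])
    s = silhouette_widths(DistanceMatrix(list("abc"), d), np.array([1, 1, 2]))
    # sample c alone -> 0; a and b have a=1, b=1 -> 0
    assert np.allclose(s.to_numpy(), 0.0)


def test_silhouette_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = 8
        x = rng.uniform(0.1, 3, (n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = rng.integers(1, 4, n)
        if len(set(labels)) < 2:
            continue
        ours = silhouette_widths(DistanceMatrix([str(i) for i in range(n)], d), labels)
        oracle = silhouette_brute(d, labels)
        assert np.allclose(ours.to_numpy(), oracle, atol=1e-12)


def test_silhouette_single_cluster_errors():
    d = DistanceMatrix(list("ab"), np.array([[0, 1.0], [1, 0]]))
    with pytest.raises(ValueError):
        silhouette_widths(d, np.array([1, 1]))


# ---------------------------------------------------------------- sigclust
def test_sigclust_p_bounds():
    rng = np.random.default_rng(0)
    m = ExpressionMatrix(
        [f"g{i}" for i in range(5)],
        [f"s{i}" for i in range(12)],
        rng.normal(size=(5, 12)),
    )
    p = sigclust(m, n_sim=49, seed=1)
    assert 1 / 50 <= p <= 1


def test_sigclust_detects_separated_clusters():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(10, 40))
    data[0, 20:] += 6.0  # 6-sigma shift in one coordinate
    m = ExpressionMatrix(
        [f"g{i}" for i in range(10)], [f"s{i}" for i in range(40)], data
    )
    labels = np.array([1] * 20 + [2] * 20)
    p = sigclust(m, labels=labels, n_sim=99, seed=3)
    assert p <= 0.01


def test_sigclust_null_not_small_on_single_gaussian():
    rng = np.random.default_rng(4)
    m = ExpressionMatrix(
        [f"g{i}" for i in range(10)], [f"s{i}" for i in range(40)],
        rng.normal(size=(10, 40)),
    )
    assert sigclust(m, n_sim=99, seed=5) > 0.05


def test_sigclust_validates_cluster_sizes():
    rng = np.random.default_rng(0)
    m = ExpressionMatrix(["g0", "g1"], [f"s{i}" for i in range(6)], rng.normal(size=(2, 6)))
    with pytest.raises(ValueError):
        sigclust(m, labels=np.array([1, 1, 1, 1, 1, 2]), n_sim=19, seed=0)
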