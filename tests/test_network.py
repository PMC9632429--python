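"""Correlation, soft adjacency, TOM, thresholding, clustering, subnetworks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from coldacclim import (
    association_strength,
    cluster,
    cluster_trait_correlation,
    correlate,
    eigengene,
    neighborhood,
    soft_adjacency,
    subnetwork,
    threshold_top,
    tom,
)
from coldacclim.network import AssociationNetwork

import networkx as nx


def _df(arr, prefix="n"):
    names = [f"{prefix}{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=names, columns=cols)


def _net_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_weighted_edges_from([(u, v, 1.0) for u, v in edges])
    return AssociationNetwork(graph=g, threshold_quantile=0.99, cutoff=1.0)


# ------------------------------------------------------------- correlate
def test_correlate_self_and_negation():
    rng = np.random.default_rng(0)
    x = _df(rng.normal(size=(1, 8)))
    r, _ = correlate(pd.concat([x, -x.set_index(pd.Index(["m0"]))]))
    assert r.iloc[0, 0] == pytest.approx(1.0)
    assert r.iloc[0, 1] == pytest.approx(-1.0)


def test_correlate_matches_pairwise_oracle():
    rng = np.random.default_rng(3)
    data = _df(rng.normal(size=(10, 6)))
    r, p = correlate(data)
    for i in range(10):
        for j in range(10):
            ref = stats.pearsonr(data.iloc[i], data.iloc[j])
            assert r.iloc[i, j] == pytest.approx(ref.statistic, abs=1e-12)
            if i != j:
                assert p.iloc[i, j] == pytest.approx(ref.pvalue, abs=1e-10)


def test_correlate_zero_variance_row_marked_undefined():
    data = _df(np.vstack([np.ones(6), np.arange(6.0)]))
    r, p = correlate(data)
    assert np.isnan(r.iloc[0]).all() and np.isnan(p.iloc[0]).all()
    assert r.iloc[1, 1] == pytest.approx(1.0)


# -------------------------------------------------------- soft adjacency
def test_soft_adjacency_arithmetic():
    data = _df(np.vstack([np.arange(6.0), np.arange(6.0) * 2]))
    a = soft_adjacency(data, beta=6)
    assert a.iloc[0, 1] == pytest.approx(1.0)  # r = 1, beta = 6
    assert a.iloc[0, 0] == 0.0  # zero diagonal
    # signed option: r = 1 -> ((1+1)/2)^beta = 1
    assert soft_adjacency(data, beta=4, signed=True).iloc[0, 1] == pytest.approx(1.0)


def test_soft_adjacency_matches_elementwise_computation():
    rng = np.random.default_rng(5)
    data = _df(rng.normal(size=(8, 10)))
    r = np.corrcoef(data.to_numpy())
    for beta, signed in ((2, False), (6, False), (6, True)):
        a = soft_adjacency(data, beta=beta, signed=signed).to_numpy()
        expected = np.abs(r) ** beta if not signed else ((1 + r) / 2) ** beta
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(a, expected, atol=1e-12)


# ------------------------------------------------------------------- TOM
def _tom_oracle(a):
    n = len(a)
    k = a.sum(axis=1)
    t = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def test_tom_hand_examples():
    # two nodes, single unit edge -> TOM = 1
    a = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert tom(_df(a)).iloc[0, 1] == pytest.approx(1.0)
    # no edge, no shared neighbors -> 0
    assert tom(_df(np.zeros((2, 2)))).iloc[0, 1] == 0.0
    # complete unit triangle -> all TOM = 1
    tri = np.ones((3, 3)) - np.eye(3)
    t = tom(_df(tri))
    assert np.allclose(t.to_numpy(), 1.0)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(11)
    for n in (4, 8, 12):
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        t = tom(_df(a)).to_numpy()
        assert np.allclose(t, _tom_oracle(a), atol=1e-12)
        assert np.allclose(t, t.T) and t.min() >= 0 and t.max() <= 1


def test_tom_rejects_asymmetric_input():
    a = np.zeros((3, 3))
    a[0, 1] = 0.5
    with pytest.raises(ValueError):
        tom(_df(a))


# ------------------------------------------------------------ thresholding
def _random_tom(n, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return tom(_df(a))


def test_threshold_retains_expected_edge_count():
    t = _random_tom(21)  # 210 candidate pairs
    net = threshold_top(t, quantile=0.99)
    assert net.graph.number_of_edges() >= math.ceil(0.01 * 210)
    all_edges = threshold_top(t, quantile=0.0)
    assert all_edges.graph.number_of_edges() == 210


def test_threshold_keeps_ties_at_cutoff():
    t = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
    t.iloc[0, 1] = t.iloc[1, 0] = 0.5  # 5 pairs at 1.0, one at 0.5
    net = threshold_top(t, quantile=0.9)  # m = 1 but five ties at the cutoff
    assert net.graph.number_of_edges() == 5


def test_threshold_identical_weights_error():
    t = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError):
        threshold_top(t, quantile=0.99)


def test_raising_quantile_never_adds_edges():
    t = _random_tom(15, seed=3)
    prev = None
    for q in (0.5, 0.8, 0.95, 0.99):
        edges = set(map(frozenset, threshold_top(t, q).graph.edges))
        if prev is not None:
            assert edges <= prev
        prev = edges


def test_degree_conservation():
    t = _random_tom(15, seed=4)
    net = threshold_top(t, 0.9)
    assert sum(d for _, d in net.graph.degree) == 2 * net.graph.number_of_edges()


# -------------------------------------------------------------- clustering
def _two_block_data(n_per=10, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 12)
    block1 = np.sin(2 * np.pi * t) + rng.normal(0, noise, (n_per, 12))
    block2 = np.cos(2 * np.pi * 3 * t) + rng.normal(0, noise, (n_per, 12))
    return _df(np.vstack([block1, block2])), [0] * n_per + [1] * n_per


def test_cluster_recovers_planted_blocks():
    data, labels = _two_block_data(noise=0.0)
    t = tom(soft_adjacency(data, beta=6))
    assignment = cluster(t, n_clusters=2)
    assert adjusted_rand_score(labels, assignment) == 1.0


def test_cluster_edge_cases():
    data, _ = _two_block_data(n_per=3)
    t = tom(soft_adjacency(data, beta=6))
    singletons = cluster(t, n_clusters=len(t))
    assert singletons.nunique() == len(t)
    with pytest.raises(ValueError):
        cluster(t, n_clusters=len(t) + 1)
    # all-identical rows: TOM degenerate but k = 1 must not crash
    same = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
    assert cluster(same, n_clusters=1).nunique() == 1


def test_planted_blocks_keep_top_edges_within_block():
    """With two disconnected planted blocks, >= 90% of retained top edges are
    within-block."""
    data, labels = _two_block_data(n_per=12, noise=0.1, seed=2)
    block = dict(zip(data.index, labels))
    net = threshold_top(tom(soft_adjacency(data, beta=6)), quantile=0.9)
    edges = list(net.graph.edges)
    within = sum(block[u] == block[v] for u, v in edges)
    assert within / len(edges) >= 0.9


# ---------------------------------------------------------------- eigengene
def test_eigengene_of_identical_genes_is_their_profile():
    profile = np.sin(np.linspace(0, 3, 10))
    data = _df(np.tile(profile, (4, 1)))
    e = eigengene(data)
    z = (profile - profile.mean()) / profile.std()
    assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0)
    assert np.corrcoef(e, data.mean(axis=0))[0, 1] >= 0  # orientation


def test_single_gene_cluster_eigengene_is_standardized_profile():
    data = _df(np.arange(8.0).reshape(1, -1))
    e = eigengene(data)
    assert e.mean() == pytest.approx(0.0, abs=1e-12)
    assert np.corrcoef(e, data.iloc[0])[0, 1] == pytest.approx(1.0)


def test_cluster_trait_correlation_finds_planted_driver():
    rng = np.random.default_rng(9)
    profile = np.sin(np.linspace(0, 4, 12))
    genes = _df(profile + rng.normal(0, 0.1, (6, 12)))
    clusters = pd.Series([1] * 6, index=genes.index)
    traits = _df(np.vstack([profile, rng.normal(0, 1, 12)]), prefix="t")
    r, p = cluster_trait_correlation(clusters, genes, traits)
    assert abs(r.loc[1, "t0"]) >= 0.9
    assert p.loc[1, "t0"] <= 0.05


# ----------------------------------------------- subnetworks & neighborhoods
def test_subnetwork_and_as_closed_forms():
    k5 = _net_from_edges([(a, b) for a in "abcde" for b in "abcde" if a < b])
    sub = subnetwork(k5, set("abcde"))
    assert len(sub.connected_members) == 5 and sub.avg_degree == 4.0
    assert association_strength(sub) == pytest.approx(4 / 5)

    star = _net_from_edges([("h", "a"), ("h", "b"), ("h", "c")])
    sub = subnetwork(star, {"h", "a", "b", "c"})
    assert sub.avg_degree == pytest.approx(1.5)
    assert association_strength(sub) == pytest.approx(1.5 / 4)

    isolated = _net_from_edges([("x", "y")], nodes=["z"])
    sub = subnetwork(isolated, {"z"})
    assert sub.connected_members == set()
    assert association_strength(sub) == 0.0


def test_as_bounds_and_completeness():
    rng = np.random.default_rng(13)
    for trial in range(20):
        n = rng.integers(3, 9)
        nodes = [f"v{i}" for i in range(n)]
        possible = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        take = rng.random(len(possible)) < 0.5
        edges = [e for e, t in zip(possible, take) if t]
        net = _net_from_edges(edges, nodes=nodes)
        sub = subnetwork(net, set(nodes))
        as_val = association_strength(sub)
        m = len(sub.connected_members)
        assert 0.0 <= as_val <= (max(m, 1) - 1) / max(m, 1) + 1e-12
        if len(edges) == len(possible):
            assert as_val == pytest.approx((n - 1) / n)


def test_as_denominator_variants():
    star = _net_from_edges([("h", "a"), ("h", "b")], nodes=["i"])
    sub = subnetwork(star, {"h", "a", "b", "i"})
    avg = (2 + 1 + 1) / 3
    assert association_strength(sub, "connected") == pytest.approx(avg / 3)
    assert association_strength(sub, "all_members") == pytest.approx(avg / 4)


def test_neighborhood_chain_and_clique():
    chain = _net_from_edges([("a", "b"), ("b", "c")])
    assert neighborhood(chain, {"a"}, "immediate") == {"b"}
    assert neighborhood(chain, {"a"}, "secondary") == {"c"}
    k5 = _net_from_edges([(a, b) for a in "abcde" for b in "abcde" if a < b])
    assert neighborhood(k5, {"a"}, "immediate") == set("bcde")
    assert neighborhood(k5, {"a"}, "secondary") == set()
    with pytest.raises(KeyError):
        neighborhood(chain, {"nope"}, "immediate")


def test_disconnected_planted_blocks_share_no_neighbors():
    """Seeds from one planted block reach no node of a disconnected block even
    at the secondary neighborhood."""
    data, labels = _two_block_data(n_per=8, noise=0.05, seed=6)
    block = dict(zip(data.index, labels))
    net = threshold_top(tom(soft_adjacency(data, beta=6)), quantile=0.8)
    seeds = {n for n in data.index if block[n] == 0}
    reach = neighborhood(net, seeds, "immediate") | neighborhood(net, seeds, "secondary")
    assert not {n for n in reach if block[n] == 1}
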