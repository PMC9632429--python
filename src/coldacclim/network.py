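"""Gene–lipid association networks via topological overlap.

Pipeline: Pearson correlation over samples → soft-threshold adjacency
(|r|^β, unsigned by default) → topological overlap matrix (TOM) → retain the
top-quantile edges (default top 1%) → hierarchical clustering, cluster–trait
correlation, subnetwork association strength, and neighborhood propagation.

The TOM variant is the unsigned form

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  TOM_ii = 1

with k_i = Σ_u a_iu, which rewards node pairs that share neighbors even when
their direct adjacency is weak.  The *association strength* of a subnetwork
of n nodes is its average within-group connection degree divided by n; a
complete subgraph attains the maximum (n − 1)/n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

#: the five binary condition-indicator traits over samples
CONDITION_INDICATORS = (
    "cold_treatment",
    "winter_habit",
    "spring_habit",
    "winter_habit_cold",
    "spring_habit_cold",
)


def condition_indicator_traits(samples: pd.DataFrame, design) -> pd.DataFrame:
    """0/1 indicator traits (rows) over samples from design metadata."""
    winter = {w for w, _ in design.nil_pairs()}
    cold = (samples["treatment"] == "cold").astype(int)
    is_winter = samples["genotype"].isin(winter).astype(int)
    out = pd.DataFrame(
        {
            "cold_treatment": cold,
            "winter_habit": is_winter,
            "spring_habit": 1 - is_winter,
            "winter_habit_cold": cold * is_winter,
            "spring_habit_cold": cold * (1 - is_winter),
        }
    ).T
    out.columns = samples.index
    return out


def correlate(
    rows_a: pd.DataFrame, rows_b: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-by-row Pearson r and two-sided t-test p matrices.

    Zero-variance rows yield NaN r/p (excluded from downstream thresholding).
    """
    b = rows_a if rows_b is None else rows_b
    if list(rows_a.columns) != list(b.columns):
        raise ValueError("sample columns must match")
    n = rows_a.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")

    def standardized(df: pd.DataFrame) -> np.ndarray:
        x = df.to_numpy(float)
        x = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((x**2).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = x / norm
        z[norm[:, 0] == 0.0] = np.nan
        return z

    za, zb = standardized(rows_a), standardized(b)
    r = np.clip(za @ zb.T, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * math.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    rf = pd.DataFrame(r, index=rows_a.index, columns=b.index)
    pf = pd.DataFrame(p, index=rows_a.index, columns=b.index)
    return rf, pf


def soft_adjacency(
    data: pd.DataFrame, beta: int = 6, signed: bool = False
) -> pd.DataFrame:
    """Soft-threshold adjacency from row correlations.

    Unsigned: a_ij = |r_ij|^β; signed: a_ij = ((1 + r_ij)/2)^β.  Diagonal is
    zeroed for the TOM step; undefined correlations become 0 with a warning.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r, _ = correlate(data)
    rv = r.to_numpy(float)
    n_undef = int(np.isnan(rv).sum())
    if n_undef:
        log.warning("%d undefined correlations set to adjacency 0", n_undef)
        rv = np.nan_to_num(rv)
    a = np.abs(rv) ** beta if not signed else ((1.0 + rv) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    a = adjacency.to_numpy(float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


@dataclass
class AssociationNetwork:
    """Thresholded TOM network over gene and lipid nodes."""

    graph: nx.Graph
    threshold_quantile: float
    cutoff: float
    cluster_of_node: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": u, "node_b": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def threshold_top(tom_matrix: pd.DataFrame, quantile: float = 0.99) -> AssociationNetwork:
    """Retain the top (1 − quantile) fraction of upper-triangle TOM weights.

    The cutoff is the m-th largest weight with m = ceil((1 − q) × #pairs);
    all ties at the cutoff are kept.  All nodes appear in the graph, including
    isolated ones.
    """
    if not (0.0 <= quantile < 1.0):
        raise ValueError("quantile must lie in [0, 1)")
    names = list(tom_matrix.index)
    t = tom_matrix.to_numpy(float)
    iu, ju = np.triu_indices(len(names), k=1)
    w = t[iu, ju]
    if len(w) == 0:
        raise ValueError("need at least two nodes")
    if np.ptp(w) == 0.0:
        raise ValueError("all weights identical: top-quantile cutoff undefined")
    m = max(1, math.ceil((1.0 - quantile) * len(w)))
    cutoff = float(np.sort(w)[::-1][m - 1])
    keep = w >= cutoff

    g = nx.Graph()
    g.add_nodes_from(names)
    for i, j, weight in zip(iu[keep], ju[keep], w[keep]):
        g.add_edge(names[i], names[j], weight=float(weight))
    return AssociationNetwork(graph=g, threshold_quantile=quantile, cutoff=cutoff)


def cluster(
    tom_matrix: pd.DataFrame, n_clusters: int = 50, height: float | None = None
) -> pd.Series:
    """Average-linkage hierarchical clustering on dissimilarity 1 − TOM.

    Cut to ``n_clusters`` flat clusters, or by ``height`` when given.
    """
    n = len(tom_matrix)
    if height is None and n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} nodes")
    d = 1.0 - tom_matrix.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    if height is not None:
        labels = fcluster(z, t=height, criterion="distance")
    else:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=tom_matrix.index, name="cluster")


def eigengene(member_rows: pd.DataFrame) -> pd.Series:
    """First principal component over samples of a standardized cluster.

    Oriented to correlate non-negatively with the cluster mean profile; a
    single-member cluster returns that row's standardized profile.
    """
    x = member_rows.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    z = (x - mu) / sd
    if z.shape[0] == 1:
        e = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return pd.Series(e, index=member_rows.columns)


def cluster_trait_correlation(
    clusters: pd.Series, expr_rows: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eigengene-vs-trait Pearson r and p per cluster × trait."""
    covered = clusters.index.intersection(expr_rows.index)
    if len(covered) < len(clusters):
        raise ValueError("clusters reference rows absent from the expression data")
    eigs = {}
    for cid in sorted(clusters.unique()):
        members = clusters.index[clusters == cid]
        eigs[cid] = eigengene(expr_rows.loc[members])
    eig_df = pd.DataFrame(eigs).T
    eig_df.index.name = "cluster"
    return correlate(eig_df, traits)


@dataclass
class Subnetwork:
    """Induced subgraph summary used by the association-strength statistic."""

    members: set[str]
    graph: nx.Graph
    connected_members: set[str]
    avg_degree: float

    @property
    def n_members(self) -> int:
        return len(self.members)


def subnetwork(net: AssociationNetwork, members: set[str]) -> Subnetwork:
    """Induce the subgraph on ``members``; missing members are logged."""
    if not members:
        raise ValueError("empty subnetwork membership")
    present = members & net.nodes
    missing = members - present
    if missing:
        log.info("%d subnetwork members absent from the network", len(missing))
    g = net.graph.subgraph(present).copy()
    connected = {n for n in g.nodes if g.degree[n] >= 1}
    avg = float(np.mean([g.degree[n] for n in connected])) if connected else 0.0
    return Subnetwork(members=present, graph=g, connected_members=connected, avg_degree=avg)


def association_strength(sub: Subnetwork, denominator: str = "connected") -> float:
    """AS = average within-group degree / subnetwork size.

    ``denominator`` chooses the population: nodes with ≥ 1 within-group edge
    ("connected", default) or all members ("all_members").
    """
    if denominator == "connected":
        n = len(sub.connected_members)
    elif denominator == "all_members":
        n = len(sub.members)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n == 0:
        log.warning("empty subnetwork population: AS defined as 0")
        return 0.0
    return sub.avg_degree / n


def neighborhood(
    net: AssociationNetwork, seeds: set[str], order: str = "immediate"
) -> set[str]:
    """Immediate or secondary neighborhood of a seed set.

    immediate = neighbors of seeds minus seeds; secondary = neighbors of the
    immediate set minus seeds and the immediate set.
    """
    unknown = seeds - net.nodes
    if unknown:
        raise KeyError(f"unknown seed node {sorted(unknown)[0]!r}")
    immediate = set()
    for s in seeds:
        immediate |= set(net.graph.neighbors(s))
    immediate -= seeds
    if order == "immediate":
        return immediate
    if order == "secondary":
        secondary = set()
        for s in immediate:
            secondary |= set(net.graph.neighbors(s))
        return secondary - seeds - immediate
    raise ValueError(f"unknown neighborhood order {order!r}")
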