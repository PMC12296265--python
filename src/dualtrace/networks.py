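"""Correlation-network statistics downstream of regional count tables.

Region-by-region Pearson correlation matrices of volume-normalized counts
with asymptotic one-sample t-test p-values; functional networks thresholded
on correlation strength and significance; per-node degree, clustering,
nodal efficiency, and betweenness; threshold-sweep stability curves;
permutation tests of group correlation differences (label shuffles); a
two-sample Kolmogorov-Smirnov comparison of a region's correlation
distribution; and two-community detection by the sign of the leading
eigenvector of the modularity matrix.

Topology metrics are computed on the unweighted, sign-ignored skeleton of
the thresholded graph; the signed correlation is carried on edges as a
weight for presentation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model import RegionCountTable


# --------------------------------------------------------------------------
# correlation matrices


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations between regions for one group.

    ``r`` and ``p`` are symmetric with unit/one diagonals; ``n`` holds the
    per-pair count of complete mouse observations. Pairs with fewer than
    three complete observations (or a constant region) are NaN.
    """

    regions: list[str]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray

    def index(self, region: str) -> int:
        return self.regions.index(region)

    def region_values(self, region: str) -> np.ndarray:
        """The region's off-diagonal correlation values (NaNs dropped)."""
        i = self.index(region)
        vals = np.delete(self.r[i], i)
        return vals[~np.isnan(vals)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.regions, columns=self.regions)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def correlation_pvalue(r, n) -> np.ndarray | float:
    """Two-sided asymptotic p-value for a Pearson correlation.

    Uses the one-sample t transform t = r sqrt(n-2) / sqrt(1-r²) with n-2
    degrees of freedom; |r| = 1 maps to p = 0 by the limit convention.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n)
    if np.any(n_arr < 3):
        raise ValueError("correlation p-value requires n >= 3")
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("|r| must be <= 1")
    r_clip = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_clip * np.sqrt(n_arr - 2) / np.sqrt(1.0 - r_clip**2)
        p = 2.0 * stats.t.sf(np.abs(t), np.asarray(n_arr) - 2)
    p = np.where(np.abs(r_clip) >= 1.0, 0.0, p)
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def density_pivot(table: RegionCountTable, channel: str | None = None) -> pd.DataFrame:
    """Mouse × region matrix of densities for one channel."""
    df = table.df
    if channel is None:
        channels = df["channel"].unique()
        if len(channels) != 1:
            raise ValueError(f"table has several channels {list(channels)}; pick one")
        channel = channels[0]
    sub = df[df["channel"] == channel]
    return sub.pivot_table(index="mouse_id", columns="region", values="density",
                           aggfunc="first")


def pairwise_correlations(
    table: RegionCountTable, channel: str | None = None
) -> CorrelationMatrix:
    """Pearson correlations of per-mouse densities between all region pairs.

    Observations are pairwise-complete: a pair's n counts the mice with a
    density for both regions. Pairs with n < 3 or with a constant region are
    reported missing (NaN) with a warning.
    """
    pivot = density_pivot(table, channel)
    regions = list(pivot.columns)
    X = pivot.to_numpy(dtype=float)
    k = len(regions)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(n, (~np.isnan(X)).sum(axis=0))
    degenerate = []
    for i, j in combinations(range(k), 2):
        mask = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
        nij = int(mask.sum())
        n[i, j] = n[j, i] = nij
        if nij < 3:
            degenerate.append((regions[i], regions[j], "n < 3"))
            continue
        xi, xj = X[mask, i], X[mask, j]
        if np.std(xi) == 0 or np.std(xj) == 0:
            degenerate.append((regions[i], regions[j], "constant region"))
            continue
        rij = float(np.corrcoef(xi, xj)[0, 1])
        r[i, j] = r[j, i] = rij
        pij = correlation_pvalue(rij, nij)
        p[i, j] = p[j, i] = pij
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} region pair(s) reported missing "
            f"(first: {degenerate[0]})",
            stacklevel=2,
        )
    return CorrelationMatrix(regions=regions, r=r, p=p, n=n)


# --------------------------------------------------------------------------
# thresholded functional networks


@dataclass
class FunctionalNetwork:
    """Simple graph over regions; an edge survives when |r| (or signed r)
    exceeds r_min and its p-value beats alpha. Edge attribute ``r`` keeps
    the signed correlation."""

    graph: nx.Graph
    r_min: float
    alpha: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"region_a": a, "region_b": b, "r": d["r"], "p": d["p"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["region_a", "region_b", "r", "p"])


def build_network(
    corr: CorrelationMatrix,
    r_min: float = 0.9,
    alpha: float = 0.01,
    use_absolute: bool = True,
) -> FunctionalNetwork:
    """Threshold a correlation matrix into a functional network.

    By default both strongly correlated and strongly anti-correlated pairs
    survive (|r| > r_min); set ``use_absolute=False`` for the signed rule
    r > r_min.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= r_min < 1:
        raise ValueError("r_min must lie in [0, 1)")
    G = nx.Graph()
    G.add_nodes_from(corr.regions)
    k = len(corr.regions)
    for i, j in combinations(range(k), 2):
        rij, pij = corr.r[i, j], corr.p[i, j]
        if np.isnan(rij) or np.isnan(pij):
            continue
        strength = abs(rij) if use_absolute else rij
        if strength > r_min and pij < alpha:
            G.add_edge(corr.regions[i], corr.regions[j], r=float(rij), p=float(pij))
    return FunctionalNetwork(graph=G, r_min=r_min, alpha=alpha)


# --------------------------------------------------------------------------
# node and network topology metrics


@dataclass
class NodeMetrics:
    per_node: pd.DataFrame      # node, degree, clustering, efficiency, betweenness
    mean_degree: float
    mean_clustering: float
    global_efficiency: float
    mean_betweenness: float


def node_metrics(network: FunctionalNetwork | nx.Graph) -> NodeMetrics:
    """Degree, clustering coefficient, nodal efficiency, and betweenness.

    All computed on the unweighted skeleton. Nodal efficiency is the mean
    over all other nodes of the inverse shortest-path length (1/∞ = 0 for
    unreachable pairs); global efficiency is the mean nodal efficiency.
    Betweenness is unnormalized, each unordered pair counted once.
    """
    G = network.graph if isinstance(network, FunctionalNetwork) else network
    nodes = list(G.nodes)
    n = len(nodes)
    degree = dict(G.degree())
    clustering = nx.clustering(G)
    betweenness = nx.betweenness_centrality(G, normalized=False)
    efficiency = {}
    for v in nodes:
        if n <= 1:
            efficiency[v] = 0.0
            continue
        lengths = nx.single_source_shortest_path_length(G, v)
        efficiency[v] = sum(
            1.0 / d for u, d in lengths.items() if u != v
        ) / (n - 1)
    per_node = pd.DataFrame(
        {
            "node": nodes,
            "degree": [degree[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "efficiency": [efficiency[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        }
    )
    return NodeMetrics(
        per_node=per_node,
        mean_degree=float(per_node["degree"].mean()) if n else 0.0,
        mean_clustering=float(per_node["clustering"].mean()) if n else 0.0,
        global_efficiency=float(per_node["efficiency"].mean()) if n else 0.0,
        mean_betweenness=float(per_node["betweenness"].mean()) if n else 0.0,
    )


def threshold_sweep(
    corrs: dict[str, CorrelationMatrix],
    alphas: list[float],
    r_min: float = 0.9,
    use_absolute: bool = True,
) -> pd.DataFrame:
    """Network-mean metrics per group across a sweep of alpha thresholds."""
    if list(alphas) != sorted(alphas):
        raise ValueError("alphas must be sorted ascending")
    rows = []
    for group, corr in corrs.items():
        for alpha in alphas:
            net = build_network(corr, r_min=r_min, alpha=alpha, use_absolute=use_absolute)
            m = node_metrics(net)
            rows.append(
                {
                    "group": group,
                    "alpha": alpha,
                    "mean_degree": m.mean_degree,
                    "mean_clustering": m.mean_clustering,
                    "global_efficiency": m.global_efficiency,
                    "mean_betweenness": m.mean_betweenness,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# permutation analysis of correlation differences


@dataclass
class PermutationResult:
    """Observed group correlation differences with shuffle p-values.

    ``d_obs`` is r(group B) − r(group A) per pair; p-values are two-sided on
    |d| with the add-one estimator p = (#{|d_null| ≥ |d_obs|} + 1) / (N + 1).
    """

    regions: list[str]
    d_obs: np.ndarray
    p: np.ndarray
    n_permutations: int
    seed: int | None
    group_a: str = "A"
    group_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.regions)
        for i, j in combinations(range(k), 2):
            if np.isnan(self.d_obs[i, j]):
                continue
            rows.append(
                {
                    "region_a": self.regions[i],
                    "region_b": self.regions[j],
                    "d": self.d_obs[i, j],
                    "p": self.p[i, j],
                }
            )
        return pd.DataFrame(rows, columns=["region_a", "region_b", "d", "p"])

    def pair(self, region_a: str, region_b: str) -> tuple[float, float]:
        i, j = self.regions.index(region_a), self.regions.index(region_b)
        return float(self.d_obs[i, j]), float(self.p[i, j])


def _corr_nan_aware(X: np.ndarray) -> np.ndarray:
    if np.isnan(X).any():
        return pd.DataFrame(X).corr().to_numpy()
    with np.errstate(invalid="ignore"):
        return np.corrcoef(X, rowvar=False)


def permutation_correlation_diff(
    table_a: RegionCountTable,
    table_b: RegionCountTable,
    n_permutations: int = 1000,
    seed: int | None = None,
    channel: str | None = None,
) -> PermutationResult:
    """Permutation test of per-pair correlation differences between groups.

    The observed statistic is d = r_B − r_A for every region pair. The null
    distribution shuffles the group labels of the pooled mice (preserving
    group sizes) and recomputes d per shuffle. No multiple-testing
    correction is applied.
    """
    pa = density_pivot(table_a, channel)
    pb = density_pivot(table_b, channel)
    shared = [c for c in pa.columns if c in set(pb.columns)]
    if not shared:
        raise ValueError("the two groups share no regions")
    na, nb = pa.shape[0], pb.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 mice")
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give a coarse p-value resolution",
            stacklevel=2,
        )
    Xa = pa[shared].to_numpy(dtype=float)
    Xb = pb[shared].to_numpy(dtype=float)
    pooled = np.vstack([Xa, Xb])
    d_obs = _corr_nan_aware(Xb) - _corr_nan_aware(Xa)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(d_obs)
    total = na + nb
    for _ in range(n_permutations):
        perm = rng.permutation(total)
        Pa = pooled[perm[:na]]
        Pb = pooled[perm[na:]]
        d_null = _corr_nan_aware(Pb) - _corr_nan_aware(Pa)
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(d_null) >= np.abs(d_obs)).astype(float)
    p = (exceed + 1.0) / (n_permutations + 1.0)
    p[np.isnan(d_obs)] = np.nan
    np.fill_diagonal(p, np.nan)
    return PermutationResult(
        regions=shared,
        d_obs=d_obs,
        p=p,
        n_permutations=n_permutations,
        seed=seed,
        group_a=str(table_a.df["group"].iloc[0]),
        group_b=str(table_b.df["group"].iloc[0]),
    )


# --------------------------------------------------------------------------
# distribution comparison and communities


def ks_region_distributions(
    corr_a: CorrelationMatrix, corr_b: CorrelationMatrix, region: str
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test comparing one region's correlation
    values (to every other region, self excluded) between the two groups."""
    va = corr_a.region_values(region)
    vb = corr_b.region_values(region)
    if len(va) < 3 or len(vb) < 3:
        raise ValueError(
            f"region {region!r} needs >= 3 correlations per group "
            f"(got {len(va)} and {len(vb)})"
        )
    res = stats.ks_2samp(va, vb)
    return float(res.statistic), float(res.pvalue)


def leading_eigenvector_partition(
    network: FunctionalNetwork | nx.Graph,
) -> dict[str, int]:
    """Two-community split by the sign of the modularity matrix's leading
    eigenvector.

    B = A − k kᵀ / (2m) on the unweighted skeleton; vertices are separated
    by the sign of their element in the eigenvector of the largest positive
    eigenvalue. If the leading eigenvalue is not positive the graph is left
    as a single community. One-level split only (no recursion, no
    refinement); an empty graph (no edges) is an error.
    """
    G = network.graph if isinstance(network, FunctionalNetwork) else network
    nodes = list(G.nodes)
    if G.number_of_edges() == 0:
        raise ValueError("community detection requires a graph with >= 1 edge")
    A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    two_m = k.sum()
    B = A - np.outer(k, k) / two_m
    eigvals, eigvecs = np.linalg.eigh(B)
    if eigvals[-1] <= 1e-12:
        return {v: 0 for v in nodes}
    lead = eigvecs[:, -1]
    return {v: int(lead[i] >= 0) for i, v in enumerate(nodes)}


def modularity(graph: nx.Graph, membership: dict[str, int]) -> float:
    """Newman modularity Q of a partition on the unweighted skeleton."""
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    B = A - np.outer(k, k) / two_m
    s = np.array([membership[v] for v in nodes])
    q = 0.0
    for c in set(s.tolist()):
        idx = np.where(s == c)[0]
        q += B[np.ix_(idx, idx)].sum()
    return float(q / two_m)
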