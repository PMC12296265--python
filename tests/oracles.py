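"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive path enumeration, direct
formula evaluation, full enumeration of 2-partitions — and shares no code
with the package under test.
"""

from __future__ import annotations

import math
from itertools import combinations

from scipy.integrate import quad


# --------------------------------------------------------------------------
# graph metrics by exhaustive enumeration


def _neighbors(n_nodes: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    adj = [set() for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _all_simple_paths(adj, s, t):
    paths = []

    def walk(node, seen, path):
        if node == t:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                path.append(nxt)
                walk(nxt, seen, path)
                path.pop()
                seen.discard(nxt)

    walk(s, {s}, [s])
    return paths


def brute_force_metrics(n_nodes: int, edges: list[tuple[int, int]]) -> dict:
    """Degree, clustering, nodal/global efficiency, and betweenness by
    exhaustive simple-path enumeration (feasible for ~8 nodes)."""
    adj = _neighbors(n_nodes, edges)
    degree = [len(adj[v]) for v in range(n_nodes)]

    clustering = []
    for v in range(n_nodes):
        d = degree[v]
        if d < 2:
            clustering.append(0.0)
            continue
        links = sum(
            1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a]
        )
        clustering.append(2.0 * links / (d * (d - 1)))

    # all shortest paths per pair, from full simple-path enumeration
    shortest: dict[tuple[int, int], list[list[int]]] = {}
    for s, t in combinations(range(n_nodes), 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths) - 1
        shortest[(s, t)] = [p for p in paths if len(p) - 1 == d]

    efficiency = []
    for v in range(n_nodes):
        if n_nodes <= 1:
            efficiency.append(0.0)
            continue
        total = 0.0
        for u in range(n_nodes):
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            if key in shortest:
                total += 1.0 / (len(shortest[key][0]) - 1)
        efficiency.append(total / (n_nodes - 1))

    betweenness = [0.0] * n_nodes
    for (s, t), paths in shortest.items():
        sigma = len(paths)
        for v in range(n_nodes):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / sigma

    return {
        "degree": degree,
        "clustering": clustering,
        "efficiency": efficiency,
        "global_efficiency": sum(efficiency) / n_nodes if n_nodes else 0.0,
        "betweenness": betweenness,
    }


# --------------------------------------------------------------------------
# modularity by full enumeration


def modularity_oracle(n_nodes, edges, labels) -> float:
    adj = _neighbors(n_nodes, edges)
    k = [len(adj[v]) for v in range(n_nodes)]
    two_m = sum(k)
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n_nodes):
        for j in range(n_nodes):
            if labels[i] != labels[j]:
                continue
            a = 1.0 if j in adj[i] else 0.0
            q += a - k[i] * k[j] / two_m
    return q / two_m


def best_two_partition(n_nodes, edges) -> tuple[float, list[int]]:
    """Maximum modularity over every 2-partition (incl. the trivial one)."""
    best_q, best_labels = -math.inf, [0] * n_nodes
    for bits in range(2 ** (n_nodes - 1)):
        labels = [(bits >> i) & 1 for i in range(n_nodes - 1)] + [0]
        q = modularity_oracle(n_nodes, edges, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


# --------------------------------------------------------------------------
# Student-t tail by numeric integration of the density formula


def t_two_sided_p(t_value: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(pdf, abs(t_value), math.inf)
    return 2.0 * tail


def correlation_p_oracle(r: float, n: int) -> float:
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return t_two_sided_p(t, n - 2)
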