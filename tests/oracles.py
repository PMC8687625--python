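"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: betweenness is
recomputed from an all-pairs Floyd-Warshall distance matrix with explicit
shortest-path counting, hypergeometric tails by enumerating every possible
draw, and greedy set-cover traces by plain set arithmetic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall_distances(nodes: list, edges: set) -> dict:
    """All-pairs shortest-path lengths by Floyd-Warshall (inf if unreachable)."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in edges:
        d[idx[a], idx[b]] = 1.0
        d[idx[b], idx[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return {(a, b): d[idx[a], idx[b]] for a in nodes for b in nodes}


def shortest_path_counts(nodes: list, edges: set, dist: dict) -> dict:
    """sigma[a][b]: number of distinct shortest a-b paths, by DP over distance."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    sigma = {}
    for a in nodes:
        counts = {a: 1}
        order = sorted((n for n in nodes if np.isfinite(dist[a, n])),
                       key=lambda n: dist[a, n])
        for v in order:
            if v == a:
                continue
            counts[v] = sum(counts[u] for u in adj[v]
                            if np.isfinite(dist[a, u]) and dist[a, u] == dist[a, v] - 1)
        for b, c in counts.items():
            sigma[a, b] = c
    return sigma


def brute_betweenness(nodes: list, edges: set) -> dict:
    """Unnormalized undirected betweenness: sum over unordered pairs a<b of
    sigma_ab(s)/sigma_ab, with sigma_ab(s) = sigma_as * sigma_sb when s lies
    on a shortest a-b path."""
    nodes = list(nodes)
    dist = floyd_warshall_distances(nodes, edges)
    sigma = shortest_path_counts(nodes, edges, dist)
    out = {s: 0.0 for s in nodes}
    for a, b in combinations(nodes, 2):
        if not np.isfinite(dist[a, b]):
            continue
        for s in nodes:
            if s in (a, b):
                continue
            if (np.isfinite(dist[a, s]) and np.isfinite(dist[s, b])
                    and dist[a, s] + dist[s, b] == dist[a, b]):
                out[s] += sigma[a, s] * sigma[s, b] / sigma[a, b]
    return out


def brute_nim(nodes: list, edges: set, communities: dict) -> dict:
    """Nim recomputed from first principles on top of the brute betweenness."""
    dist = floyd_warshall_distances(list(nodes), edges)
    betw = brute_betweenness(list(nodes), edges)
    n_total = len(nodes)
    nim = {}
    for s in nodes:
        comm = {w for w, c in communities.items() if c == communities[s]}
        others = [w for w in comm if w != s and np.isfinite(dist[s, w])]
        if not others:
            nim[s] = 0.0
            continue
        ecc = max(dist[s, w] for w in others)
        total = sum(ecc + 1 - dist[s, w] for w in others)
        factor = (len(comm) / n_total) * (total / ecc)
        nim[s] = betw[s] * factor ** 2
    return nim


def enumerate_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-element universe
    whose first K elements are 'annotated'."""
    universe = range(N)
    annotated = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


def greedy_trace(targets: dict, key: set, coverage_target: float) -> list:
    """Replay marginal-gain greedy by direct set arithmetic.

    Ties: larger raw target set, then smaller id. Returns the ordered picks
    with their marginal gains and cumulative coverage.
    """
    key = set(key)
    eff = {i: set(t) & key for i, t in targets.items()}
    covered: set = set()
    picks = []
    left = set(targets)
    while left:
        ranked = sorted(
            left,
            key=lambda i: (-len(eff[i] - covered), -len(targets[i]), i),
        )
        best = ranked[0]
        gain = len(eff[best] - covered)
        if gain == 0:
            break
        covered |= eff[best]
        picks.append((best, gain, len(covered) / len(key)))
        left.discard(best)
        if len(covered) / len(key) >= coverage_target:
            break
    return picks


def best_k_coverage(targets: dict, key: set, k: int) -> float:
    """Exhaustive optimum coverage achievable with any k ingredients."""
    key = set(key)
    best = 0
    for combo in combinations(targets, min(k, len(targets))):
        cov = set()
        for i in combo:
            cov |= set(targets[i]) & key
        best = max(best, len(cov))
    return best / len(key) if key else 0.0
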