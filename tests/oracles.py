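"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive and self-contained (no networkx, no
scipy, no statsmodels) so the checks are genuinely independent of the
code paths they verify.
"""

from __future__ import annotations

import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# betweenness by exhaustive shortest-path enumeration

def _bfs_dist(adj: dict, src) -> dict:
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj: dict, dist: dict, s, t) -> list[list]:
    """All shortest s->t paths, by walking the BFS layering backwards."""
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_force_betweenness(nodes, edges, normalized: bool = True) -> dict:
    """Betweenness by enumerating every shortest path between every pair.

    Endpoints are excluded; pair dependencies accumulate only within
    connected components; normalization divides by (n-1)(n-2)/2 using the
    full node count (0 if n < 3).
    """
    nodes = list(nodes)
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bc = {u: Fraction(0) for u in nodes}
    for i, s in enumerate(nodes):
        dist = _bfs_dist(adj, s)
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            total = len(paths)
            through: dict = {}
            for p in paths:
                for v in p[1:-1]:
                    through[v] = through.get(v, 0) + 1
            for v, cnt in through.items():
                bc[v] += Fraction(cnt, total)
    n = len(nodes)
    if normalized:
        denom = Fraction((n - 1) * (n - 2), 2) if n >= 3 else None
        return {u: (float(v / denom) if denom else 0.0) for u, v in bc.items()}
    return {u: float(v) for u, v in bc.items()}


# ---------------------------------------------------------------------------
# exact hypergeometric tail by PMF summation

def exact_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


def exact_rejection_probability(K: int, n: int, N: int, alpha: float) -> float:
    """P(reject) under the null for the discrete test rejecting iff tail < alpha.

    The tail P(X >= k) is nonincreasing in k, so the rejection region is
    {k >= k*} for the smallest k* whose tail falls below alpha; the
    rejection probability is the PMF mass of that region.
    """
    total = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(K, n)
    prob = Fraction(0)
    for k in range(lo, hi + 1):
        if float(exact_hypergeom_tail(k, K, n, N)) < alpha:
            for j in range(k, hi + 1):
                prob += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
            break
    return float(prob)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg step-up by hand

def bh_by_hand(pvalues) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adj[i] = running
    return adj
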