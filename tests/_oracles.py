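"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms the package uses: centralities
come from an explicit distance-matrix / path-count enumeration (not
Brandes accumulation, not networkx), and hypergeometric tails from
literal enumeration of draws.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def _adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a == b:
            continue
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _bfs_dist(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def _path_counts(adj, dist, source):
    """Number of shortest paths from source to each reachable node."""
    sigma = {source: 1}
    for v in sorted(dist, key=dist.get):
        if v == source:
            continue
        sigma[v] = sum(sigma[u] for u in adj[v] if dist.get(u) == dist[v] - 1)
    return sigma


def brute_force_centralities(nodes, edges):
    """degree / closeness / betweenness via pairwise shortest-path counting.

    Closeness(v) = (#reachable others) / (sum of distances to them), 0 for
    an isolated node.  Betweenness is unnormalized over unordered pairs,
    endpoints excluded.
    """
    nodes = list(nodes)
    adj = _adjacency(nodes, edges)
    dist = {v: _bfs_dist(adj, v) for v in nodes}
    sigma = {v: _path_counts(adj, dist[v], v) for v in nodes}

    degree = {v: len(adj[v]) for v in nodes}
    closeness = {}
    for v in nodes:
        others = {u: d for u, d in dist[v].items() if u != v}
        closeness[v] = len(others) / sum(others.values()) if others else 0.0

    betweenness = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if t not in dist[s]:
            continue
        dst = dist[s][t]
        sig_st = sigma[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist[s] or v not in dist[t]:
                continue
            if dist[s][v] + dist[t][v] == dst:
                betweenness[v] += sigma[s][v] * sigma[t][v] / sig_st
    return degree, closeness, betweenness


def hypergeom_tail_enumerated(N, K, n, k):
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    universe = range(N)
    special = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_closed_form(N, K, n, k):
    """P(X >= k) from the closed-form hypergeometric pmf (math.comb)."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / denom
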