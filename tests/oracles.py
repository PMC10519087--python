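"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and written against plain adjacency
dicts / edge lists, independent of the package's code paths: pure-python BFS,
literal shortest-path enumeration, dense eigendecomposition, and a direct
linear-system solve for the damped random walk.
"""

from __future__ import annotations

import numpy as np


def adjacency_from_edges(nodes, edges) -> dict:
    """Undirected adjacency sets from an iterable of (u, v) pairs."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    """Hop distances from source to every reachable node (pure-python BFS)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def ball(adj: dict, center, radius: int) -> set:
    """All nodes within `radius` hops of center."""
    return {n for n, d in bfs_distances(adj, center).items() if d <= radius}


def degree_oracle(nodes, edges) -> dict:
    adj = adjacency_from_edges(nodes, edges)
    return {n: float(len(adj[n])) for n in nodes}


def closeness_oracle(nodes, edges) -> dict:
    """Wasserman–Faust closeness: ((r-1)/total_dist) * ((r-1)/(n-1))."""
    adj = adjacency_from_edges(nodes, edges)
    n = len(adj)
    out = {}
    for s in adj:
        dist = bfs_distances(adj, s)
        r = len(dist)
        total = sum(dist.values())
        if r <= 1 or total == 0:
            out[s] = 0.0
        else:
            out[s] = ((r - 1) / total) * ((r - 1) / (n - 1))
    return out


def _shortest_path_counts(adj: dict, s) -> tuple[dict, dict]:
    """(distance, number of shortest paths) from s, by BFS-layer counting."""
    dist = bfs_distances(adj, s)
    sigma = {v: 0 for v in adj}
    sigma[s] = 1
    for v in sorted(dist, key=dist.get):
        if v == s:
            continue
        sigma[v] = sum(
            sigma[u] for u in adj[v] if u in dist and dist[u] == dist[v] - 1
        )
    return dist, sigma


def betweenness_oracle(nodes, edges) -> dict:
    """Pair-summation betweenness via distance/σ matrices, normalized by
    (n−1)(n−2)/2.  Independent of Brandes' dependency accumulation."""
    adj = adjacency_from_edges(nodes, edges)
    n = len(adj)
    dist = {}
    sigma = {}
    for s in adj:
        dist[s], sigma[s] = _shortest_path_counts(adj, s)
    bc = {v: 0.0 for v in adj}
    node_list = list(adj)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1 :]:
            if t not in dist[s] or sigma[s][t] == 0:
                continue
            d_st = dist[s][t]
            for v in adj:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    scale = (n - 1) * (n - 2) / 2
    if scale > 0:
        for v in bc:
            bc[v] /= scale
    return bc


def betweenness_enumeration_oracle(nodes, edges) -> dict:
    """Literal enumeration of every shortest simple path (tiny graphs only)."""
    adj = adjacency_from_edges(nodes, edges)
    n = len(adj)
    bc = {v: 0.0 for v in adj}

    def all_paths(s, t, maxlen):
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                yield path
                continue
            if len(path) > maxlen:
                continue
            for w in adj[u]:
                if w not in path:
                    stack.append((w, path + [w]))

    node_list = list(adj)
    for i, s in enumerate(node_list):
        dist = bfs_distances(adj, s)
        for t in node_list[i + 1 :]:
            if t not in dist:
                continue
            paths = [p for p in all_paths(s, t, dist[t] + 1) if len(p) - 1 == dist[t]]
            for v in adj:
                if v in (s, t):
                    continue
                on = sum(1 for p in paths if v in p)
                bc[v] += on / len(paths)
    scale = (n - 1) * (n - 2) / 2
    if scale > 0:
        for v in bc:
            bc[v] /= scale
    return bc


def eigenvector_oracle(nodes, edges) -> dict:
    """Principal eigenvector by dense symmetric eigendecomposition,
    max-normalized.  Only meaningful for connected graphs."""
    order = sorted(nodes)
    idx = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v in edges:
        if u != v:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
    w, vecs = np.linalg.eigh(a)
    principal = np.abs(vecs[:, np.argmax(w)])
    principal /= principal.max()
    return {n: float(principal[idx[n]]) for n in order}


def pagerank_oracle(nodes, directed_edges, damping=0.85) -> dict:
    """Exact damped-walk fixed point by linear solve, dangling mass uniform."""
    order = sorted(nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for u, v in directed_edges:
        if u != v:
            a[idx[u], idx[v]] = 1.0
    out = a.sum(axis=1)
    m = np.zeros((n, n))  # column-stochastic transition
    for j in range(n):
        if out[j] > 0:
            m[:, j] = a[j] / out[j]
        else:
            m[:, j] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - damping * m, np.full(n, (1 - damping) / n))
    x /= x.sum()
    return {node: float(x[idx[node]]) for node in order}


class UnionFind:
    """Plain union-find, the oracle for equivalence-component grouping."""

    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> list[frozenset]:
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]
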