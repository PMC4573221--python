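"""Brute-force reference implementations used only by the tests.

These are deliberately naive (exhaustive enumeration, dense linear
algebra) and share no code with the package, so they can serve as
independent oracles for the graph construction and topology metrics.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


def brute_degree(nodes, edges):
    """Tally degree directly from the edge list; a self-loop counts twice."""
    deg = {n: 0 for n in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def _bfs_distances(adj, source):
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


def _enumerate_shortest_paths(adj, dist, u, target):
    """All shortest paths u -> target, recursively along BFS layers."""
    if u == target:
        return [[u]]
    paths = []
    for v in adj[u]:
        if dist.get(v) == dist[u] + 1 and dist.get(target) is not None:
            if dist[v] <= dist[target]:
                for tail in _enumerate_shortest_paths(adj, dist, v, target):
                    paths.append([u] + tail)
    return paths


def brute_betweenness(nodes, edges, normalized=True):
    """Directed betweenness by explicit enumeration of all shortest paths."""
    nodes = list(nodes)
    adj = defaultdict(list)
    for a, b in edges:
        if a != b and b not in adj[a]:
            adj[a].append(b)
    score = {n: 0.0 for n in nodes}
    for s in nodes:
        dist = _bfs_distances(adj, s)
        for t in nodes:
            if t == s or t not in dist:
                continue
            paths = _enumerate_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for interior in path[1:-1]:
                    score[interior] += w
    n = len(nodes)
    if normalized and n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        score = {k: v * scale for k, v in score.items()}
    elif normalized:
        score = {k: 0.0 for k in score}
    return score


def brute_clustering(nodes, edges):
    """Local clustering on the undirected projection by triple enumeration."""
    nbrs = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            nbrs[a].add(b)
            nbrs[b].add(a)
    out = {}
    for n in nodes:
        k = len(nbrs[n])
        if k < 2:
            out[n] = 0.0
            continue
        ns = sorted(nbrs[n])
        triangles = 0
        for i in range(k):
            for j in range(i + 1, k):
                if ns[j] in nbrs[ns[i]]:
                    triangles += 1
        out[n] = triangles / (k * (k - 1) / 2)
    return out


def pagerank_linear(nodes, edges, damping=0.85):
    """PageRank from the stationarity linear system (dense solve)."""
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    P = np.zeros((n, n))  # P[i, j]: probability of stepping i -> j
    out = defaultdict(list)
    for a, b in edges:
        out[a].append(b)
    for v in nodes:
        i = idx[v]
        if out[v]:
            for w in out[v]:
                P[i, idx[w]] += 1.0 / len(out[v])
        else:
            P[i, :] = 1.0 / n
    A = np.eye(n) - damping * P.T
    x = np.linalg.solve(A, np.full(n, (1.0 - damping) / n))
    return {v: float(x[idx[v]]) for v in nodes}


def random_digraph(rng, max_nodes=10, p_edge=0.25, allow_self_loops=False):
    """A random directed graph as (nodes, edge set)."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"K{i:05d}" for i in range(1, n + 1)]
    edges = set()
    for a in nodes:
        for b in nodes:
            if a == b and not allow_self_loops:
                continue
            if rng.random() < p_edge:
                edges.add((a, b))
    return nodes, edges
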