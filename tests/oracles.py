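"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and self-contained: Gaussian
elimination on the normal equations, exhaustive shortest-path enumeration
with exact rationals, a truncated Taylor matrix exponential, and direct
triangle counting.  None of it shares code with the package.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction

import numpy as np


def ols_gauss(design, response):
    """Solve the normal equations (X'X) b = X'y by Gaussian elimination
    with partial pivoting; return (b, residual_sum_of_squares)."""
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    ata = design.T @ design
    atb = design.T @ response
    n = ata.shape[0]
    aug = np.hstack([ata, atb[:, None]])
    for col in range(n):
        pivot = col + int(np.argmax(np.abs(aug[col:, col])))
        if abs(aug[pivot, col]) < 1e-12:
            raise ValueError("singular normal equations")
        aug[[col, pivot]] = aug[[pivot, col]]
        for row in range(col + 1, n):
            aug[row] -= (aug[row, col] / aug[col, col]) * aug[col]
    beta = np.zeros(n)
    for col in range(n - 1, -1, -1):
        beta[col] = (aug[col, -1] - aug[col, col + 1 : n] @ beta[col + 1 :]
                     ) / aug[col, col]
    resid = response - design @ beta
    return beta, float(resid @ resid)


def _bfs_layers(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nbr in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                queue.append(nbr)
    return dist


def _all_shortest_paths(adj, source, target, dist):
    """Enumerate every shortest source->target path (node tuples)."""
    if target not in dist:
        return []
    paths = []

    def extend(path):
        node = path[-1]
        if node == target:
            paths.append(tuple(path))
            return
        for nbr in adj[node]:
            if dist.get(nbr) == dist[node] + 1 and dist[nbr] <= dist[target]:
                extend(path + [nbr])

    extend([source])
    return [p for p in paths if len(p) - 1 == dist[target]]


def brute_betweenness(graph):
    """Ordered-pair betweenness by explicit path enumeration, exact
    rationals."""
    adj = {v: sorted(graph[v]) for v in graph.nodes()}
    scores = {v: Fraction(0) for v in adj}
    for s in adj:
        dist = _bfs_layers(adj, s)
        for t in adj:
            if t == s:
                continue
            paths = _all_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            total = len(paths)
            for v in adj:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                scores[v] += Fraction(through, total)
    return scores


def brute_closeness(graph):
    """Component-local closeness by BFS; isolated nodes 0."""
    adj = {v: set(graph[v]) for v in graph.nodes()}
    scores = {}
    for v in adj:
        dist = _bfs_layers(adj, v)
        total = sum(dist.values())
        scores[v] = Fraction(len(dist) - 1, total) if total else Fraction(0)
    return scores


def taylor_expm_diag(adj_matrix, terms: int = 50):
    """Diagonal of exp(A) by truncated power series sum A^k / k!."""
    adj_matrix = np.asarray(adj_matrix, dtype=float)
    n = adj_matrix.shape[0]
    result = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms + 1):
        term = term @ adj_matrix / k
        result = result + term
    return np.diag(result).copy()


def naive_lac(graph):
    """Average neighbor degree within the neighbor-induced subgraph, by
    direct pair checks."""
    scores = {}
    for v in graph.nodes():
        nbrs = list(graph[v])
        if not nbrs:
            scores[v] = 0.0
            continue
        total = sum(1 for a in nbrs for b in nbrs
                    if a != b and graph.has_edge(a, b))
        scores[v] = total / len(nbrs)
    return scores


def naive_nc(graph):
    """Node score from per-edge triangle counts, by direct enumeration."""
    scores = {v: 0.0 for v in graph.nodes()}
    for u, v in graph.edges():
        triangles = sum(1 for w in graph.nodes()
                        if w not in (u, v) and graph.has_edge(u, w)
                        and graph.has_edge(v, w))
        denom = min(graph.degree(u) - 1, graph.degree(v) - 1)
        ecc = triangles / denom if denom > 0 else 0.0
        scores[u] += ecc
        scores[v] += ecc
    return scores


def trapezoid_auc(ys):
    """Trapezoidal area under (0..n, y) computed by the summation rule."""
    return sum((ys[i] + ys[i + 1]) / 2 for i in range(len(ys) - 1))
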