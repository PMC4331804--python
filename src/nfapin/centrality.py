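"""Six topological centrality measures and deterministic ranking.

All measures operate on a simple undirected graph and return a score per
node:

- DC: degree.
- BC: betweenness — the summed fraction of shortest paths through the
  node, over ordered distinct (s, t) pairs (each unordered pair counts
  twice; the constant factor does not affect ranks).
- CC: closeness — (n_c - 1) / sum of distances within the node's
  connected component of size n_c; isolated nodes score 0.  The
  component-local form is used because active networks are frequently
  disconnected.
- SC: subgraph centrality — the diagonal of exp(A), i.e. the count of
  closed walks through the node weighted by 1/length!, computed by full
  symmetric eigendecomposition of the adjacency matrix.
- LAC: local average connectivity — the mean degree of the node's
  neighbors within the subgraph they induce (the node itself excluded).
- NC: the sum over incident edges of the edge clustering coefficient
  ECC(u, v) = (#triangles on the edge) / min(deg u - 1, deg v - 1),
  with ECC = 0 when the denominator vanishes (pendant edges).

Rankings are descending by score with lexicographic tie-breaking, so a
given graph always yields the same order.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "subgraph_centrality",
    "lac",
    "edge_clustering_coefficient",
    "nc",
    "MEASURES",
    "rank",
]


def degree_centrality(graph: nx.Graph) -> dict:
    return {v: float(d) for v, d in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict:
    # Brandes, unnormalized; doubled to count ordered (s, t) pairs.
    raw = nx.betweenness_centrality(graph, normalized=False)
    return {v: 2.0 * s for v, s in raw.items()}


def closeness_centrality(graph: nx.Graph) -> dict:
    # wf_improved=False is the component-local (n_c - 1)/sum(d) form;
    # networkx gives isolated nodes 0.
    return {v: float(s) for v, s in
            nx.closeness_centrality(graph, wf_improved=False).items()}


def subgraph_centrality(graph: nx.Graph) -> dict:
    nodes = list(graph.nodes())
    if not nodes:
        return {}
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    eigvals, eigvecs = np.linalg.eigh(adj)
    scores = (eigvecs**2) @ np.exp(eigvals)
    return {v: float(s) for v, s in zip(nodes, scores)}


def lac(graph: nx.Graph) -> dict:
    scores = {}
    for v in graph.nodes():
        nbrs = list(graph[v])
        if not nbrs:
            scores[v] = 0.0
            continue
        induced = graph.subgraph(nbrs)
        scores[v] = sum(d for _, d in induced.degree()) / len(nbrs)
    return scores


def edge_clustering_coefficient(graph: nx.Graph, u, v) -> float:
    if not graph.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge of the graph")
    triangles = len(set(graph[u]) & set(graph[v]))
    denom = min(graph.degree(u) - 1, graph.degree(v) - 1)
    if denom <= 0:
        return 0.0
    return triangles / denom


def nc(graph: nx.Graph) -> dict:
    return {
        v: sum(edge_clustering_coefficient(graph, u, v) for u in graph[v])
        for v in graph.nodes()
    }


MEASURES = {
    "DC": degree_centrality,
    "BC": betweenness_centrality,
    "CC": closeness_centrality,
    "SC": subgraph_centrality,
    "LAC": lac,
    "NC": nc,
}


def rank(scores: dict) -> list:
    """Nodes in descending score order, ties broken lexicographically."""
    return sorted(scores, key=lambda v: (-scores[v], str(v)))
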