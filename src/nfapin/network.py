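"""Active PPI network construction.

The static PPI network is an undirected simple graph (self-interactions
and duplicate edges removed at load time).  Given the activity matrix, an
edge of the static network is part of the active network at time t when
both endpoint proteins are active at t; the active network (NF-APIN) is
the collection of these per-time-point edge sets together with their
union graph.  Proteins without expression data are never active and thus
never enter the active network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .activity import ActivityMatrix

__all__ = [
    "ActiveNetwork",
    "canonical_edge",
    "clean_network",
    "build_active_network",
    "restrict_to_expression",
]


def canonical_edge(u, v) -> tuple:
    """Order-insensitive edge key."""
    return (u, v) if u <= v else (v, u)


def clean_network(graph: nx.Graph) -> tuple[nx.Graph, int]:
    """Drop self-loops (networkx already holds edges deduplicated).

    Returns the cleaned graph and the number of self-loops removed.
    """
    g = graph.copy()
    loops = list(nx.selfloop_edges(g))
    g.remove_edges_from(loops)
    return g, len(loops)


@dataclass(frozen=True)
class ActiveNetwork:
    """Per-time-point active edge sets and their union graph.

    ``per_time[t]`` is the set of canonical static edges whose two
    endpoints are simultaneously active at time t; ``union_graph`` has
    exactly the union of these edges (its nodes are their endpoints).
    """

    timepoints: int
    per_time: tuple[frozenset, ...]
    union_graph: nx.Graph

    def edges_with_times(self):
        """Iterate (u, v, t) over all per-time edges, for export."""
        for t, edges in enumerate(self.per_time):
            for u, v in sorted(edges):
                yield u, v, t


def build_active_network(static: nx.Graph,
                         activity: ActivityMatrix) -> ActiveNetwork:
    """Restrict the static network to co-active protein pairs, per time.

    Genes in the activity matrix may cover only part of the network; the
    remainder is treated as inactive at every time point.
    """
    if static.number_of_nodes() == 0:
        raise ValueError("empty static network")
    static_edges = [canonical_edge(u, v) for u, v in static.edges()]
    per_time = []
    for t in range(activity.n_timepoints):
        active = activity.active_genes_at(t)
        per_time.append(frozenset(
            (u, v) for u, v in static_edges if u in active and v in active
        ))
    union = nx.Graph()
    for edges in per_time:
        union.add_edges_from(edges)
    return ActiveNetwork(timepoints=activity.n_timepoints,
                         per_time=tuple(per_time), union_graph=union)


def restrict_to_expression(static: nx.Graph, measured) -> nx.Graph:
    """Induced subgraph on the nodes with expression data.

    Optional preprocessing so that static-vs-active comparisons share a
    node universe when expression coverage is incomplete.
    """
    keep = set(measured) & set(static.nodes())
    return static.subgraph(keep).copy()
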