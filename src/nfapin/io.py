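"""Readers and writers for the tab-delimited interchange formats.

Three inputs: a two-column edge list of protein identifiers (extra
columns ignored, '#' comment lines allowed), a gene-expression matrix
(first column gene id, then M numeric columns, optional header), and an
identifier list (one per line).  Identifiers are opaque strings; tab is
the only field separator.  Self-interactions and duplicate edges are
dropped at load time, with counts logged.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .activity import ActivityMatrix
from .network import ActiveNetwork

logger = logging.getLogger("nfapin")

__all__ = [
    "ParseError",
    "read_edge_list",
    "read_expression",
    "read_protein_list",
    "write_edge_list",
    "write_expression",
    "write_protein_list",
    "write_activity",
    "write_per_time_edges",
    "write_scores",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _data_lines(path):
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            yield lineno, stripped


def read_edge_list(path, normalize_ids: bool = False) -> nx.Graph:
    """Load a static PPI network from a tab-delimited edge list.

    Self-loops and order-insensitive duplicate edges are removed; with
    ``normalize_ids`` identifiers are uppercased before matching.
    """
    graph = nx.Graph()
    loops = dupes = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected at least 2 tab-separated "
                f"fields, got {len(fields)}"
            )
        u, v = fields[0].strip(), fields[1].strip()
        if normalize_ids:
            u, v = u.upper(), v.upper()
        if u == v:
            loops += 1
            continue
        if graph.has_edge(u, v):
            dupes += 1
            continue
        graph.add_edge(u, v)
    if graph.number_of_edges() == 0:
        raise ParseError(f"{path}: empty network")
    logger.info("read %d nodes / %d edges from %s (dropped %d self-loops, "
                "%d duplicates)", graph.number_of_nodes(),
                graph.number_of_edges(), path, loops, dupes)
    return graph


def read_expression(path, normalize_ids: bool = False) -> pd.DataFrame:
    """Load a gene x time expression matrix.

    A header line is assumed when the second field of the first line is
    not numeric.  Rows whose cells fail to parse as numbers are dropped
    with a warning; a duplicated gene id keeps its first row.  A row with
    a different field count from the first data row is a hard error.
    """
    rows: dict[str, list[float]] = {}
    columns = None
    n_fields = None
    dropped = dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if n_fields is None:
            try:
                float(fields[1])
            except (ValueError, IndexError):
                columns = [c.strip() for c in fields[1:]]
                n_fields = len(fields)
                continue
            n_fields = len(fields)
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_fields} fields, "
                f"got {len(fields)}"
            )
        gene = fields[0].strip()
        if normalize_ids:
            gene = gene.upper()
        try:
            values = [float(f) for f in fields[1:]]
        except ValueError:
            dropped += 1
            logger.warning("%s: line %d: non-numeric cell, gene %r dropped",
                           path, lineno, gene)
            continue
        if gene in rows:
            dup += 1
            logger.warning("%s: line %d: duplicate gene %r, first kept",
                           path, lineno, gene)
            continue
        rows[gene] = values
    if not rows:
        raise ParseError(f"{path}: no usable expression rows")
    if columns is None:
        columns = [f"t{t}" for t in range(n_fields - 1)]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    logger.info("read %d expression profiles x %d time points from %s "
                "(%d rows dropped, %d duplicates)", frame.shape[0],
                frame.shape[1], path, dropped, dup)
    return frame


def read_protein_list(path, normalize_ids: bool = False) -> set[str]:
    """Load a deduplicated identifier set; blank lines are ignored."""
    out = set()
    for _, line in _data_lines(path):
        name = line.split("\t")[0].strip()
        out.add(name.upper() if normalize_ids else name)
    if not out:
        raise ParseError(f"{path}: empty protein list")
    return out


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for u, v in sorted((min(u, v), max(u, v))
                           for u, v in graph.edges()):
            handle.write(f"{u}\t{v}\n")


def write_expression(frame: pd.DataFrame, path, header: bool = True) -> None:
    frame.to_csv(path, sep="\t", header=header, index_label="gene_id")


def write_protein_list(names, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted(names):
            handle.write(f"{name}\n")


def write_activity(activity: ActivityMatrix, path) -> None:
    activity.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_per_time_edges(active: ActiveNetwork, path) -> None:
    """Three-column export: u, v, time point."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("u\tv\tt\n")
        for u, v, t in active.edges_with_times():
            handle.write(f"{u}\t{v}\t{t}\n")


def write_scores(scores_by_measure: dict, path) -> None:
    """Long-format export: protein_id, measure, score, rank."""
    from .centrality import rank as _rank

    with open(path, "w", encoding="utf-8") as handle:
        handle.write("protein_id\tmeasure\tscore\trank\n")
        for measure in sorted(scores_by_measure):
            scores = scores_by_measure[measure]
            for position, node in enumerate(_rank(scores), start=1):
                handle.write(
                    f"{node}\t{measure}\t{scores[node]:.10g}\t{position}\n"
                )
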