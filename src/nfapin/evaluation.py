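"""Ranking evaluation: top-k essential counts, jackknife curves, overlaps.

A centrality measure ranks proteins; the evaluation asks how many known
essential proteins appear among the top-k candidates, how the cumulative
essential count grows as the cut-off slides down the ranking (the
jackknife curve, summarized by its trapezoidal area and by that area
normalized against the ideal all-essentials-first ranking), and how much
the essential proteins recovered by two rankings overlap.

Proteins that a ranking does not cover (e.g. proteins absent from the
active network) are appended after the ranked ones, in lexicographic
order, so that comparisons between the static and active networks share a
common node universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

import networkx as nx

from .centrality import MEASURES, rank
from .network import ActiveNetwork

__all__ = [
    "JackknifeCurve",
    "OverlapReport",
    "top_k_counts",
    "jackknife",
    "overlap",
    "complete_ranking",
    "compare_networks",
    "plot_jackknife",
]


@dataclass(frozen=True)
class JackknifeCurve:
    """Cumulative true-essential count y_i over the top i candidates.

    ``auc`` is the trapezoidal area under (x, y) over the full ranking;
    ``auc_normalized`` divides by the area of the ideal ranking (all
    essentials first) on the same node set, so it lies in [0, 1].
    """

    x: np.ndarray
    y: np.ndarray
    auc: float
    auc_normalized: float


@dataclass(frozen=True)
class OverlapReport:
    """Decomposition of the top-k essential sets of two rankings."""

    k: int
    s1: int  # true essentials in ranking A's top k
    s2: int  # true essentials in ranking B's top k
    s3: int  # essentials common to both top-k sets
    unique_a: int  # s1 - s3
    unique_b: int  # s2 - s3


def top_k_counts(ranking: Sequence, essential: Iterable,
                 ks: Sequence[int]) -> dict[int, int]:
    """Number of true essentials among the top k, for each cutoff k."""
    essential = set(essential)
    for k in ks:
        if k > len(ranking):
            raise ValueError(
                f"cutoff k={k} exceeds ranking length {len(ranking)}"
            )
    return {k: sum(1 for v in ranking[:k] if v in essential) for k in ks}


def jackknife(ranking: Sequence, essential: Iterable) -> JackknifeCurve:
    """Cumulative essential-count curve and its (normalized) area."""
    if len(ranking) == 0:
        raise ValueError("cannot evaluate an empty ranking")
    essential = set(essential)
    hits = np.fromiter((v in essential for v in ranking), dtype=float,
                       count=len(ranking))
    y = np.concatenate([[0.0], np.cumsum(hits)])
    x = np.arange(len(ranking) + 1, dtype=float)
    auc = float(np.trapezoid(y, x))
    n_hit = int(y[-1])
    ideal = np.concatenate([[0.0],
                            np.minimum(np.arange(1, len(ranking) + 1),
                                       n_hit).astype(float)])
    auc_ideal = float(np.trapezoid(ideal, x))
    auc_norm = auc / auc_ideal if auc_ideal > 0 else 0.0
    return JackknifeCurve(x=x, y=y, auc=auc, auc_normalized=auc_norm)


def overlap(rank_a: Sequence, rank_b: Sequence, essential: Iterable,
            k: int) -> OverlapReport:
    """Shared and unique essentials in the two top-k candidate sets."""
    if k > len(rank_a) or k > len(rank_b):
        raise ValueError("k exceeds a ranking's length")
    essential = set(essential)
    top_a = set(rank_a[:k]) & essential
    top_b = set(rank_b[:k]) & essential
    s3 = len(top_a & top_b)
    return OverlapReport(k=k, s1=len(top_a), s2=len(top_b), s3=s3,
                         unique_a=len(top_a) - s3, unique_b=len(top_b) - s3)


def complete_ranking(ranking: Sequence, universe: Iterable) -> list:
    """Append universe nodes missing from the ranking, in lexicographic
    order, so every ranking covers the same node set."""
    ranked = set(ranking)
    tail = sorted((v for v in set(universe) - ranked), key=str)
    return list(ranking) + tail


def compare_networks(static: nx.Graph, active: ActiveNetwork,
                     essential: Iterable,
                     measures: Sequence[str] = tuple(MEASURES),
                     ks: Sequence[int] | None = None,
                     ranked_only: bool = False,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate each centrality measure on the static network (PPIN) and
    on the active union graph (APPIN).

    Returns (counts, overlaps): ``counts`` has one row per (measure,
    network) with the top-k essential counts and jackknife areas;
    ``overlaps`` decomposes, per measure, the essentials recovered by the
    two networks at the smallest cutoff.  With ``ranked_only`` the APPIN
    ranking is not padded to the static node universe.
    """
    universe = sorted(static.nodes(), key=str)
    essential = set(essential) & set(universe)
    if ks is None:
        n = len(universe)
        ks = sorted({max(1, round(n * f)) for f in (0.02, 0.04, 0.06,
                                                    0.08, 0.10)})
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}")

    count_rows, overlap_rows = [], []
    for name in measures:
        fn = MEASURES[name]
        ppin_rank = rank(fn(static))
        appin_rank = rank(fn(active.union_graph))
        if not ranked_only:
            appin_rank = complete_ranking(appin_rank, universe)
        rankings = {"PPIN": ppin_rank, "APPIN": appin_rank}
        for net, ranking in rankings.items():
            usable_ks = [k for k in ks if k <= len(ranking)]
            counts = top_k_counts(ranking, essential, usable_ks)
            curve = jackknife(ranking, essential)
            row = {"measure": name, "network": net,
                   "auc": curve.auc, "auc_normalized": curve.auc_normalized}
            row.update({f"top_{k}": counts[k] for k in usable_ks})
            count_rows.append(row)
        k0 = min(k for k in ks if k <= min(map(len, rankings.values())))
        rep = overlap(rankings["PPIN"], rankings["APPIN"], essential, k0)
        overlap_rows.append({"measure": name, "k": rep.k, "S1": rep.s1,
                             "S2": rep.s2, "S3": rep.s3,
                             "S1_only": rep.unique_a,
                             "S2_only": rep.unique_b})
    return pd.DataFrame(count_rows), pd.DataFrame(overlap_rows)


def plot_jackknife(curves: Mapping[str, JackknifeCurve], path) -> None:
    """Write a PNG/SVG of one or more jackknife curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in curves.items():
        ax.plot(curve.x, curve.y, label=label)
    ax.set_xlabel("top-ranked proteins")
    ax.set_ylabel("cumulative true essentials")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
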