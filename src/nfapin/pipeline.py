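"""End-to-end orchestration: filter -> threshold -> build -> rank -> evaluate.

The pipeline reads the three standard inputs, runs the time-dependence
test on every profile, discards noise genes, computes activity thresholds
and flags, restricts the static network to co-active pairs, scores both
the static network and the active union graph with the requested
centrality measures, and writes the evaluation tables.  Every stage's
record counts go to the log; the resolved configuration is echoed to a
JSON file next to the outputs for provenance.  The whole run is
deterministic, so the same inputs and configuration give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nfio
from .activity import NoiseFilterConfig, activity_matrix, filter_noise
from .centrality import MEASURES
from .evaluation import compare_networks, jackknife, plot_jackknife
from .network import build_active_network
from .timeseries import call_dependence

logger = logging.getLogger("nfapin")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters of a full run."""

    network_path: str
    expression_path: str
    essential_path: str
    out_dir: str
    alpha: float = 0.01
    k: float = 2.5
    mean_floor: float | None = None
    mean_floor_percentile: float = 20.0
    measures: tuple[str, ...] = tuple(MEASURES)
    ks: tuple[int, ...] | None = None
    log2: bool = False
    bonferroni: bool = False
    normalize_ids: bool = False
    ranked_only: bool = False
    plot: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0.0 <= self.k <= 3.0:
            raise ValueError("k must lie in [0, 3]")
        if not 0.0 <= self.mean_floor_percentile <= 100.0:
            raise ValueError("mean_floor_percentile must lie in [0, 100]")
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise ValueError(f"unknown measures: {unknown}")
        if self.ks is not None and any(k < 1 for k in self.ks):
            raise ValueError("all ks must be >= 1")


def _calls_to_frame(calls):
    import pandas as pd

    rows = []
    for gene, call in calls.items():
        f_val = (float("nan") if call.best_order is None
                 else call.per_order[call.best_order][0])
        rows.append((gene, call.best_order, f_val, call.min_pvalue,
                     call.time_dependent))
    return pd.DataFrame(rows, columns=["gene_id", "best_order", "F",
                                       "min_pvalue", "time_dependent"]
                        ).set_index("gene_id")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the paths of the written reports."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    static = nfio.read_edge_list(cfg.network_path,
                                 normalize_ids=cfg.normalize_ids)
    expression = nfio.read_expression(cfg.expression_path,
                                      normalize_ids=cfg.normalize_ids)
    essential = nfio.read_protein_list(cfg.essential_path,
                                       normalize_ids=cfg.normalize_ids)
    if cfg.log2:
        expression = np.log2(expression + 1.0)
    essential_in_net = essential & set(static.nodes())
    logger.info("%d of %d essential proteins present in the network",
                len(essential_in_net), len(essential))

    calls = {g: call_dependence(expression.loc[g].to_numpy(dtype=float),
                                alpha=cfg.alpha, bonferroni=cfg.bonferroni)
             for g in expression.index}
    calls_frame = _calls_to_frame(calls)
    ncfg = NoiseFilterConfig(alpha=cfg.alpha, k=cfg.k,
                             mean_floor=cfg.mean_floor,
                             mean_floor_percentile=cfg.mean_floor_percentile,
                             bonferroni=cfg.bonferroni)
    retained = filter_noise(expression, calls, ncfg)
    logger.info("noise filter retained %d of %d genes", len(retained),
                expression.shape[0])

    activity = activity_matrix(expression.loc[retained], k=cfg.k)
    active = build_active_network(static, activity)
    logger.info("active network: %d nodes, %d edges in the union graph",
                active.union_graph.number_of_nodes(),
                active.union_graph.number_of_edges())

    counts, overlaps = compare_networks(static, active, essential_in_net,
                                        measures=cfg.measures, ks=cfg.ks,
                                        ranked_only=cfg.ranked_only)

    paths = {
        "dependence": out / "dependence_calls.tsv",
        "activity": out / "activity.tsv",
        "active_edges": out / "active_edges.tsv",
        "union_edges": out / "active_union_edges.tsv",
        "scores": out / "centrality_scores.tsv",
        "counts": out / "evaluation_counts.tsv",
        "overlaps": out / "evaluation_overlaps.tsv",
        "report": out / "evaluation.json",
        "config": out / "config.json",
    }
    calls_frame.to_csv(paths["dependence"], sep="\t")
    nfio.write_activity(activity, paths["activity"])
    nfio.write_per_time_edges(active, paths["active_edges"])
    nfio.write_edge_list(active.union_graph, paths["union_edges"])
    nfio.write_scores(
        {m: MEASURES[m](active.union_graph) for m in cfg.measures},
        paths["scores"])
    counts.to_csv(paths["counts"], sep="\t", index=False)
    overlaps.to_csv(paths["overlaps"], sep="\t", index=False)
    paths["report"].write_text(json.dumps({
        "counts": counts.to_dict(orient="records"),
        "overlaps": overlaps.to_dict(orient="records"),
        "n_genes": int(expression.shape[0]),
        "n_retained": int(len(retained)),
        "n_active_union_edges": int(active.union_graph.number_of_edges()),
        "n_essential_in_network": len(essential_in_net),
    }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")

    if cfg.plot:
        from .centrality import rank as _rank
        from .evaluation import complete_ranking
        universe = sorted(static.nodes(), key=str)
        curves = {}
        for m in cfg.measures:
            curves[f"{m} PPIN"] = jackknife(_rank(MEASURES[m](static)),
                                            essential_in_net)
            appin = complete_ranking(_rank(MEASURES[m](active.union_graph)),
                                     universe)
            curves[f"{m} APPIN"] = jackknife(appin, essential_in_net)
        paths["plot"] = out / "jackknife.png"
        plot_jackknife(curves, paths["plot"])

    return paths
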