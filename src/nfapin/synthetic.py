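"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here: AR(p) series with
chosen coefficients and Gaussian innovations, i.i.d. normal null series
(the time-independent model), and toy benchmarks — a random simple graph
with a planted module of genes that are strongly co-expressed inside a
short window of time points, against a background of flat low-expression
noise genes, with essential labels assigned preferentially inside the
module at a configurable enrichment ratio.

By construction the module genes exceed their activity thresholds exactly
in the window and the background genes never do, so the active network a
correct pipeline recovers is exactly the static subgraph induced on the
module.  One seed drives all randomness; per-component substreams are
derived from it deterministically, so identical parameters and seed give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "gen_ar_series",
    "gen_null_series",
    "BenchmarkSpec",
    "Benchmark",
    "gen_benchmark",
]


def gen_ar_series(coefficients, sigma: float, m: int,
                  rng: np.random.Generator | int | None = None,
                  initial=None) -> np.ndarray:
    """Simulate an AR(p) series of length ``m``.

    ``coefficients`` is (b0, b1, ..., bp): intercept, then the lag weights
    from oldest to newest as in the model's design matrix, i.e.
    x_t = b0 + b1*x_{t-p} + ... + bp*x_{t-1} + e_t with e_t ~ N(0, sigma^2).
    Without ``initial`` the recursion starts from zeros and a burn-in of
    10*p steps is discarded to shed the initial condition; with ``initial``
    (the first p values) the series starts exactly there, no burn-in.
    """
    rng = np.random.default_rng(rng)
    coefficients = np.asarray(coefficients, dtype=float)
    p = coefficients.size - 1
    if p < 1:
        raise ValueError("need at least one lag coefficient")
    b0, lags = coefficients[0], coefficients[1:]
    if initial is not None:
        start = np.asarray(initial, dtype=float)
        if start.size != p:
            raise ValueError(f"initial must supply exactly p={p} values")
        burn = 0
        x = np.empty(m)
        x[:p] = start
    else:
        burn = 10 * p
        x = np.zeros(m + burn)
    noise = rng.normal(0.0, sigma, size=x.size)
    for t in range(p if initial is not None else p, x.size):
        x[t] = b0 + lags @ x[t - p : t] + noise[t]
    return x[burn:] if initial is None else x


def gen_null_series(mean: float, sigma: float, m: int,
                    rng: np.random.Generator | int | None = None
                    ) -> np.ndarray:
    """i.i.d. N(mean, sigma^2) series — the time-independent model."""
    rng = np.random.default_rng(rng)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return mean + rng.normal(0.0, sigma, size=m) if sigma > 0 \
        else np.full(m, float(mean))


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the planted-module benchmark.

    Module genes sit at ``module_base`` with small observation noise and
    are boosted by ``module_boost`` inside the co-active window (default:
    three consecutive time points at mid-series).  Background genes are
    flat at ``background_level`` (plus optional noise), i.e. realizations
    of the time-independent model with a very small mean — the noise
    genes the filter is meant to discard.  Essential labels are drawn
    without replacement with sampling weight ``enrichment`` inside the
    module versus 1 outside.
    """

    n_nodes: int = 50
    n_edges: int = 120
    module_size: int = 10
    n_timepoints: int = 36
    window: tuple[int, ...] | None = None  # time indices; None -> 3 mid
    module_base: float = 5.0
    module_boost: float = 10.0
    module_noise_sd: float = 0.05
    background_level: float = 0.01
    background_noise_sd: float = 0.0
    n_essential: int = 15
    enrichment: float = 3.0
    seed: int = 0
    id_prefix: str = field(default="P")

    def resolved_window(self) -> tuple[int, ...]:
        if self.window is not None:
            return tuple(self.window)
        mid = self.n_timepoints // 2
        return (mid - 1, mid, mid + 1)


@dataclass(frozen=True)
class Benchmark:
    """A generated benchmark with its ground truth."""

    network: nx.Graph
    expression: pd.DataFrame
    essential: frozenset
    module: frozenset
    window: tuple[int, ...]
    spec: BenchmarkSpec


def gen_benchmark(spec: BenchmarkSpec | None = None, **overrides
                  ) -> Benchmark:
    """Generate a benchmark from a spec (or keyword overrides of the
    default spec)."""
    if spec is None:
        spec = BenchmarkSpec(**overrides)
    elif overrides:
        raise ValueError("pass either a spec or keyword overrides, not both")
    max_edges = spec.n_nodes * (spec.n_nodes - 1) // 2
    if spec.n_edges > max_edges:
        raise ValueError(
            f"{spec.n_edges} edges infeasible for {spec.n_nodes} nodes"
        )
    if spec.module_size > spec.n_nodes:
        raise ValueError("module larger than the network")
    if spec.n_essential > spec.n_nodes:
        raise ValueError("more essentials than nodes")
    window = spec.resolved_window()
    if any(t < 0 or t >= spec.n_timepoints for t in window):
        raise ValueError("window indices outside the time axis")

    root = np.random.SeedSequence(spec.seed)
    graph_ss, module_ss, expr_ss, ess_ss = root.spawn(4)

    width = len(str(spec.n_nodes))
    ids = [f"{spec.id_prefix}{i:0{width}d}" for i in range(spec.n_nodes)]
    raw = nx.gnm_random_graph(
        spec.n_nodes, spec.n_edges,
        seed=int(graph_ss.generate_state(1)[0]))
    graph = nx.relabel_nodes(raw, dict(enumerate(ids)))

    rng_mod = np.random.default_rng(module_ss)
    module = frozenset(rng_mod.choice(ids, size=spec.module_size,
                                      replace=False))

    rng_expr = np.random.default_rng(expr_ss)
    win = np.zeros(spec.n_timepoints)
    win[list(window)] = spec.module_boost
    rows = {}
    for gene in ids:
        if gene in module:
            rows[gene] = (spec.module_base + win
                          + rng_expr.normal(0.0, spec.module_noise_sd,
                                            spec.n_timepoints))
        else:
            rows[gene] = gen_null_series(spec.background_level,
                                         spec.background_noise_sd,
                                         spec.n_timepoints, rng_expr)
    expression = pd.DataFrame.from_dict(rows, orient="index",
                                        columns=[f"t{t}" for t in
                                                 range(spec.n_timepoints)])
    expression = expression.loc[ids]

    rng_ess = np.random.default_rng(ess_ss)
    weights = np.array([spec.enrichment if g in module else 1.0
                        for g in ids])
    essential = frozenset(rng_ess.choice(
        ids, size=spec.n_essential, replace=False,
        p=weights / weights.sum()))

    return Benchmark(network=graph, expression=expression,
                     essential=essential, module=module, window=window,
                     spec=spec)
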