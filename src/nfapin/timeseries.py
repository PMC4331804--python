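"""Time-dependence testing for expression time series.

A gene's expression profile x = (x_1, ..., x_M), sampled at equally spaced
time points, is called *time-dependent* when an autoregressive model

    AR(p):  x_m = b0 + b1*x_{m-p} + ... + bp*x_{m-1} + e_m,   m = p+1..M

fits it significantly better than the time-independent (constant-plus-noise)
model

    x_m = b0 + e_m,   m = p+1..M

with i.i.d. Gaussian errors in both cases.  Both models are fitted by
maximum likelihood on the same M - p response values, so the likelihood
ratio

    Lambda = (s2_ar / s2_const) ** ((M - p) / 2)

lies in [0, 1] (the constant model is nested in AR(p)), and

    F = (M - 2p - 1) / p * (s2_const / s2_ar - 1)

follows an F(p, M - 2p - 1) distribution under the constant-model null.
The order p is unknown, so the test is run for every admissible order and a
gene is called time-dependent when the smallest p-value across orders falls
below a preset significance level (no multiple-testing correction by
default; a Bonferroni option exists for users who want conservatism).

The maximum-likelihood variance estimates divide by M - p, not by the
residual degrees of freedom; the F statistic's degrees of freedom absorb
the difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InvalidOrderError",
    "RankDeficientDesignError",
    "ARFit",
    "ConstantFit",
    "DependenceCall",
    "max_test_order",
    "build_design",
    "fit_ar",
    "fit_constant",
    "likelihood_ratio",
    "f_statistic",
    "call_dependence",
    "dependence_table",
]


class InvalidOrderError(ValueError):
    """The requested AR order is outside the admissible range for this M."""


class RankDeficientDesignError(ValueError):
    """The design matrix at this order is rank-deficient (e.g. a constant
    series); the order carries no information and callers skip it."""


@dataclass(frozen=True)
class ARFit:
    """Least-squares / maximum-likelihood fit of an AR(p) model.

    ``coefficients`` holds (b0, b1, ..., bp) with the intercept first and
    the lag columns ordered oldest-to-newest; ``residual_variance`` is the
    MLE, i.e. the residual sum of squares divided by M - p.
    """

    order: int
    coefficients: np.ndarray
    residual_variance: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order + 1:
            raise ValueError("coefficient vector must have length order + 1")
        if self.residual_variance < 0:
            raise ValueError("residual variance must be nonnegative")


@dataclass(frozen=True)
class ConstantFit:
    """MLE of the constant model over the span m = p+1..M.

    ``order_context`` records the AR order this fit is paired against; it
    fixes the response span so both models see the same M - p observations.
    """

    mean: float
    residual_variance: float
    order_context: int

    def __post_init__(self) -> None:
        if self.residual_variance < 0:
            raise ValueError("residual variance must be nonnegative")


@dataclass(frozen=True)
class DependenceCall:
    """Outcome of the order-scanned likelihood-ratio test for one series."""

    per_order: Mapping[int, tuple[float, float]]  # p -> (F, p-value)
    min_pvalue: float
    best_order: int | None
    time_dependent: bool
    alpha: float
    bonferroni: bool = field(default=False)


def _as_series(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("a series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def max_test_order(m: int) -> int:
    """Largest order usable in the F test: rank needs p <= (M-1)/2 and the
    denominator degrees of freedom need M - 2p - 1 >= 1."""
    return (m - 2) // 2


def build_design(values, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response Y (length M-p) and design X (shape (M-p, p+1)) for AR(p).

    Row r of Y is x_{p+r}; row r of X is (1, x_r, x_{r+1}, ..., x_{r+p-1})
    (1-based), i.e. the lag columns run oldest to newest.
    """
    x = _as_series(values)
    m = x.size
    if not (1 <= p <= (m - 1) / 2):
        raise InvalidOrderError(
            f"order p={p} not admissible for series length M={m} "
            f"(need 1 <= p <= (M-1)/2)"
        )
    n = m - p
    y = x[p:]
    design = np.empty((n, p + 1))
    design[:, 0] = 1.0
    for j in range(1, p + 1):
        design[:, j] = x[j - 1 : j - 1 + n]
    return y, design


def fit_ar(values, p: int) -> ARFit:
    """Fit AR(p) by least squares (the Gaussian MLE).

    Raises :class:`RankDeficientDesignError` when the design has rank
    below p + 1 — e.g. for a constant series — so callers can skip the
    order instead of failing the gene.
    """
    y, design = build_design(values, p)
    if np.linalg.matrix_rank(design) < p + 1:
        raise RankDeficientDesignError(
            f"design matrix rank-deficient at order p={p}"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    s2 = float(resid @ resid) / y.size
    return ARFit(order=p, coefficients=beta, residual_variance=max(s2, 0.0))


def fit_constant(values, p: int) -> ConstantFit:
    """Fit the constant model on the span m = p+1..M (M - p observations),
    matching the AR(p) response span; the variance divisor is M - p."""
    x = _as_series(values)
    m = x.size
    if not (1 <= p <= (m - 1) / 2):
        raise InvalidOrderError(
            f"order p={p} not admissible for series length M={m}"
        )
    span = x[p:]
    mean = float(span.mean())
    s2 = float(np.mean((span - mean) ** 2))
    return ConstantFit(mean=mean, residual_variance=max(s2, 0.0),
                       order_context=p)


def likelihood_ratio(ar: ARFit, const: ConstantFit, m: int) -> float:
    """Lambda = (s2_ar / s2_const)^((M-p)/2), in [0, 1] by nesting."""
    if ar.order != const.order_context:
        raise ValueError("AR and constant fits must share the same order")
    if const.residual_variance == 0.0:
        raise RankDeficientDesignError(
            "degenerate constant series: both models fit exactly"
        )
    ratio = min(ar.residual_variance / const.residual_variance, 1.0)
    return ratio ** ((m - ar.order) / 2.0)


def f_statistic(values, p: int) -> tuple[float, float]:
    """F statistic and upper-tail p-value of the AR(p)-vs-constant test.

    F = (M - 2p - 1)/p * (s2_const/s2_ar - 1), referred to F(p, M-2p-1).
    A perfect AR fit (s2_ar = 0) gives F = +inf, p-value 0; a degenerate
    constant span (s2_const = 0) gives F = 0, p-value 1 — a flat series
    carries no time information.
    """
    x = _as_series(values)
    m = x.size
    dof2 = m - 2 * p - 1
    if p < 1 or dof2 < 1 or p > (m - 1) / 2:
        raise InvalidOrderError(
            f"order p={p} not admissible for the F test at M={m} "
            f"(need M - 2p - 1 >= 1)"
        )
    ar = fit_ar(x, p)  # rank-deficient designs raise; callers skip
    const = fit_constant(x, p)
    if const.residual_variance == 0.0:
        return 0.0, 1.0
    # an exact AR fit leaves only rounding noise in the residual
    if ar.residual_variance <= 1e-12 * const.residual_variance:
        return math.inf, 0.0
    f_val = (dof2 / p) * (const.residual_variance / ar.residual_variance - 1.0)
    f_val = max(f_val, 0.0)
    return f_val, float(stats.f.sf(f_val, p, dof2))


def call_dependence(values, alpha: float = 0.01,
                    bonferroni: bool = False) -> DependenceCall:
    """Scan all admissible orders and call the series time-dependent when
    the minimum p-value falls below ``alpha``.

    Orders with a rank-deficient design are skipped; if every order is
    skipped (a fully degenerate series) the call is time-independent with
    min_pvalue 1.  With ``bonferroni=True`` the threshold is divided by
    the number of orders actually tested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    x = _as_series(values)
    m = x.size
    if m < 4:
        raise ValueError("need at least 4 time points to test dependence")
    per_order: dict[int, tuple[float, float]] = {}
    for p in range(1, max_test_order(m) + 1):
        try:
            per_order[p] = f_statistic(x, p)
        except RankDeficientDesignError:
            continue
    if not per_order:
        return DependenceCall(per_order={}, min_pvalue=1.0, best_order=None,
                              time_dependent=False, alpha=alpha,
                              bonferroni=bonferroni)
    best_order = min(per_order, key=lambda p: (per_order[p][1], p))
    min_pvalue = per_order[best_order][1]
    threshold = alpha / len(per_order) if bonferroni else alpha
    return DependenceCall(per_order=per_order, min_pvalue=min_pvalue,
                          best_order=best_order,
                          time_dependent=min_pvalue < threshold,
                          alpha=alpha, bonferroni=bonferroni)


def dependence_table(expression: pd.DataFrame, alpha: float = 0.01,
                     bonferroni: bool = False) -> pd.DataFrame:
    """Run :func:`call_dependence` on every row of a gene x time matrix.

    Returns a frame indexed by gene id with columns ``best_order``, ``F``,
    ``min_pvalue`` and ``time_dependent`` — the exportable per-gene
    summary of the test.
    """
    rows = []
    for gene_id, row in expression.iterrows():
        call = call_dependence(row.to_numpy(dtype=float), alpha=alpha,
                               bonferroni=bonferroni)
        if call.best_order is None:
            f_val = float("nan")
        else:
            f_val = call.per_order[call.best_order][0]
        rows.append((gene_id, call.best_order, f_val, call.min_pvalue,
                     call.time_dependent))
    return pd.DataFrame(
        rows, columns=["gene_id", "best_order", "F", "min_pvalue",
                       "time_dependent"]
    ).set_index("gene_id")
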