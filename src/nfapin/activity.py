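"""Noise filtering and per-gene activity thresholds.

Each gene gets its own activity cutoff derived from the moments of its
expression profile:

    threshold = u + k * sigma * (1 - F),      F = 1 / (1 + sigma^2)

where u and sigma are the mean and (population) standard deviation of the
profile, k is a global coefficient in [0, 3] (default 2.5), and F is a
damping factor: high-variance genes approach the classical k-sigma rule
while flat genes degenerate to threshold = u.  A protein is *active* at a
time point when its expression strictly exceeds its threshold there.

Before thresholds are applied, noise genes — those called time-independent
by the AR likelihood-ratio test AND whose mean expression is very small —
are discarded.  "Very small" defaults to the 20th percentile of the gene
means of the dataset at hand and can be overridden by an absolute floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .timeseries import DependenceCall

__all__ = [
    "ActivityProfile",
    "ActivityMatrix",
    "NoiseFilterConfig",
    "active_threshold",
    "activity_profile",
    "resolve_mean_floor",
    "filter_noise",
    "activity_matrix",
]

DEFAULT_K = 2.5


@dataclass(frozen=True)
class ActivityProfile:
    """One gene's threshold decomposition and per-time activity flags."""

    gene_id: str
    mean: float
    sd: float
    damping: float  # F = 1 / (1 + sd^2), in (0, 1]
    threshold: float
    active_at: np.ndarray  # boolean, length M


@dataclass(frozen=True)
class ActivityMatrix:
    """Boolean gene x time activity table plus the per-gene thresholds."""

    flags: pd.DataFrame  # bool, genes x time points
    thresholds: pd.Series  # float, indexed like flags
    k: float

    @property
    def n_timepoints(self) -> int:
        return self.flags.shape[1]

    def active_genes_at(self, t: int) -> set[str]:
        col = self.flags.iloc[:, t]
        return set(col.index[col])

    def to_frame(self) -> pd.DataFrame:
        """Exportable table: threshold column then M columns of 0/1."""
        out = self.flags.astype(int)
        out.insert(0, "threshold", self.thresholds)
        return out


@dataclass(frozen=True)
class NoiseFilterConfig:
    """Parameters of the noise filter and threshold computation.

    ``mean_floor`` is an absolute cutoff; when None, the floor is the
    ``mean_floor_percentile``-th percentile of the dataset's gene means.
    """

    alpha: float = 0.01
    k: float = DEFAULT_K
    mean_floor: float | None = None
    mean_floor_percentile: float = 20.0
    bonferroni: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0.0 <= self.k <= 3.0:
            raise ValueError("k must lie in [0, 3]")
        if not 0.0 <= self.mean_floor_percentile <= 100.0:
            raise ValueError("mean_floor_percentile must lie in [0, 100]")


def active_threshold(values, k: float = DEFAULT_K
                     ) -> tuple[float, float, float, float]:
    """Return (u, sigma, F, threshold) for one profile.

    sigma is the population standard deviation (divisor M): u and sigma
    are descriptive moments of the fixed-length profile, not estimates of
    an infinite-population quantity.
    """
    if not 0.0 <= k <= 3.0:
        raise ValueError("k must lie in [0, 3]")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    u = float(x.mean())
    sigma = float(x.std(ddof=0))
    damping = 1.0 / (1.0 + sigma**2)
    threshold = u + k * sigma * (1.0 - damping)
    return u, sigma, damping, threshold


def activity_profile(gene_id: str, values, k: float = DEFAULT_K
                     ) -> ActivityProfile:
    """Threshold one profile; activity is strict: expression > threshold,
    so ties at the threshold (and all points of a constant series) are
    inactive."""
    x = np.asarray(values, dtype=float)
    u, sigma, damping, threshold = active_threshold(x, k)
    return ActivityProfile(gene_id=gene_id, mean=u, sd=sigma,
                           damping=damping, threshold=threshold,
                           active_at=x > threshold)


def resolve_mean_floor(means: pd.Series, cfg: NoiseFilterConfig) -> float:
    """Absolute floor if configured, else the dataset percentile."""
    if cfg.mean_floor is not None:
        return float(cfg.mean_floor)
    return float(np.percentile(means.to_numpy(dtype=float),
                               cfg.mean_floor_percentile))


def filter_noise(expression: pd.DataFrame,
                 calls: Mapping[str, DependenceCall],
                 cfg: NoiseFilterConfig | None = None) -> pd.Index:
    """Return the retained gene ids.

    A gene is removed iff it is time-independent AND its mean expression
    is below the floor; both conditions are required, so a dim but
    time-dependent gene survives, as does a bright flat one.
    """
    cfg = cfg or NoiseFilterConfig()
    missing = [g for g in expression.index if g not in calls]
    if missing:
        raise ValueError(
            f"{len(missing)} genes lack a dependence call "
            f"(first: {missing[0]!r})"
        )
    means = expression.mean(axis=1)
    floor = resolve_mean_floor(means, cfg)
    keep = [
        g for g in expression.index
        if calls[g].time_dependent or means.loc[g] >= floor
    ]
    return pd.Index(keep)


def activity_matrix(expression: pd.DataFrame,
                    k: float = DEFAULT_K) -> ActivityMatrix:
    """Threshold every (already noise-filtered) profile into a boolean
    gene x time table."""
    values = expression.to_numpy(dtype=float)
    u = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=0)
    damping = 1.0 / (1.0 + sigma**2)
    thresholds = u + k * sigma * (1.0 - damping)
    flags = pd.DataFrame(values > thresholds[:, None],
                         index=expression.index,
                         columns=expression.columns)
    return ActivityMatrix(flags=flags,
                          thresholds=pd.Series(thresholds,
                                               index=expression.index,
                                               name="threshold"),
                          k=k)
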