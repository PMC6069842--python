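"""Downsampling harness and sequencing-depth saturation models.

Footprint yield grows approximately linearly with read depth over the
practically sampled range, while ChIP-recovery AUC grows concavely and
saturates; this module provides the two corresponding fits:

* :func:`fit_linear` — ordinary least squares of a metric on depth, with the
  slope expressed per **million** reads;
* :func:`fit_power` — ``value = a * depth^b`` fitted by OLS on the log–log
  scale (replicates averaged per depth first), plus
  :func:`predict_reads_for_auc` to invert the fitted curve for a target AUC,
  flagging extrapolation beyond the fitted depth range.

:func:`downsample` reproduces the common convention of seeding the sampler
with the target count itself when no seed is given, so repeated runs at the
same depth select the same subsample (note this couples seed to depth).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TypeVar

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthSeries",
    "LinearFit",
    "PowerFit",
    "ReadPrediction",
    "DEFAULT_DEPTH_GRID",
    "downsample",
    "fit_linear",
    "fit_power",
    "predict_reads_for_auc",
    "saturation_fraction",
]

T = TypeVar("T")

#: Conventional downsampling grid: 20M to 200M reads, three samplings each.
DEFAULT_DEPTH_GRID = tuple(
    int(d * 1e6) for d in (20, 40, 60, 80, 100, 120, 140, 160, 200)
)
DEFAULT_REPLICATES_PER_DEPTH = 3


@dataclass
class DepthSeries:
    """A metric measured at several read depths with repeated samplings.

    ``values[i, j]`` is the metric (footprint count, mean AUC, ...) at
    ``depths[i]`` for sampling repetition ``j``.
    """

    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.depths <= 0):
            raise ValueError("depths must be positive")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.values.shape[0] != len(self.depths):
            raise ValueError(
                f"values has {self.values.shape[0]} depth rows, expected {len(self.depths)}"
            )

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def depth_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: depth, replicate, value."""
        rows = [
            {"depth": int(d), "replicate": j, "value": self.values[i, j]}
            for i, d in enumerate(self.depths)
            for j in range(self.n_replicates)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthSeries":
        df = pd.read_csv(path, sep="\t")
        piv = df.pivot(index="depth", columns="replicate", values="value").sort_index()
        return cls(piv.index.to_numpy(), piv.to_numpy())


@dataclass(frozen=True)
class LinearFit:
    """OLS line of a metric on depth; slope is per million reads."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class PowerFit:
    """Power-law ``value = a * depth^b`` fitted on the log–log scale."""

    a: float
    b: float
    depth_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale a must be positive")

    def predict(self, depth: float) -> float:
        return self.a * depth ** self.b


@dataclass(frozen=True)
class ReadPrediction:
    """Predicted read depth for a target metric value."""

    reads: float
    target: float
    extrapolated: bool


def downsample(
    items: Sequence[T], n_target: int, seed: int | None = None
) -> list[T]:
    """Uniform sample of ``n_target`` items without replacement.

    When ``seed`` is omitted it defaults to ``n_target`` itself, the
    convention of seeding each downsampling by its target count; repeated
    calls at one depth are then identical, at the cost of coupling seed to
    depth.  Sampled items are returned in their original order.
    """
    if n_target > len(items):
        raise ValueError(f"cannot sample {n_target} from {len(items)} items")
    if seed is None:
        seed = n_target
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(items), size=n_target, replace=False))
    return [items[i] for i in idx]


def fit_linear(series: DepthSeries) -> LinearFit:
    """OLS of all replicate points on depth (in millions of reads)."""
    if len(np.unique(series.depths)) < 2:
        raise ValueError("need at least 2 distinct depths for a linear fit")
    x = np.repeat(series.depths / 1e6, series.n_replicates)
    y = series.values.ravel()
    if np.ptp(y) == 0:
        # Constant metric: exact flat line, conventionally R^2 = 1.
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=1.0)
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def fit_power(series: DepthSeries) -> PowerFit:
    """Fit ``value = a * depth^b`` by OLS of log(value) on log(depth).

    Replicates are averaged per depth before fitting.  All values must be
    positive (the log is undefined otherwise).  The log–log OLS is
    deterministic and closed-form; it recovers noiseless power laws exactly.
    """
    if len(np.unique(series.depths)) < 2:
        raise ValueError("need at least 2 distinct depths for a power fit")
    means = series.depth_means()
    if np.any(means <= 0):
        raise ValueError("power fit requires strictly positive values")
    b, log_a = np.polyfit(np.log(series.depths), np.log(means), 1)
    return PowerFit(
        a=float(np.exp(log_a)),
        b=float(b),
        depth_range=(float(series.depths[0]), float(series.depths[-1])),
    )


def predict_reads_for_auc(fit: PowerFit, target_auc: float) -> ReadPrediction:
    """Invert a fitted power curve: reads needed to reach a target value.

    Returns ``(target / a) ** (1 / b)``; the inverse property holds, i.e.
    evaluating the fitted curve at the returned depth reproduces the target.
    The result is flagged as an extrapolation when it lies beyond the maximum
    fitted depth.  Requires a rising curve (``b > 0``).
    """
    if fit.b <= 1e-9:
        raise ValueError(f"power curve with b={fit.b} never crosses the target")
    if target_auc <= 0:
        raise ValueError("target must be positive")
    reads = (target_auc / fit.a) ** (1.0 / fit.b)
    return ReadPrediction(
        reads=float(reads),
        target=float(target_auc),
        extrapolated=bool(reads > fit.depth_range[1] * (1 + 1e-12)),
    )


def saturation_fraction(
    series: DepthSeries,
    at_depth: float,
    reference_depth: float,
    basis: str = "raw",
) -> float:
    """How much of the reference-depth metric a shallower depth achieves.

    ``basis='raw'`` (default) is the plain ratio of depth means;
    ``basis='above_random'`` subtracts the AUC chance level 0.5 from both
    means first.  Both bases are meaningful for saturation statements such as
    "depth X recovers 95% of the metric at depth Y"; the choice is recorded
    by the caller.
    """
    means = dict(zip(series.depths, series.depth_means()))
    for d in (at_depth, reference_depth):
        if float(d) not in means:
            raise ValueError(f"depth {d} not present in series")
    m_at, m_ref = means[float(at_depth)], means[float(reference_depth)]
    if basis == "raw":
        return float(m_at / m_ref)
    if basis == "above_random":
        return float((m_at - 0.5) / (m_ref - 0.5))
    raise ValueError(f"unknown basis {basis!r}")


# ---------------------------------------------------------------------------
# Synthetic depth series
# ---------------------------------------------------------------------------

def depth_response_params(base, depth: int, d0: float):
    """Derive depth-dependent simulation parameters.

    Models the empirical saturation of footprint detection with library
    depth: detection sensitivity scales as ``1 - exp(-depth / d0)`` (near
    linear for ``depth << d0``, saturating above), as does the score
    separation between true and false footprints.  ``d0`` is the depth scale
    (reads) at which detection reaches ~63% of its asymptote.
    """
    from dataclasses import replace as _replace

    s = 1.0 - np.exp(-depth / d0)
    return _replace(
        base,
        depth=int(depth),
        footprint_sensitivity=base.footprint_sensitivity * s,
        score_separation=base.score_separation * s,
    )


def simulate_depth_series(
    base_params,
    depths: Sequence[int],
    n_replicates: int,
    d0: float,
    metric: str,
    seed: int,
) -> DepthSeries:
    """Run the synthetic world across a depth grid and collect a metric.

    ``metric`` is ``'n_footprints'`` (replicate-1 footprint count) or
    ``'mean_auc'`` (expected-mode mean AUC over TFs with both classes).
    Each (depth, repetition) cell uses its own derived sub-seed.
    """
    from dataclasses import replace as _replace

    from . import chip as _chip
    from .simulate import simulate_world

    if metric not in ("n_footprints", "mean_auc"):
        raise ValueError(f"unknown metric {metric!r}")
    values = np.empty((len(depths), n_replicates))
    for i, d in enumerate(depths):
        for j in range(n_replicates):
            params = depth_response_params(base_params, d, d0)
            params = _replace(params, seed=(seed + 7919 * i + j) % (2**31))
            world = simulate_world(params)
            if metric == "n_footprints":
                values[i, j] = len(world.footprints_rep1)
            else:
                table = _chip.assign_footprint_scores(
                    world.sites, world.footprints_rep1
                )
                results = _chip.per_tf_roc(table, mode="expected", skip_undefined=True)
                values[i, j] = _chip.mean_auc(results)
    return DepthSeries(np.asarray(depths, dtype=float), values)
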