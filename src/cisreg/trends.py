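"""Gaussian-process expression trends over differentiation pseudotime.

Single-cell counts are depth-normalised per cell, variance-stabilised with
t = ln(alpha*y + beta) (alpha=100, beta=1, so t=0 at y=0), and a GP with a
Matern-5/2 kernel plus observation noise is fitted to t against pseudotime.
The posterior mean and 95% band on the transformed scale are mapped back
through the exact inverse (exp(t)-beta)/alpha; because the inverse is
monotone, the transformed-scale mean maps to the median of the (lognormal-
style) posterior on the original count scale, which is what gets reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .genomics import BoxplotStats, boxplot_stats

__all__ = [
    "TransformParams",
    "ExpressionSeries",
    "GPTrend",
    "depth_normalize",
    "vst",
    "inverse_vst",
    "fit_gp_trend",
    "stage_summary",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TransformParams:
    """Variance-stabilising transform t = ln(alpha*y + beta)."""

    alpha: float = 100.0
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def vst(y: Union[float, np.ndarray], params: TransformParams = TransformParams()):
    """ln(alpha*y + beta); defined for y >= 0."""
    arr = np.asarray(y, dtype=float)
    if (arr < 0).any():
        raise ValueError("expression values must be >= 0")
    out = np.log(params.alpha * arr + params.beta)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def inverse_vst(t: Union[float, np.ndarray],
                params: TransformParams = TransformParams()):
    """(exp(t) - beta)/alpha; exact inverse of :func:`vst`."""
    arr = np.asarray(t, dtype=float)
    out = (np.exp(arr) - params.beta) / params.alpha
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def depth_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell (row) by its total count, rescale by the median total.

    The median-cell-total scale keeps normalised values on a count-like
    scale rather than fractions.
    """
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"cells with zero total counts: {list(zero.index)}")
    if (counts.values < 0).any():
        raise ValueError("counts must be >= 0")
    scale = float(totals.median())
    return counts.div(totals, axis=0) * scale


@dataclass(frozen=True)
class ExpressionSeries:
    """Expression of one gene over pseudotime, one value per cell."""

    pseudotime: np.ndarray
    expression: np.ndarray
    gene: str = ""

    def __post_init__(self):
        t = np.asarray(self.pseudotime, dtype=float)
        y = np.asarray(self.expression, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("pseudotime and expression must be equal-length 1-D")
        if not np.isfinite(t).all():
            raise ValueError("pseudotime must be finite")
        if (y < 0).any():
            raise ValueError("expression must be >= 0")
        object.__setattr__(self, "pseudotime", t)
        object.__setattr__(self, "expression", y)


@dataclass(frozen=True)
class GPTrend:
    """Fitted trend on the original count scale over a pseudotime grid."""

    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    gene: str = ""
    log_marginal_likelihood: float = float("nan")

    def __post_init__(self):
        if not (np.all(self.lower <= self.median + 1e-12)
                and np.all(self.median <= self.upper + 1e-12)):
            raise ValueError("band ordering violated: need lower <= median <= upper")


def fit_gp_trend(series: ExpressionSeries,
                 params: TransformParams = TransformParams(),
                 grid: Optional[np.ndarray] = None,
                 n_grid: int = 100,
                 n_restarts: int = 3,
                 seed: int = 0) -> GPTrend:
    """GP regression of transformed expression on pseudotime.

    Kernel: amplitude * Matern(nu=5/2) + white observation noise, all
    hyperparameters fitted by marginal-likelihood maximisation with
    ``n_restarts`` seeded restarts.  The posterior mean +/- 1.96 sd band on
    the transformed scale is mapped through the monotone inverse transform;
    the lower band is clamped at zero since counts cannot be negative.
    """
    t, y = series.pseudotime, series.expression
    if t.size < 10:
        raise ValueError(f"need >= 10 cells to fit a trend, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("degenerate pseudotime: all values identical")
    if grid is None:
        grid = np.linspace(t.min(), t.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < t.min() - 1e-9 or grid.max() > t.max() + 1e-9:
        raise ValueError("grid extends beyond the observed pseudotime range")

    z = vst(y, params)
    span = float(np.ptp(t))
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=span / 5, length_scale_bounds=(span / 100, span * 10),
                 nu=2.5)
        + WhiteKernel(noise_level=max(np.var(z), 1e-4) / 10,
                      noise_level_bounds=(1e-6, 1e2))
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    gpr.fit(t.reshape(-1, 1), z)
    mean, sd = gpr.predict(grid.reshape(-1, 1), return_std=True)
    lower_t, upper_t = mean - Z_95 * sd, mean + Z_95 * sd
    return GPTrend(
        grid=grid,
        median=np.maximum(inverse_vst(mean, params), 0.0),
        lower=np.maximum(inverse_vst(lower_t, params), 0.0),
        upper=np.maximum(inverse_vst(upper_t, params), 0.0),
        gene=series.gene,
        log_marginal_likelihood=float(gpr.log_marginal_likelihood_value_),
    )


def stage_summary(values: Sequence[float], stages: Sequence[str],
                  stage_order: Optional[Sequence[str]] = None) -> dict[str, BoxplotStats]:
    """Tukey boxplot stats per developmental stage, in the given order."""
    values = np.asarray(values, dtype=float)
    stages = list(stages)
    if len(values) != len(stages):
        raise ValueError("values and stage labels differ in length")
    present = list(dict.fromkeys(stages))
    order = list(stage_order) if stage_order is not None else present
    unknown = set(stages) - set(order)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    out = {}
    for s in order:
        vals = values[[i for i, lab in enumerate(stages) if lab == s]]
        if vals.size == 0:
            raise ValueError(f"stage {s!r} has no values")
        out[s] = boxplot_stats(vals)
    return out
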