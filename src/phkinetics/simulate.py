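"""Posterior(-predictive) simulation of pH kinetics and rate-vs-dose curves.

For a user-chosen lactate/atmosphere condition the full posterior sample is
pushed through the two-phase model to give a median curve and a pointwise
95% credible band over a time grid.  Two toggles control what the band
expresses:

* ``new_batch`` (default True) draws a fresh batch initial pH per posterior
  draw from N(mu_pH0, sigma_pH0), so the band covers parameter uncertainty
  *and* batch-to-batch variability — the view a producer wants for a future
  batch.  With ``new_batch=False`` the curve starts at mu_pH0 (mean batch).
* ``measurement_noise`` (default False) adds N(0, sigma_pH) observation
  noise, widening the band to a predictive band for single measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Condition, acidification_rate
from .mcmc import Trace
from .selection import PosteriorSummary

__all__ = ["KineticsBand", "simulate_kinetics", "rate_curve"]


@dataclass
class KineticsBand:
    """Pointwise median and 95% band of simulated pH over a time grid."""

    time: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    condition: Condition
    new_batch: bool
    measurement_noise: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.time,
                "pH_median": self.median,
                "pH_lower": self.lower,
                "pH_upper": self.upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pooled_or_fixed(trace: Trace, name: str, fixed: float | None, size: int) -> np.ndarray:
    if name in trace.param_names:
        return trace.pooled(name)
    if fixed is None:
        raise ValueError(f"trace holds no draws for {name!r} and the variant does not fix it")
    return np.full(size, float(fixed))


def simulate_kinetics(trace: Trace, condition: Condition, time_grid,
                      new_batch: bool = True, measurement_noise: bool = False,
                      seed: int | None = 0) -> KineticsBand:
    """Simulate pH trajectories under one condition from every pooled draw.

    Returns the pointwise 2.5/50/97.5% quantiles across draws on the grid.
    ``seed`` controls the new-batch and noise draws (irrelevant when both
    toggles are off).
    """
    grid = np.atleast_1d(np.asarray(time_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("time grid must be non-negative")
    condition = Condition(condition.lactate, condition.atmosphere)
    size = trace.n_chains * trace.n_retained
    if size == 0:
        raise ValueError("empty trace")

    mu = trace.pooled("mu_pH0")
    sigma0 = trace.pooled("sigma_pH0")
    sigma = trace.pooled("sigma_pH")
    lam = trace.pooled("lambda")
    delta = trace.pooled(f"delta_{condition.atmosphere.value}")
    n = _pooled_or_fixed(trace, "n", trace.variant.n_fixed, size)
    theta = _pooled_or_fixed(trace, "theta", trace.variant.theta_fixed, size)

    # 0^n := 0 for n > 0; undefined (NaN -> error below) otherwise
    lp = np.where(n > 0, 0.0, np.nan) if condition.lactate == 0 else condition.lactate ** n
    beta = np.exp(lam * lp + delta)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite acidification rate for some posterior draws")

    rng = np.random.default_rng(seed)
    pH0 = mu + sigma0 * rng.standard_normal(size) if new_batch else mu
    curves = pH0[:, None] - beta[:, None] * np.minimum(grid[None, :], theta[:, None])
    if measurement_noise:
        curves = curves + sigma[:, None] * rng.standard_normal(curves.shape)

    lo, med, hi = np.quantile(curves, [0.025, 0.5, 0.975], axis=0, method="linear")
    return KineticsBand(
        time=grid, median=med, lower=lo, upper=hi, condition=condition,
        new_batch=new_batch, measurement_noise=measurement_noise,
    )


def rate_curve(summary: PosteriorSummary, lactate_grid, atmosphere) -> np.ndarray:
    """Acidification rate beta at the point estimates over a lactate grid."""
    grid = np.atleast_1d(np.asarray(lactate_grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("lactate grid must be >= 0")
    state = summary.point_estimates()
    return np.asarray(
        acidification_rate(state.lam, state.n, state.delta_for(atmosphere), grid)
    )


def plot_band(band: KineticsBand, path) -> None:
    """Save a median-curve-plus-band figure for one simulated condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(band.time, band.lower, band.upper, alpha=0.25, label="95% band")
    ax.plot(band.time, band.median, lw=2, label="median")
    ax.set_xlabel("storage time (days)")
    ax.set_ylabel("pH")
    ax.set_title(
        f"{band.condition.lactate}% lactate, {band.condition.atmosphere.value}"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
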