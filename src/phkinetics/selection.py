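"""DIC model comparison, posterior summaries and goodness of fit.

The Deviance Information Criterion uses the Spiegelhalter decomposition:
Dbar (posterior mean of the deviance D = -2 log L stored per retained draw)
plus the effective parameter count pD = Dbar - D(posterior mean), giving
DIC = Dbar + pD = 2*Dbar - D(posterior mean).  The plug-in point is the
posterior mean of *all* sampled quantities, latent batch pH0 values
included; only the observation-model likelihood counts as deviance (the
hierarchical layer sits in the prior).  Different engines implement other
penalties, so absolute DIC values are comparable only within one
implementation — model choice rests on the ordering, not the raw numbers.

Posterior summaries follow the study's convention: the point estimate is
the pooled-chain median and the 95% credibility interval is the (2.5%,
97.5%) quantile pair, with linearly interpolated quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelVariant, ParameterState, log_likelihood
from .mcmc import Trace
from .synth import Dataset

__all__ = [
    "DICResult",
    "PosteriorSummary",
    "compute_dic",
    "select_model",
    "summarize_posterior",
    "goodness_of_fit",
]


@dataclass(frozen=True)
class DICResult:
    """Mean deviance, plug-in deviance, pD and DIC for one fitted variant."""

    variant_name: str
    mean_deviance: float
    plugin_deviance: float
    n_free_parameters: int

    @property
    def p_d(self) -> float:
        return self.mean_deviance - self.plugin_deviance

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.p_d

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_name,
            "mean_deviance": self.mean_deviance,
            "plugin_deviance": self.plugin_deviance,
            "p_d": self.p_d,
            "dic": self.dic,
            "n_free_parameters": self.n_free_parameters,
        }


def _state_from_values(values: dict[str, float], variant: ModelVariant,
                       batch_ids: tuple[str, ...],
                       fixed_values: dict[str, float] | None = None,
                       fixed_pH0: dict[str, float] | None = None) -> ParameterState:
    """Assemble a ParameterState from per-parameter values plus fixed ones."""
    values = {**(fixed_values or {}), **values}
    pH0 = dict(fixed_pH0 or {})
    pH0.update({b: values[f"pH0[{b}]"] for b in batch_ids if f"pH0[{b}]" in values})
    return ParameterState(
        mu_pH0=values["mu_pH0"],
        sigma_pH0=values["sigma_pH0"],
        sigma_pH=values["sigma_pH"],
        lam=values["lambda"],
        delta_Air=values["delta_Air"],
        delta_MAP1=values["delta_MAP1"],
        delta_MAP2=values["delta_MAP2"],
        n=values.get("n", variant.n_fixed if variant.n_fixed is not None else 1.0),
        theta=values.get("theta",
                         variant.theta_fixed if variant.theta_fixed is not None else 15.0),
        pH0_by_batch=pH0 or None,
    )


def posterior_mean_state(trace: Trace) -> ParameterState:
    """Plug-in state at the posterior mean of every sampled quantity."""
    pooled = trace.pooled_matrix()
    values = {nm: float(m) for nm, m in zip(trace.param_names, pooled.mean(axis=0))}
    return _state_from_values(values, trace.variant, trace.batch_ids,
                              trace.fixed_values, trace.fixed_pH0)


def compute_dic(trace: Trace, dataset: Dataset) -> DICResult:
    """DIC of a fitted trace against the dataset it was fitted to.

    Dbar averages the per-draw deviances stored by the sampler; the plug-in
    deviance re-evaluates the likelihood at the posterior-mean state.
    """
    if trace.n_obs != dataset.n_obs:
        raise ValueError(
            f"trace was fitted to {trace.n_obs} observations but dataset has "
            f"{dataset.n_obs}; refusing to compute DIC on mismatched inputs"
        )
    mean_dev = float(trace.deviance.mean())
    state = posterior_mean_state(trace)
    plugin_dev = -2.0 * log_likelihood(dataset, state)
    if not math.isfinite(plugin_dev):
        raise ValueError("likelihood at the posterior mean is non-finite")
    return DICResult(
        variant_name=trace.variant.name,
        mean_deviance=mean_dev,
        plugin_deviance=plugin_dev,
        n_free_parameters=trace.variant.n_free_parameters,
    )


def select_model(results) -> str:
    """Name of the variant with the lowest DIC; parsimony breaks ties."""
    results = list(results)
    if not results:
        raise ValueError("select_model needs at least one DICResult")
    best = min(results, key=lambda r: (r.dic, r.n_free_parameters))
    return best.variant_name


@dataclass
class PosteriorSummary:
    """Pooled-chain medians and 95% credibility intervals per parameter."""

    table: pd.DataFrame  # index: parameter; columns: median, ci_lower, ci_upper
    variant: ModelVariant
    batch_ids: tuple[str, ...]
    fixed_values: dict[str, float] = None  # type: ignore[assignment]
    fixed_pH0: dict[str, float] | None = None

    def median(self, name: str) -> float:
        return float(self.table.loc[name, "median"])

    def interval(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ci_lower"]), float(row["ci_upper"])

    def point_estimates(self) -> ParameterState:
        values = {nm: float(v) for nm, v in self.table["median"].items()}
        return _state_from_values(values, self.variant, self.batch_ids,
                                  self.fixed_values, self.fixed_pH0)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="parameter")


def summarize_posterior(trace: Trace) -> PosteriorSummary:
    """Median and (2.5%, 97.5%) quantiles over all chains pooled.

    Uses linearly interpolated quantiles; latent pH0 values are summarised
    like any other parameter.
    """
    if trace.n_retained == 0:
        raise ValueError("empty trace")
    pooled = trace.pooled_matrix()
    qs = np.quantile(pooled, [0.5, 0.025, 0.975], axis=0, method="linear")
    table = pd.DataFrame(
        {"median": qs[0], "ci_lower": qs[1], "ci_upper": qs[2]},
        index=pd.Index(trace.param_names, name="parameter"),
    )
    return PosteriorSummary(table=table, variant=trace.variant,
                            batch_ids=trace.batch_ids,
                            fixed_values=dict(trace.fixed_values),
                            fixed_pH0=trace.fixed_pH0)


def goodness_of_fit(summary: PosteriorSummary, dataset: Dataset) -> pd.DataFrame:
    """Adjusted pH and residuals at the point estimates, one row per observation.

    Adjusted values evaluate the two-phase mean at the posterior medians with
    each batch's estimated latent initial pH; residual = observed - adjusted.
    """
    state = summary.point_estimates()
    if state.pH0_by_batch is None:
        raise ValueError("summary carries no latent pH0 estimates")
    missing = [b for b in dataset.batch_ids if b not in state.pH0_by_batch]
    if missing:
        raise ValueError(f"dataset batches absent from the posterior summary: {missing}")
    pH0 = np.array([state.pH0_by_batch[b] for b in dataset.batch_ids])
    from .model import lactate_power

    lp = lactate_power(dataset.lactate, state.n)
    beta = np.exp(state.lam * lp + state.deltas[dataset.atm_idx])
    adjusted = pH0[dataset.batch_idx] - beta * np.minimum(dataset.day, state.theta)
    out = dataset.frame.copy()
    out["pH_adjusted"] = adjusted
    out["residual"] = out["pH"] - adjusted
    return out
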