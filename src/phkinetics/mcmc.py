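"""Metropolis-within-Gibbs sampler for the hierarchical acidification model.

One sweep updates every free top-level parameter with an adaptive Gaussian
random-walk Metropolis step (one parameter per block), then refreshes all
latent batch-level initial pH values with an exact conjugate Gibbs draw
(their full conditional is normal because the two-phase mean is linear in
pH0).  Standard-deviation parameters are proposed on the log scale with the
Jacobian correction, so positivity never costs rejections.  Proposal scales
follow a Robbins-Monro recursion toward a 0.44 acceptance rate during
burn-in only and are frozen afterwards, keeping the post-burn-in kernel a
valid fixed MCMC kernel.

With an empty dataset the likelihood is identically zero and the sampler
targets the prior — useful for prior-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    LOG_2PI,
    ModelVariant,
    ParameterState,
    half_normal_logpdf,
    lactate_power,
    normal_logpdf,
    uniform_logpdf,
)
from .synth import Dataset

__all__ = ["MCMCConfig", "Trace", "run_mcmc"]

TARGET_ACCEPTANCE = 0.44

# Initial random-walk proposal sds (log-scale sds for the sigmas); the
# burn-in adaptation tunes them per chain and per parameter.
_INIT_SCALES = {
    "mu_pH0": 0.05,
    "sigma_pH0": 0.4,
    "sigma_pH": 0.3,
    "lambda": 0.05,
    "delta_Air": 0.1,
    "delta_MAP1": 0.1,
    "delta_MAP2": 0.1,
    "n": 0.3,
    "theta": 0.8,
}

_LOG_SCALE_PARAMS = frozenset({"sigma_pH0", "sigma_pH"})
_LIKELIHOOD_PARAMS = frozenset(
    {"sigma_pH", "lambda", "delta_Air", "delta_MAP1", "delta_MAP2", "n", "theta"}
)
_HIER_PARAMS = frozenset({"mu_pH0", "sigma_pH0"})


@dataclass(frozen=True)
class MCMCConfig:
    """Chain bookkeeping: counts, thinning, seed and starting values.

    ``n_iterations`` are post-burn-in sweeps per chain; the retained sample
    per chain is ``n_iterations / thinning`` (defaults: 60000 / 6 = 10000,
    i.e. 30000 pooled over the default three chains).  ``initial_values``
    is either ``"auto"`` (overdispersed prior draws per chain) or a sequence
    of per-chain mappings of parameter name to start value (optionally with
    a ``"pH0"`` entry mapping batch ids to values).
    """

    n_chains: int = 3
    burn_in: int = 5000
    n_iterations: int = 60000
    thinning: int = 6
    seed: int = 0
    initial_values: str | Sequence[Mapping] = "auto"

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.burn_in < 0 or self.n_iterations < 1 or self.thinning < 1:
            raise ValueError("burn_in >= 0, n_iterations >= 1, thinning >= 1 required")
        if self.n_iterations % self.thinning != 0:
            raise ValueError("thinning must divide n_iterations")
        if self.initial_values != "auto" and len(self.initial_values) != self.n_chains:
            raise ValueError("initial_values must be 'auto' or one mapping per chain")

    @property
    def retained_per_chain(self) -> int:
        return self.n_iterations // self.thinning


@dataclass
class Trace:
    """Retained posterior draws, organised by chain, with provenance.

    ``draws`` has shape (n_chains, retained_per_chain, n_parameters) in the
    order of ``param_names`` (free top-level parameters first, then the
    latent ``pH0[batch]`` entries).  ``deviance`` stores -2 * log likelihood
    per retained draw.  ``acceptance`` maps parameter name to the per-chain
    post-burn-in acceptance rates; ``proposal_scales`` records the per-chain
    adapted scales at the end of burn-in and at the end of the run (equal by
    construction — adaptation is frozen after burn-in).
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    deviance: np.ndarray
    variant: ModelVariant
    config: MCMCConfig
    n_obs: int
    batch_ids: tuple[str, ...]
    acceptance: dict[str, np.ndarray] = field(default_factory=dict)
    proposal_scales: dict[str, list[dict[str, float]]] = field(default_factory=dict)
    # user-pinned quantities (excluded from draws but needed to rebuild states)
    fixed_values: dict[str, float] = field(default_factory=dict)
    fixed_pH0: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.deviance = np.asarray(self.deviance, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, retained, n_parameters)")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws third dimension must match param_names")
        if self.deviance.shape != self.draws.shape[:2]:
            raise ValueError("deviance must be (n_chains, retained)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def index_of(self, name: str) -> int:
        return self.param_names.index(name)

    def chain(self, name: str, chain: int) -> np.ndarray:
        return self.draws[chain, :, self.index_of(name)]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[:, :, self.index_of(name)].reshape(-1)

    def pooled_matrix(self) -> np.ndarray:
        """(n_chains * retained, n_parameters) pooled draw matrix."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_dataframe(self):
        """Long-format view: chain, iteration, parameter, value (+ deviance)."""
        import pandas as pd

        cfg = self.config
        iters = cfg.burn_in + cfg.thinning * np.arange(1, self.n_retained + 1)
        records = []
        for c in range(self.n_chains):
            for j, name in enumerate(self.param_names):
                records.append(
                    pd.DataFrame(
                        {"chain": c, "iteration": iters, "parameter": name,
                         "value": self.draws[c, :, j]}
                    )
                )
            records.append(
                pd.DataFrame(
                    {"chain": c, "iteration": iters, "parameter": "deviance",
                     "value": self.deviance[c]}
                )
            )
        return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Chain internals
# ---------------------------------------------------------------------------

def _prior_logpdf(name: str, value: float, variant: ModelVariant) -> float:
    pri = variant.priors
    if name == "mu_pH0":
        return normal_logpdf(value, pri.mu_pH0_mean, pri.mu_pH0_sd)
    if name == "sigma_pH0":
        return half_normal_logpdf(value, pri.sigma_pH0_scale)
    if name == "sigma_pH":
        return half_normal_logpdf(value, pri.sigma_pH_scale)
    return uniform_logpdf(value, *pri.bounds_for(name))


def _hier_logpdf(pH0: np.ndarray, mu: float, sigma0: float) -> float:
    if pH0.size == 0:
        return 0.0
    if sigma0 <= 0:
        return -math.inf
    z = (pH0 - mu) / sigma0
    return -0.5 * float(np.dot(z, z)) - pH0.size * (math.log(sigma0) + 0.5 * LOG_2PI)


class _LikelihoodEngine:
    """Vectorised observation-model log likelihood over a fixed dataset."""

    def __init__(self, dataset: Dataset):
        self.n = dataset.n_obs
        self.y = dataset.pH
        self.day = dataset.day
        self.lact = dataset.lactate
        self.atm = dataset.atm_idx
        self.bidx = dataset.batch_idx
        self.n_batches = dataset.n_batches
        self.batch_counts = np.bincount(self.bidx, minlength=self.n_batches).astype(float)
        self.has_zero_lactate = bool(np.any(self.lact == 0))
        self.batch_ids = dataset.batch_ids

    def effective_time(self, theta: float) -> np.ndarray:
        return np.minimum(self.day, theta)

    def betas(self, vals: dict) -> np.ndarray | None:
        """Per-observation acidification rates; None when undefined."""
        n = vals["n"]
        if n == 1.0:
            lp = self.lact
        elif n <= 0 and self.has_zero_lactate:
            return None
        else:
            lp = lactate_power(self.lact, n)
        deltas = np.array([vals["delta_Air"], vals["delta_MAP1"], vals["delta_MAP2"]])
        eta = vals["lambda"] * lp + deltas[self.atm]
        beta = np.exp(eta)
        return beta if np.all(np.isfinite(beta)) else None

    def loglik(self, vals: dict, pH0: np.ndarray) -> float:
        if self.n == 0:
            return 0.0
        beta = self.betas(vals)
        if beta is None:
            return -math.inf
        m = pH0[self.bidx] - beta * self.effective_time(vals["theta"])
        sig = vals["sigma_pH"]
        if sig <= 0:
            return -math.inf
        z = (self.y - m) / sig
        val = -0.5 * float(np.dot(z, z)) - self.n * (math.log(sig) + 0.5 * LOG_2PI)
        return val if math.isfinite(val) else -math.inf


def _draw_initial(variant: ModelVariant, rng: np.random.Generator) -> dict:
    """Overdispersed starting values from the priors.

    Uniform supports are shrunk 10% toward the centre so no chain starts on
    a zero-density boundary; sd parameters start at |half-normal| draws
    bounded away from zero.
    """
    pri = variant.priors
    vals = {
        "mu_pH0": pri.mu_pH0_mean + pri.mu_pH0_sd * rng.standard_normal(),
        "sigma_pH0": max(0.02, abs(pri.sigma_pH0_scale * rng.standard_normal())),
        "sigma_pH": max(0.02, abs(pri.sigma_pH_scale * rng.standard_normal())),
    }

    def shrunk_uniform(lo: float, hi: float) -> float:
        span = hi - lo
        return rng.uniform(lo + 0.05 * span, hi - 0.05 * span)

    vals["lambda"] = shrunk_uniform(*pri.lambda_bounds)
    for name in ("delta_Air", "delta_MAP1", "delta_MAP2"):
        vals[name] = shrunk_uniform(*pri.delta_bounds)
    vals["n"] = variant.n_fixed if variant.n_fixed is not None else shrunk_uniform(*pri.n_bounds)
    vals["theta"] = (variant.theta_fixed if variant.theta_fixed is not None
                     else shrunk_uniform(*pri.theta_bounds))
    return vals


def _run_chain(engine: _LikelihoodEngine, variant: ModelVariant, config: MCMCConfig,
               rng: np.random.Generator, free_names: tuple[str, ...],
               init: Mapping | None, fixed: Mapping, sample_pH0: bool,
               fixed_pH0: np.ndarray | None):
    burn, total_iters, thin = config.burn_in, config.n_iterations, config.thinning
    n_keep = config.retained_per_chain
    nb = engine.n_batches

    # ---- starting state ----------------------------------------------------
    def state_logpost(vals, pH0):
        prior = sum(_prior_logpdf(nm, vals[nm], variant) for nm in free_names)
        hier = _hier_logpdf(pH0, vals["mu_pH0"], vals["sigma_pH0"])
        ll = engine.loglik(vals, pH0)
        return prior, hier, ll

    if init is not None:
        vals = _draw_initial(variant, rng)
        for nm, v in init.items():
            if nm != "pH0":
                vals[nm] = float(v)
        vals.update({k: float(v) for k, v in fixed.items() if k != "pH0"})
        if fixed_pH0 is not None:
            pH0 = fixed_pH0.copy()
        elif "pH0" in init:
            given = init["pH0"]
            pH0 = np.array([float(given[b]) for b in engine.batch_ids])
        else:
            pH0 = vals["mu_pH0"] + vals["sigma_pH0"] * rng.standard_normal(nb)
        prior, hier, ll = state_logpost(vals, pH0)
        if not all(map(math.isfinite, (prior, hier, ll))):
            raise ValueError(
                "supplied initial values give a non-finite log posterior: "
                + _diagnose_nonfinite(vals, pH0, variant, engine, free_names)
            )
    else:
        for _ in range(100):
            vals = _draw_initial(variant, rng)
            vals.update({k: float(v) for k, v in fixed.items() if k != "pH0"})
            pH0 = (fixed_pH0.copy() if fixed_pH0 is not None
                   else vals["mu_pH0"] + vals["sigma_pH0"] * rng.standard_normal(nb))
            prior, hier, ll = state_logpost(vals, pH0)
            if all(map(math.isfinite, (prior, hier, ll))):
                break
        else:
            raise ValueError(
                "could not find a finite starting state: "
                + _diagnose_nonfinite(vals, pH0, variant, engine, free_names)
            )

    # ---- adaptive MH bookkeeping -------------------------------------------
    log_scales = {nm: math.log(_INIT_SCALES[nm]) for nm in free_names}
    accept_post = {nm: 0 for nm in free_names}
    cur_prior = {nm: _prior_logpdf(nm, vals[nm], variant) for nm in free_names}

    n_free = len(free_names)
    n_params = n_free + (nb if sample_pH0 else 0)
    draws = np.empty((n_keep, n_params))
    deviance = np.empty(n_keep)
    scales_at_burn_end: dict[str, float] = {}
    keep_row = 0

    for it in range(1, burn + total_iters + 1):
        adapting = it <= burn
        gamma = it ** -0.6 if adapting else 0.0

        for nm in free_names:
            cur = vals[nm]
            step = math.exp(log_scales[nm]) * rng.standard_normal()
            if nm in _LOG_SCALE_PARAMS:
                prop = cur * math.exp(step)
                log_jac = math.log(prop / cur)
            else:
                prop = cur + step
                log_jac = 0.0

            prop_prior = _prior_logpdf(nm, prop, variant)
            accepted = False
            if prop_prior > -math.inf:
                if nm in _HIER_PARAMS:
                    mu = prop if nm == "mu_pH0" else vals["mu_pH0"]
                    s0 = prop if nm == "sigma_pH0" else vals["sigma_pH0"]
                    prop_hier = _hier_logpdf(pH0, mu, s0)
                    prop_ll = ll
                else:
                    vals_prop = dict(vals)
                    vals_prop[nm] = prop
                    prop_hier = hier
                    prop_ll = engine.loglik(vals_prop, pH0)
                logr = (prop_prior + prop_hier + prop_ll
                        - cur_prior[nm] - hier - ll + log_jac)
                if logr >= 0 or rng.random() < math.exp(logr):
                    vals[nm] = prop
                    cur_prior[nm] = prop_prior
                    hier = prop_hier
                    ll = prop_ll
                    accepted = True
            if adapting:
                log_scales[nm] += gamma * ((1.0 if accepted else 0.0) - TARGET_ACCEPTANCE)
            elif accepted:
                accept_post[nm] += 1

        if sample_pH0 and nb:
            # Exact conjugate draw: z_i = y_i + beta_i * min(t_i, theta) has
            # mean pH0_{r(i)}, so each batch's full conditional is normal.
            s0, sig, mu = vals["sigma_pH0"], vals["sigma_pH"], vals["mu_pH0"]
            if engine.n:
                beta = engine.betas(vals)
                c = beta * engine.effective_time(vals["theta"])
                z = engine.y + c
                sums = np.bincount(engine.bidx, weights=z, minlength=nb)
                prec = 1.0 / s0 ** 2 + engine.batch_counts / sig ** 2
                mean = (mu / s0 ** 2 + sums / sig ** 2) / prec
                pH0 = mean + rng.standard_normal(nb) / np.sqrt(prec)
                resid = engine.y - (pH0[engine.bidx] - c)
                zz = resid / sig
                ll = (-0.5 * float(np.dot(zz, zz))
                      - engine.n * (math.log(sig) + 0.5 * LOG_2PI))
            else:
                pH0 = mu + s0 * rng.standard_normal(nb)
            hier = _hier_logpdf(pH0, mu, s0)

        if adapting and it == burn:
            scales_at_burn_end = {nm: math.exp(s) for nm, s in log_scales.items()}
        if it > burn and (it - burn) % thin == 0:
            row = [vals[nm] for nm in free_names]
            if sample_pH0:
                draws[keep_row, :n_free] = row
                draws[keep_row, n_free:] = pH0
            else:
                draws[keep_row, :] = row
            deviance[keep_row] = -2.0 * ll
            keep_row += 1

    if not scales_at_burn_end:  # burn_in == 0
        scales_at_burn_end = {nm: math.exp(s) for nm, s in log_scales.items()}
    final_scales = {nm: math.exp(s) for nm, s in log_scales.items()}
    accept_rates = {nm: accept_post[nm] / total_iters for nm in free_names}
    return draws, deviance, accept_rates, scales_at_burn_end, final_scales


def _diagnose_nonfinite(vals, pH0, variant, engine, free_names) -> str:
    """Name the component responsible for a non-finite starting log posterior."""
    for nm in free_names:
        if not math.isfinite(_prior_logpdf(nm, vals[nm], variant)):
            return f"prior of parameter '{nm}' is -inf at {vals[nm]!r}"
    if not math.isfinite(_hier_logpdf(pH0, vals["mu_pH0"], vals["sigma_pH0"])):
        return "hierarchical pH0 term is non-finite (check mu_pH0/sigma_pH0/pH0)"
    if not math.isfinite(engine.loglik(vals, pH0)):
        if vals["n"] <= 0 and engine.has_zero_lactate:
            return "likelihood is -inf: parameter 'n' <= 0 with zero-lactate observations"
        return "likelihood is non-finite (check sigma_pH, lambda, deltas, n, theta)"
    return "unknown component"


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def run_mcmc(dataset: Dataset, variant: ModelVariant, config: MCMCConfig,
             fixed: Mapping | None = None) -> Trace:
    """Fit a model variant to a dataset; returns the multi-chain Trace.

    Chains run sequentially with independent reproducible streams spawned
    from ``config.seed``.  ``fixed`` optionally pins top-level parameters
    (name -> value) and/or the latent vector (``"pH0"`` -> mapping of batch
    id to value); pinned quantities are excluded from updates and from the
    trace.  With an empty dataset the sampler targets the prior.
    """
    if not isinstance(dataset, Dataset):
        raise TypeError("dataset must be a Dataset")
    fixed = dict(fixed or {})
    engine = _LikelihoodEngine(dataset)

    free_names = tuple(nm for nm in variant.free_parameters if nm not in fixed)
    for nm in fixed:
        if nm != "pH0" and nm not in variant.free_parameters:
            raise ValueError(f"cannot fix unknown or already-fixed parameter {nm!r}")

    fixed_vals = {k: float(v) for k, v in fixed.items() if k != "pH0"}
    sample_pH0 = "pH0" not in fixed
    fixed_pH0 = None
    if not sample_pH0:
        given = fixed["pH0"]
        fixed_pH0 = np.array([float(given[b]) for b in dataset.batch_ids])

    param_names = list(free_names)
    if sample_pH0:
        param_names += [f"pH0[{b}]" for b in dataset.batch_ids]

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_chains)

    all_draws = np.empty((config.n_chains, config.retained_per_chain, len(param_names)))
    all_dev = np.empty((config.n_chains, config.retained_per_chain))
    acceptance: dict[str, list[float]] = {nm: [] for nm in free_names}
    scales_burn: list[dict[str, float]] = []
    scales_final: list[dict[str, float]] = []

    inits: Sequence[Mapping | None]
    if config.initial_values == "auto":
        inits = [None] * config.n_chains
    else:
        inits = list(config.initial_values)

    for c in range(config.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        draws, dev, acc, sc_burn, sc_final = _run_chain(
            engine, variant, config, rng, free_names, inits[c], fixed_vals,
            sample_pH0, fixed_pH0,
        )
        all_draws[c] = draws
        all_dev[c] = dev
        for nm in free_names:
            acceptance[nm].append(acc[nm])
        scales_burn.append(sc_burn)
        scales_final.append(sc_final)

    return Trace(
        draws=all_draws,
        param_names=tuple(param_names),
        deviance=all_dev,
        variant=variant,
        config=config,
        n_obs=dataset.n_obs,
        batch_ids=dataset.batch_ids,
        acceptance={nm: np.array(v) for nm, v in acceptance.items()},
        proposal_scales={"end_of_burn_in": scales_burn, "final": scales_final},
        fixed_values=fixed_vals,
        fixed_pH0=(None if sample_pH0
                   else {b: float(fixed["pH0"][b]) for b in dataset.batch_ids}),
    )
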