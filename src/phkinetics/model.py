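"""Core model for two-phase pH acidification kinetics in fresh meat products.

The pH of a fresh meat product (the motivating case study is industrially
produced fresh turkey sausage) drops linearly during storage as lactic acid
bacteria ferment, then plateaus once the matrix's buffering capacity is
reached.  The mean trajectory for a product from batch ``r`` under process
condition ``k`` (a lactate dose combined with a packaging atmosphere) is

    m(t) = pH0_r - beta_k * min(t, theta)

where ``theta`` (days) is the stabilisation time shared across conditions and
``beta_k`` (pH units/day) is the condition-specific acidification rate,
modelled on the log scale as

    ln(beta_k) = lambda * Lactate^n + delta_p

with ``Lactate`` the potassium-lactate dose (% w/w), ``delta_p`` an additive
offset for the packaging atmosphere p in {Air, MAP1, MAP2} and ``n`` a scale
exponent (``n = 1`` gives a plain log-linear dose effect).

The stochastic layers are a batch-level random initial pH,
``pH0_r ~ N(mu_pH0, sigma_pH0)``, and Gaussian measurement noise,
``Y ~ N(m(t), sigma_pH)``.  All spread parameters are standard deviations
throughout this package (never variances or precisions).

This module houses the parameter containers, the prior specification of the
four model variants M1-M4 (exponent and/or breakpoint fixed vs. estimated)
and the deterministic/probabilistic kernels every other module builds on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synth import Dataset

LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "Atmosphere",
    "ATMOSPHERES",
    "Condition",
    "Observation",
    "PriorSpec",
    "ModelVariant",
    "model_variant",
    "VARIANT_NAMES",
    "ParameterState",
    "reference_estimates",
    "acidification_rate",
    "lactate_power",
    "mean_pH",
    "log_likelihood",
    "log_prior",
    "normal_logpdf",
    "half_normal_logpdf",
    "uniform_logpdf",
]


class Atmosphere(str, enum.Enum):
    """Packaging atmosphere: air, 70%O2-30%CO2 (MAP1) or 50%CO2-50%N2 (MAP2)."""

    AIR = "Air"
    MAP1 = "MAP1"
    MAP2 = "MAP2"

    @classmethod
    def parse(cls, token: str) -> "Atmosphere":
        """Case-insensitive lookup; raises ValueError for unknown tokens."""
        if isinstance(token, Atmosphere):
            return token
        key = str(token).strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        raise ValueError(
            f"unknown atmosphere {token!r}; expected one of "
            + ", ".join(m.value for m in cls)
        )


ATMOSPHERES: tuple[Atmosphere, ...] = (Atmosphere.AIR, Atmosphere.MAP1, Atmosphere.MAP2)


@dataclass(frozen=True)
class Condition:
    """A process condition: lactate dose (% w/w) under a packaging atmosphere."""

    lactate: float
    atmosphere: Atmosphere

    def __post_init__(self) -> None:
        object.__setattr__(self, "atmosphere", Atmosphere.parse(self.atmosphere))
        lac = float(self.lactate)
        if not math.isfinite(lac) or lac < 0:
            raise ValueError(f"lactate dose must be finite and >= 0, got {self.lactate}")
        object.__setattr__(self, "lactate", lac)


@dataclass(frozen=True)
class Observation:
    """One pH measurement: batch, condition, storage day and value."""

    batch_id: str
    condition: Condition
    day: float
    pH: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.day) or self.day < 0:
            raise ValueError(f"storage day must be finite and >= 0, got {self.day}")
        if not math.isfinite(self.pH):
            raise ValueError(f"pH must be finite, got {self.pH}")


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters for all top-level parameters.

    Defaults encode the study priors: an informative normal on the mean
    initial pH elicited from earlier poultry-sausage surveys, weak
    half-normals on both standard deviations, and wide uniforms on the
    kinetic effects.  The breakpoint prior U(8, 22) brackets the producers'
    15-day use-by date by +/- 7 days.
    """

    mu_pH0_mean: float = 5.84
    mu_pH0_sd: float = 0.11
    sigma_pH0_scale: float = 0.1
    sigma_pH_scale: float = 0.1
    delta_bounds: tuple[float, float] = (-10.0, 10.0)
    lambda_bounds: tuple[float, float] = (-1.0, 1.0)
    n_bounds: tuple[float, float] = (-3.0, 3.0)
    theta_bounds: tuple[float, float] = (8.0, 22.0)

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name.startswith("delta"):
            return self.delta_bounds
        if name == "lambda":
            return self.lambda_bounds
        if name == "n":
            return self.n_bounds
        if name == "theta":
            return self.theta_bounds
        raise KeyError(name)


VARIANT_NAMES = ("M1", "M2", "M3", "M4")

# (n fixed at 1?, theta fixed at 15 days?)
_VARIANT_FLAGS = {
    "M1": (True, True),
    "M2": (False, True),
    "M3": (True, False),
    "M4": (False, False),
}

FIXED_N = 1.0
FIXED_THETA = 15.0


@dataclass(frozen=True)
class ModelVariant:
    """One of the four variants: exponent n and/or breakpoint theta fixed or free.

    M1 fixes both (n=1, theta=15 days), M2 fixes theta only, M3 fixes n only,
    M4 estimates both.  The free-parameter counts are 7/8/8/9.
    """

    name: str
    n_fixed: float | None
    theta_fixed: float | None
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"variant name must be one of {VARIANT_NAMES}, got {self.name!r}")
        nf, tf = _VARIANT_FLAGS[self.name]
        if nf != (self.n_fixed is not None) or tf != (self.theta_fixed is not None):
            raise ValueError(
                f"variant {self.name} requires n_fixed={'set' if nf else 'None'}, "
                f"theta_fixed={'set' if tf else 'None'}"
            )

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Free top-level parameter names in canonical order."""
        names = ["mu_pH0", "sigma_pH0", "sigma_pH", "lambda",
                 "delta_Air", "delta_MAP1", "delta_MAP2"]
        if self.n_fixed is None:
            names.append("n")
        if self.theta_fixed is None:
            names.append("theta")
        return tuple(names)

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameters)


def model_variant(name: str, priors: PriorSpec | None = None) -> ModelVariant:
    """Build M1/M2/M3/M4 with the default (or supplied) prior specification."""
    nf, tf = _VARIANT_FLAGS[name] if name in _VARIANT_FLAGS else (None, None)
    if name not in _VARIANT_FLAGS:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    return ModelVariant(
        name=name,
        n_fixed=FIXED_N if nf else None,
        theta_fixed=FIXED_THETA if tf else None,
        priors=priors or PriorSpec(),
    )


@dataclass
class ParameterState:
    """One complete setting of all model parameters.

    ``lam`` is the lactate slope (the field's lambda; renamed because of the
    Python keyword).  ``pH0_by_batch`` holds the latent batch-level initial
    pH values keyed by batch id; it may be None for states that only describe
    the kinetic layer.
    """

    mu_pH0: float
    sigma_pH0: float
    sigma_pH: float
    lam: float
    delta_Air: float
    delta_MAP1: float
    delta_MAP2: float
    n: float = 1.0
    theta: float = 15.0
    pH0_by_batch: dict[str, float] | None = None

    def delta_for(self, atmosphere: Atmosphere) -> float:
        atmosphere = Atmosphere.parse(atmosphere)
        return {
            Atmosphere.AIR: self.delta_Air,
            Atmosphere.MAP1: self.delta_MAP1,
            Atmosphere.MAP2: self.delta_MAP2,
        }[atmosphere]

    @property
    def deltas(self) -> np.ndarray:
        """Atmosphere offsets ordered as ATMOSPHERES (Air, MAP1, MAP2)."""
        return np.array([self.delta_Air, self.delta_MAP1, self.delta_MAP2])

    def with_pH0(self, pH0_by_batch: Mapping[str, float]) -> "ParameterState":
        return replace(self, pH0_by_batch=dict(pH0_by_batch))

    def get(self, name: str) -> float:
        return getattr(self, "lam" if name == "lambda" else name)


def reference_estimates() -> ParameterState:
    """Posterior point estimates from the fresh turkey-sausage case study.

    These are the medians obtained by fitting variant M3 (n fixed at 1,
    breakpoint estimated) to the ten-batch industrial monitoring data; they
    double as the default generating truth of the synthetic-data module.
    """
    return ParameterState(
        mu_pH0=6.49,
        sigma_pH0=0.10,
        sigma_pH=0.15,
        lam=-0.095,
        delta_Air=-2.430,
        delta_MAP1=-2.487,
        delta_MAP2=-2.339,
        n=1.0,
        theta=12.9,
    )


# ---------------------------------------------------------------------------
# Deterministic kernels
# ---------------------------------------------------------------------------

def lactate_power(lactate, n: float):
    """Lactate^n with the convention 0^n := 0 for n > 0.

    For lactate = 0 and n <= 0 the power is undefined; NaN is returned so the
    resulting rate is non-finite and the state is rejected upstream.
    Accepts scalars or arrays.
    """
    lac = np.asarray(lactate, dtype=float)
    if np.any(lac < 0):
        raise ValueError("lactate must be >= 0")
    if n == 1.0:
        out = lac
    else:
        with np.errstate(divide="ignore"):
            out = np.where(lac > 0, np.power(np.where(lac > 0, lac, 1.0), n), 0.0)
        if n <= 0:
            out = np.where(lac == 0, np.nan, out)
    return out if out.ndim else float(out)


def acidification_rate(lam: float, n: float, delta_p: float, lactate) -> float | np.ndarray:
    """Acidification rate beta = exp(lambda * lactate^n + delta_p), pH units/day.

    Strictly positive whenever finite; NaN signals an undefined zero-lactate
    power (n <= 0), which callers treat as an invalid state.
    """
    lp = lactate_power(lactate, n)
    out = np.exp(lam * np.asarray(lp) + delta_p)
    return out if np.ndim(out) else float(out)


def mean_pH(state: ParameterState, condition: Condition, batch_pH0: float, day) -> float | np.ndarray:
    """Expected pH: pH0 - beta*day before the breakpoint, flat afterwards.

    Continuous in ``day`` at the breakpoint ``theta`` and non-increasing.
    A non-finite rate propagates as NaN (invalid-state signal).
    """
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < 0):
        raise ValueError("day must be >= 0")
    beta = acidification_rate(state.lam, state.n, state.delta_for(condition.atmosphere),
                              condition.lactate)
    out = batch_pH0 - beta * np.minimum(day_arr, state.theta)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Log-densities (hand-coded for sampler speed; sd parameterisation throughout)
# ---------------------------------------------------------------------------

def normal_logpdf(x, mean: float, sd: float):
    if sd <= 0:
        raise ValueError("sd must be > 0")
    z = (np.asarray(x, dtype=float) - mean) / sd
    out = -0.5 * z * z - math.log(sd) - 0.5 * LOG_2PI
    return out if np.ndim(out) else float(out)


def half_normal_logpdf(x: float, scale: float) -> float:
    """log density of |N(0, scale)|: 2*phi(x/scale)/scale on x >= 0, else -inf."""
    if x < 0:
        return -math.inf
    return math.log(2.0) + normal_logpdf(x, 0.0, scale)


def uniform_logpdf(x: float, lo: float, hi: float) -> float:
    if lo <= x <= hi:
        return -math.log(hi - lo)
    return -math.inf


# ---------------------------------------------------------------------------
# Likelihood and prior
# ---------------------------------------------------------------------------

def _gaussian_loglik_sum(resid: np.ndarray, sd: float) -> float:
    """Sum of N(0, sd) log densities of the residual vector."""
    n = resid.size
    if sd <= 0:
        return math.inf if not np.any(resid != 0) else -math.inf
    z = resid / sd
    val = -0.5 * float(np.dot(z, z)) - n * (math.log(sd) + 0.5 * LOG_2PI)
    return val if math.isfinite(val) else -math.inf


def log_likelihood(dataset: "Dataset", state: ParameterState) -> float:
    """Observation-model log likelihood: sum of Gaussian log densities.

    Each observation contributes log N(pH; m(t), sigma_pH) with the mean from
    the two-phase kinetic model and the batch's latent initial pH.  The
    hierarchical pH0 layer is *not* part of the likelihood (it belongs to
    :func:`log_prior`); this split fixes the deviance used for DIC.

    Returns -inf for states with non-finite means.  Raises KeyError for
    observations whose batch has no latent pH0 entry.
    """
    if dataset.n_obs == 0:
        return 0.0
    pH0_map = state.pH0_by_batch
    if pH0_map is None:
        raise KeyError("state.pH0_by_batch is required to evaluate the likelihood")
    pH0 = np.array([pH0_map[b] for b in dataset.batch_ids])
    lp = lactate_power(dataset.lactate, state.n)
    beta = np.exp(state.lam * lp + state.deltas[dataset.atm_idx])
    m = pH0[dataset.batch_idx] - beta * np.minimum(dataset.day, state.theta)
    if not np.all(np.isfinite(m)):
        return -math.inf
    return _gaussian_loglik_sum(dataset.pH - m, state.sigma_pH)


def log_prior(state: ParameterState, variant: ModelVariant) -> float:
    """Joint log prior of the free top-level parameters plus the hierarchical term.

    The hierarchical term sums log N(pH0_r; mu_pH0, sigma_pH0) over batches
    (zero when the state carries no latent values).  Fixed parameters of the
    variant contribute nothing but must match the state's values.
    """
    pri = variant.priors
    if variant.n_fixed is not None and state.n != variant.n_fixed:
        raise ValueError(f"{variant.name} fixes n={variant.n_fixed} but state.n={state.n}")
    if variant.theta_fixed is not None and state.theta != variant.theta_fixed:
        raise ValueError(
            f"{variant.name} fixes theta={variant.theta_fixed} but state.theta={state.theta}"
        )

    total = normal_logpdf(state.mu_pH0, pri.mu_pH0_mean, pri.mu_pH0_sd)
    total += half_normal_logpdf(state.sigma_pH0, pri.sigma_pH0_scale)
    total += half_normal_logpdf(state.sigma_pH, pri.sigma_pH_scale)
    total += uniform_logpdf(state.lam, *pri.lambda_bounds)
    for d in (state.delta_Air, state.delta_MAP1, state.delta_MAP2):
        total += uniform_logpdf(d, *pri.delta_bounds)
    if variant.n_fixed is None:
        total += uniform_logpdf(state.n, *pri.n_bounds)
    if variant.theta_fixed is None:
        total += uniform_logpdf(state.theta, *pri.theta_bounds)

    if state.pH0_by_batch:
        if state.sigma_pH0 <= 0:
            return -math.inf
        vals = np.fromiter(state.pH0_by_batch.values(), dtype=float)
        total += float(np.sum(normal_logpdf(vals, state.mu_pH0, state.sigma_pH0)))
    return total if math.isfinite(total) else -math.inf
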