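"""Deterministic and probabilistic kernels of the two-phase acidification model."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from phkinetics import (
    Condition,
    Dataset,
    ParameterState,
    acidification_rate,
    log_likelihood,
    log_prior,
    mean_pH,
    model_variant,
    reference_estimates,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# acidification_rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "lam, n, delta, lactate, expected, tol",
    [
        # zero lactate under the CO2-rich atmosphere: fastest acidification
        (-0.095, 1.0, -2.339, 0.0, 0.0964, 5e-4),
        # full lactate dose under 70%O2-30%CO2: slowest
        (-0.095, 1.0, -2.487, 2.0, 0.0688, 5e-4),
        (0.0, 1.0, 0.0, 5.0, 1.0, 0.0),
    ],
)
def test_rate_values(lam, n, delta, lactate, expected, tol):
    assert acidification_rate(lam, n, delta, lactate) == pytest.approx(expected, abs=tol)


def test_rate_rejects_negative_lactate():
    with pytest.raises(ValueError):
        acidification_rate(-0.095, 1.0, -2.4, -0.5)


def test_zero_lactate_power_convention():
    """0^n := 0 for n > 0; undefined (non-finite) for n <= 0."""
    assert acidification_rate(-0.095, 0.5, -2.4, 0.0) == pytest.approx(math.exp(-2.4))
    assert not np.isfinite(acidification_rate(-0.095, -1.0, -2.4, 0.0))
    assert not np.isfinite(acidification_rate(-0.095, 0.0, -2.4, 0.0))


@given(
    lam=st.floats(-1.0, -0.01),
    n=st.floats(0.1, 3.0),
    delta=st.floats(-5.0, 0.0),
    lac1=st.floats(0.0, 3.0),
    lac2=st.floats(0.0, 3.0),
)
def test_rate_monotone_decreasing_in_lactate(lam, n, delta, lac1, lac2):
    """Negative lambda with positive exponent: more lactate, slower acidification."""
    lo, hi = sorted((lac1, lac2))
    assert acidification_rate(lam, n, delta, hi) <= acidification_rate(lam, n, delta, lo)


# ---------------------------------------------------------------------------
# mean_pH
# ---------------------------------------------------------------------------

def test_mean_pH_worked_stabilisation_example():
    """Plug-in of the reference estimates reproduces the day-15 value 5.55."""
    est = reference_estimates()
    value = mean_pH(est, Condition(2.0, "Air"), batch_pH0=6.49, day=15.0)
    assert value == pytest.approx(5.55, abs=0.005)
    # identical to the explicit stabilised-phase identity pH0 - beta*theta
    beta = acidification_rate(est.lam, est.n, est.delta_Air, 2.0)
    assert value == pytest.approx(6.49 - beta * est.theta, abs=1e-12)


state_strategy = st.builds(
    ParameterState,
    mu_pH0=st.just(6.5),
    sigma_pH0=st.just(0.1),
    sigma_pH=st.just(0.15),
    lam=st.floats(-1.0, 1.0),
    delta_Air=st.floats(-4.0, 0.0),
    delta_MAP1=st.floats(-4.0, 0.0),
    delta_MAP2=st.floats(-4.0, 0.0),
    n=st.floats(0.1, 3.0),
    theta=st.floats(8.0, 22.0),
)


@given(state=state_strategy, lactate=st.floats(0.0, 2.0),
       atm=st.sampled_from(["Air", "MAP1", "MAP2"]))
def test_mean_pH_breakpoint_continuity_and_plateau(state, lactate, atm):
    cond = Condition(lactate, atm)
    th = state.theta
    at_theta = mean_pH(state, cond, 6.5, th)
    for later in (th + 1.0, th + 10.0):
        assert mean_pH(state, cond, 6.5, later) == pytest.approx(at_theta, abs=1e-12)
    # acidification-branch formula evaluated at theta agrees with the plateau
    beta = acidification_rate(state.lam, state.n, state.delta_for(cond.atmosphere), lactate)
    assert 6.5 - beta * th == pytest.approx(at_theta, abs=1e-12)


@given(state=state_strategy, lactate=st.floats(0.0, 2.0),
       d1=st.floats(0.0, 25.0), d2=st.floats(0.0, 25.0))
def test_mean_pH_non_increasing(state, lactate, d1, d2):
    cond = Condition(lactate, "Air")
    lo, hi = sorted((d1, d2))
    assert mean_pH(state, cond, 6.5, hi) <= mean_pH(state, cond, 6.5, lo) + 1e-12


def test_mean_pH_day_zero_is_initial_pH(truth):
    assert mean_pH(truth, Condition(1.0, "MAP2"), 6.321, 0.0) == pytest.approx(6.321)


def test_mean_pH_rejects_negative_day(truth):
    with pytest.raises(ValueError):
        mean_pH(truth, Condition(1.0, "Air"), 6.5, -1.0)


# ---------------------------------------------------------------------------
# log_likelihood against a scipy per-term oracle
# ---------------------------------------------------------------------------

def _oracle_loglik(dataset, state):
    total = 0.0
    for obs in dataset.observations:
        m = mean_pH(state, obs.condition, state.pH0_by_batch[obs.batch_id], obs.day)
        total += scipy.stats.norm.logpdf(obs.pH, loc=m, scale=state.sigma_pH)
    return total


def test_loglik_single_centred_observation():
    """A single observation at its mean with unit sd scores -0.5*ln(2*pi)."""
    from phkinetics import Observation

    state = ParameterState(6.5, 0.1, 1.0, -0.1, -2.4, -2.5, -2.3, 1.0, 13.0,
                           pH0_by_batch={"B": 6.5})
    m = mean_pH(state, Condition(1.0, "Air"), 6.5, 8.0)
    ds = Dataset.from_observations([Observation("B", Condition(1.0, "Air"), 8.0, m)])
    assert log_likelihood(ds, state) == pytest.approx(-0.5 * math.log(2 * math.pi))


def test_loglik_additive_and_matches_oracle(truth):
    from phkinetics import StudyDesign, generate_dataset

    small_design = StudyDesign(n_batches=2, lactate_doses=(0.0, 2.0),
                               atmospheres=("Air", "MAP2"), sampling_days=(2.0, 15.0))
    ds = generate_dataset(small_design, truth, seed=3)
    sub = ds.frame.iloc[:5]
    small = Dataset(sub)
    state = truth.with_pH0(ds.truth_pH0)
    ours = log_likelihood(small, state)
    assert ours == pytest.approx(_oracle_loglik(small, state), abs=1e-10)
    # additivity over two disjoint halves
    a = Dataset(sub.iloc[:2])
    b = Dataset(sub.iloc[2:])
    assert log_likelihood(a, state) + log_likelihood(b, state) == pytest.approx(ours, abs=1e-10)


def test_loglik_unknown_batch_errors(truth, tiny_dataset):
    state = truth.with_pH0({"NOT_A_BATCH": 6.5})
    with pytest.raises(KeyError):
        log_likelihood(tiny_dataset, state)


def test_loglik_zero_sigma(truth, tiny_dataset):
    state = truth.with_pH0(tiny_dataset.truth_pH0)
    state.sigma_pH = 0.0
    assert log_likelihood(tiny_dataset, state) == -math.inf


# ---------------------------------------------------------------------------
# log_prior against a scipy per-term oracle
# ---------------------------------------------------------------------------

def _oracle_logprior(state, variant):
    pri = variant.priors
    total = scipy.stats.norm.logpdf(state.mu_pH0, pri.mu_pH0_mean, pri.mu_pH0_sd)
    total += scipy.stats.halfnorm.logpdf(state.sigma_pH0, scale=pri.sigma_pH0_scale)
    total += scipy.stats.halfnorm.logpdf(state.sigma_pH, scale=pri.sigma_pH_scale)
    lo, hi = pri.lambda_bounds
    total += scipy.stats.uniform.logpdf(state.lam, lo, hi - lo)
    lo, hi = pri.delta_bounds
    for d in (state.delta_Air, state.delta_MAP1, state.delta_MAP2):
        total += scipy.stats.uniform.logpdf(d, lo, hi - lo)
    if variant.n_fixed is None:
        lo, hi = pri.n_bounds
        total += scipy.stats.uniform.logpdf(state.n, lo, hi - lo)
    if variant.theta_fixed is None:
        lo, hi = pri.theta_bounds
        total += scipy.stats.uniform.logpdf(state.theta, lo, hi - lo)
    if state.pH0_by_batch:
        for v in state.pH0_by_batch.values():
            total += scipy.stats.norm.logpdf(v, state.mu_pH0, state.sigma_pH0)
    return float(total)


def test_logprior_matches_oracle_fully_specified(truth):
    state = truth.with_pH0({"B01": 6.4, "B02": 6.55, "B03": 6.47})
    for name in ("M3", "M4"):
        variant = model_variant(name)
        if name == "M4":
            state2 = state
            state2.n = 1.2
            state2.theta = 12.9
            assert log_prior(state2, variant) == pytest.approx(
                _oracle_logprior(state2, variant), abs=1e-10)
        else:
            assert log_prior(state, variant) == pytest.approx(
                _oracle_logprior(state, variant), abs=1e-10)


def test_logprior_support_boundaries(truth):
    out_of_support = reference_estimates()
    out_of_support.theta = 25.0  # outside the U(8, 22) breakpoint prior
    assert log_prior(out_of_support, model_variant("M3")) == -math.inf

    neg_sd = reference_estimates()
    neg_sd.sigma_pH0 = -0.01
    assert log_prior(neg_sd, model_variant("M3")) == -math.inf


def test_logprior_rejects_fixed_parameter_mismatch(truth):
    state = reference_estimates()
    state.n = 2.0  # M3 fixes n = 1
    with pytest.raises(ValueError):
        log_prior(state, model_variant("M3"))


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name, n_free", [("M1", 7), ("M2", 8), ("M3", 8), ("M4", 9)])
def test_variant_free_parameter_counts(name, n_free):
    v = model_variant(name)
    assert v.n_free_parameters == n_free
    assert ("n" in v.free_parameters) == (name in ("M2", "M4"))
    assert ("theta" in v.free_parameters) == (name in ("M3", "M4"))


def test_default_priors_match_study_specification():
    pri = model_variant("M1").priors
    assert (pri.mu_pH0_mean, pri.mu_pH0_sd) == (5.84, 0.11)
    assert pri.sigma_pH0_scale == pri.sigma_pH_scale == 0.1
    assert pri.delta_bounds == (-10.0, 10.0)
    assert pri.lambda_bounds == (-1.0, 1.0)
    assert pri.n_bounds == (-3.0, 3.0)
    assert pri.theta_bounds == (8.0, 22.0)


def test_condition_validation():
    with pytest.raises(ValueError):
        Condition(-1.0, "Air")
    with pytest.raises(ValueError):
        Condition(1.0, "CO2")
    assert Condition(1.0, "map2").atmosphere.value == "MAP2"
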