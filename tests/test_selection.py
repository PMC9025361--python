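"""DIC computation, model choice, posterior summaries and goodness of fit."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from phkinetics import (
    DICResult,
    MCMCConfig,
    StudyDesign,
    compute_dic,
    generate_dataset,
    goodness_of_fit,
    model_variant,
    reference_estimates,
    run_mcmc,
    select_model,
    summarize_posterior,
)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def test_dic_identity_holds(short_fit, dataset360):
    r = compute_dic(short_fit, dataset360)
    assert r.dic == pytest.approx(2 * r.mean_deviance - r.plugin_deviance, abs=1e-9)
    assert r.p_d > 0  # a fitted hierarchical model uses effective parameters


def test_degenerate_trace_has_zero_pd(trace_factory, tiny_dataset, truth):
    """Every draw identical: pD = 0 and DIC = plug-in deviance."""
    from phkinetics import log_likelihood

    state = truth.with_pH0(tiny_dataset.truth_pH0)
    dev = -2 * log_likelihood(tiny_dataset, state)
    names = ["mu_pH0", "sigma_pH0", "sigma_pH", "lambda",
             "delta_Air", "delta_MAP1", "delta_MAP2", "theta"]
    draws = {nm: np.full((1, 50), state.get(nm)) for nm in names}
    for b in tiny_dataset.batch_ids:
        draws[f"pH0[{b}]"] = np.full((1, 50), tiny_dataset.truth_pH0[b])
    tr = trace_factory(draws, deviance=np.full((1, 50), dev),
                       n_obs=tiny_dataset.n_obs, batch_ids=tiny_dataset.batch_ids)
    r = compute_dic(tr, tiny_dataset)
    assert r.p_d == pytest.approx(0.0, abs=1e-9)
    assert r.dic == pytest.approx(dev, abs=1e-9)


def test_dic_matches_quadrature_oracle_on_conjugate_toy(truth):
    """Single batch, all kinetics pinned: DIC agrees with numeric integration.

    With only the latent initial pH free, its posterior is conjugate normal;
    the posterior-expected deviance is computed by an independent quadrature
    oracle and must agree within 1%.
    """
    design = StudyDesign(n_batches=1, lactate_doses=(2.0,), atmospheres=("Air",))
    gen_truth = dataclasses.replace(truth, sigma_pH=0.05)
    ds = generate_dataset(design, gen_truth, seed=33)
    batch = ds.batch_ids[0]

    fixed = {nm: gen_truth.get(nm) for nm in
             ("mu_pH0", "sigma_pH0", "sigma_pH", "lambda",
              "delta_Air", "delta_MAP1", "delta_MAP2", "theta")}
    cfg = MCMCConfig(n_chains=2, burn_in=500, n_iterations=15000, thinning=1, seed=3)
    tr = run_mcmc(ds, model_variant("M3"), cfg, fixed=fixed)
    assert tr.param_names == (f"pH0[{batch}]",)
    result = compute_dic(tr, ds)

    # independent oracle: conjugate posterior for pH0, quadrature for E[D]
    from phkinetics import acidification_rate

    beta = acidification_rate(gen_truth.lam, gen_truth.n, gen_truth.delta_Air, 2.0)
    c = beta * np.minimum(ds.day, gen_truth.theta)
    z = ds.pH + c  # z_i ~ N(pH0, sigma_pH)
    sig, s0, mu0 = gen_truth.sigma_pH, gen_truth.sigma_pH0, gen_truth.mu_pH0
    prec = 1 / s0 ** 2 + len(z) / sig ** 2
    post_mean = (mu0 / s0 ** 2 + z.sum() / sig ** 2) / prec
    post_sd = prec ** -0.5

    def deviance(x):
        return -2 * np.sum(scipy.stats.norm.logpdf(z, loc=x, scale=sig))

    dbar, _ = scipy.integrate.quad(
        lambda x: deviance(x) * scipy.stats.norm.pdf(x, post_mean, post_sd),
        post_mean - 10 * post_sd, post_mean + 10 * post_sd,
    )
    dic_oracle = 2 * dbar - deviance(post_mean)
    assert result.dic == pytest.approx(dic_oracle, rel=0.01)


def test_dic_rejects_mismatched_dataset(short_fit, tiny_dataset):
    with pytest.raises(ValueError, match="observations"):
        compute_dic(short_fit, tiny_dataset)


# ---------------------------------------------------------------------------
# select_model
# ---------------------------------------------------------------------------

def _dic_result(name, dic, n_free):
    # plugin = mean ensures DIC == mean_deviance for easy construction
    return DICResult(variant_name=name, mean_deviance=dic,
                     plugin_deviance=dic, n_free_parameters=n_free)


def test_select_model_prefers_lowest_dic():
    """The study's own DIC table: the n-fixed, free-breakpoint variant wins."""
    results = [
        _dic_result("M1", -274.8, 7),
        _dic_result("M2", -271.0, 8),
        _dic_result("M3", -296.5, 8),
        _dic_result("M4", -294.1, 9),
    ]
    assert select_model(results) == "M3"


def test_select_model_tie_breaks_by_parsimony_and_handles_singleton():
    assert select_model([_dic_result("M4", -100.0, 9), _dic_result("M3", -100.0, 8)]) == "M3"
    assert select_model([_dic_result("M2", -5.0, 8)]) == "M2"
    with pytest.raises(ValueError):
        select_model([])


# ---------------------------------------------------------------------------
# summarize_posterior
# ---------------------------------------------------------------------------

def test_summary_median_and_interval_examples(trace_factory):
    seq = np.arange(1.0, 1001.0).reshape(2, 500)
    const = np.full((2, 500), 4.2)
    tr = trace_factory({"a": seq, "b": const})
    s = summarize_posterior(tr)
    assert s.median("a") == pytest.approx(500.5)
    assert s.median("b") == 4.2
    assert s.interval("b") == (4.2, 4.2)
    lo, med, hi = s.table.loc["a", ["ci_lower", "median", "ci_upper"]]
    assert lo <= med <= hi


def test_summary_quantiles_match_interpolation_oracle(trace_factory):
    rng = np.random.default_rng(8)
    draws = rng.normal(size=(3, 400))
    tr = trace_factory({"p": draws})
    s = summarize_posterior(tr)
    pooled = np.sort(draws.reshape(-1))

    def oracle_quantile(q):
        # linear interpolation between order statistics
        h = (pooled.size - 1) * q
        lo = int(np.floor(h))
        return pooled[lo] + (h - lo) * (pooled[min(lo + 1, pooled.size - 1)] - pooled[lo])

    assert s.median("p") == pytest.approx(oracle_quantile(0.5), abs=1e-12)
    assert s.interval("p")[0] == pytest.approx(oracle_quantile(0.025), abs=1e-12)
    assert s.interval("p")[1] == pytest.approx(oracle_quantile(0.975), abs=1e-12)


# ---------------------------------------------------------------------------
# goodness_of_fit
# ---------------------------------------------------------------------------

def test_zero_noise_dataset_fit_by_its_truth_has_zero_residuals(trace_factory, truth):
    exact = dataclasses.replace(truth, sigma_pH0=0.0, sigma_pH=0.0)
    design = StudyDesign(n_batches=2)
    ds = generate_dataset(design, exact, seed=1)
    names = ["mu_pH0", "sigma_pH0", "sigma_pH", "lambda",
             "delta_Air", "delta_MAP1", "delta_MAP2", "theta"]
    draws = {nm: np.full((2, 20), exact.get(nm)) for nm in names}
    for b in ds.batch_ids:
        draws[f"pH0[{b}]"] = np.full((2, 20), ds.truth_pH0[b])
    tr = trace_factory(draws, n_obs=ds.n_obs, batch_ids=ds.batch_ids)
    gof = goodness_of_fit(summarize_posterior(tr), ds)
    assert np.allclose(gof["residual"], 0.0, atol=1e-12)
    # residual definition: observed minus adjusted
    gof2 = gof.copy()
    gof2.loc[0, "pH"] = gof2.loc[0, "pH_adjusted"] - 0.10
    assert (gof2.loc[0, "pH"] - gof2.loc[0, "pH_adjusted"]) == pytest.approx(-0.10)


def test_fitted_residuals_recover_noise_scale_and_show_no_trend(short_fit, dataset360):
    """Residual sd tracks the generating sigma_pH = 0.15; no trend vs fitted."""
    gof = goodness_of_fit(summarize_posterior(short_fit), dataset360)
    sd = gof["residual"].std(ddof=1)
    assert abs(sd - 0.15) / 0.15 < 0.20
    slope = np.polyfit(gof["pH_adjusted"], gof["residual"], 1)[0]
    assert abs(slope) < 0.1


def test_gof_rejects_unknown_batch(short_fit):
    from phkinetics import Condition, Dataset, Observation

    other = Dataset.from_observations(
        [Observation("OTHER_BATCH", Condition(1.0, "Air"), 8.0, 6.1)]
    )
    with pytest.raises(ValueError, match="batch"):
        goodness_of_fit(summarize_posterior(short_fit), other)
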