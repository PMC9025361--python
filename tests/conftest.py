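import numpy as np
import pytest

from phkinetics import (
    Dataset,
    MCMCConfig,
    StudyDesign,
    generate_dataset,
    model_variant,
    reference_estimates,
    run_mcmc,
)


@pytest.fixture(scope="session")
def truth():
    return reference_estimates()


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def dataset360(design, truth):
    """One full-design synthetic dataset (10 batches x 9 conditions x 4 days)."""
    return generate_dataset(design, truth, seed=42)


@pytest.fixture(scope="session")
def short_fit(dataset360):
    """A quick but usable M3 fit shared by diagnostics/selection/simulation tests."""
    cfg = MCMCConfig(n_chains=2, burn_in=800, n_iterations=2400, thinning=4, seed=7)
    return run_mcmc(dataset360, model_variant("M3"), cfg)


@pytest.fixture(scope="session")
def tiny_dataset(truth):
    """Four observations from a single batch, one condition (cheap likelihood)."""
    design = StudyDesign(n_batches=1, lactate_doses=(2.0,), atmospheres=("Air",))
    return generate_dataset(design, truth, seed=11)


def make_trace(draws_by_param, deviance=None, variant_name="M3", n_obs=0,
               batch_ids=(), config=None):
    """Assemble a Trace directly from per-parameter chain arrays (tests only)."""
    from phkinetics import Trace

    names = tuple(draws_by_param)
    arrs = [np.asarray(draws_by_param[nm], dtype=float) for nm in names]
    n_chains, n_keep = arrs[0].shape
    draws = np.stack(arrs, axis=2)
    if deviance is None:
        deviance = np.zeros((n_chains, n_keep))
    if config is None:
        thin = 1
        config = MCMCConfig(n_chains=n_chains, burn_in=0, n_iterations=n_keep * thin,
                            thinning=thin, seed=0)
    return Trace(
        draws=draws,
        param_names=names,
        deviance=np.asarray(deviance, dtype=float),
        variant=model_variant(variant_name),
        config=config,
        n_obs=n_obs,
        batch_ids=tuple(batch_ids),
    )


@pytest.fixture
def trace_factory():
    return make_trace
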