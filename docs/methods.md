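# Methods

## Model

pH monitoring data from fresh meat products are organised in three levels:
production batch, process condition (lactate dose × packaging atmosphere)
and sampling time.  The observed pH `Y` of a sample from batch *r* under
condition *k* at storage day *t* is modelled as

```
Y            ~ N( m_k(t; pH0_r), σ_pH )                 (observation noise)
m_k(t; pH0)  = pH0 − β_k · min(t, θ)                    (two-phase mean)
ln β_k       = λ · Lactate_k^n + δ_p(k)                 (log-linear rate)
pH0_r        ~ N( μ_pH0, σ_pH0 )                        (batch effect)
```

Assumptions worth spelling out:

* **Two phases, shared breakpoint.**  pH falls linearly at rate β_k and is
  exactly flat after the stabilisation time θ, which is common to all
  conditions.  The plateau reflects the buffering capacity of the meat
  matrix; a single θ keeps the parameter count workable when each curve has
  only four time points.
* **One initial pH per batch.**  All conditions of a batch are prepared from
  the same meat, so they share one latent `pH0_r`.  This is the hierarchical
  layer that lets nine non-independent curves per batch borrow strength.
* **Lactate as a continuous covariate.**  `Lactate^n` with the convention
  `0^n := 0` for `n > 0`.  For `n ≤ 0` the zero-dose power is undefined; such
  states receive log-posterior −∞ and are automatically rejected, which on
  data containing zero-lactate conditions confines a free exponent to
  (0, 3).
* **Homoscedastic Gaussian noise** with a single σ_pH across conditions and
  times.  Every spread parameter in the package is a standard deviation —
  never a variance or a precision — in priors, likelihood and outputs alike.
* Storage-temperature profiles are not a covariate; their effect is absorbed
  into the kinetic parameters.

## Parameters, priors and the four variants

| parameter | meaning | units | prior |
|---|---|---|---|
| μ_pH0 | mean initial pH across batches | pH | N(5.84, 0.11) |
| σ_pH0 | between-batch sd of initial pH | pH | half-N(0, 0.1) |
| σ_pH | measurement sd | pH | half-N(0, 0.1) |
| λ | lactate slope on log rate | per (% w/w)^n | U(−1, 1) |
| δ_Air, δ_MAP1, δ_MAP2 | atmosphere offsets on log rate | — | U(−10, 10) |
| n | lactate scale exponent | — | 1 (fixed) or U(−3, 3) |
| θ | stabilisation time | days | 15 (fixed) or U(8, 22) |

The informative μ_pH0 prior comes from earlier fresh-poultry-sausage
surveys; the U(8, 22) breakpoint prior brackets the producers' 15-day
use-by date by ±7 days.  The half-normal density used for the sds is
`2·φ(x/0.1)/0.1` on `x ≥ 0`.

Variants: **M1** fixes n = 1 and θ = 15 d (7 free parameters), **M2** fixes θ
only (8), **M3** fixes n only (8), **M4** estimates both (9) — counting the
seven parameters of the first block plus free members of {n, θ}.

A consequence of the sd-parameterised μ_pH0 prior is visible in recovery
experiments: with ten batches and σ_pH0 ≈ 0.1 the prior keeps roughly 7% of
the posterior weight for μ_pH0, so its posterior median sits a few
hundredths of a pH unit below the batch average (e.g. ≈ 6.44 when the
generating value is 6.49).  This shrinkage is the correct Bayesian answer
under these priors, and it was verified against an independent ensemble
sampler during development; software that reads the second normal argument
as a precision would instead behave as if this prior were nearly flat.

## Sampler

Inference uses an adaptive Gaussian random-walk Metropolis-within-Gibbs
sampler written for this model:

* One Metropolis block per free top-level parameter per sweep.  σ_pH0 and
  σ_pH are proposed on the log scale with the Jacobian correction, so
  positivity costs no rejections.
* The latent `pH0_r` vector is refreshed each sweep by an exact conjugate
  Gibbs draw — the two-phase mean is linear in pH0, so each batch's full
  conditional is normal.  This is the main reason mixing is fast despite the
  non-differentiable breakpoint, which the scalar Metropolis step on θ
  handles without gradients.
* Proposal scales follow a Robbins–Monro recursion (step t^−0.6) toward a
  0.44 acceptance rate during burn-in only and are frozen afterwards, so the
  post-burn-in kernel is a fixed, valid MCMC kernel.  The frozen scales and
  per-block acceptance rates are stored on the trace.
* Defaults mirror the study's configuration: 3 chains, 5,000 burn-in sweeps,
  60,000 retained-phase sweeps thinned by 6 → 10,000 draws per chain,
  30,000 pooled.  Retained iterations are burn_in + thinning,
  burn_in + 2·thinning, …
* Chain starts (auto mode) are overdispersed prior draws, with uniform
  supports shrunk 10% toward the centre so no chain starts on a zero-density
  boundary, and sds bounded away from 0; a start with non-finite posterior
  is redrawn (up to 100 times) before an error names the offending
  parameter.  Explicit per-chain starting values are accepted.
* Every chain has its own stream spawned from the single configured seed;
  identical inputs give bit-identical traces.  With an empty dataset the
  likelihood is identically zero and the sampler targets the prior, which is
  used as a correctness check.
* `run_mcmc(..., fixed=...)` can pin top-level parameters and/or the latent
  pH0 vector.  This exists for validation: with everything but one Gaussian
  location parameter pinned, the exact posterior is known in closed form and
  the sampler must reproduce it.

The per-draw deviance D = −2·log-likelihood is stored alongside the draws.
Only the observation model counts as likelihood; the hierarchical pH0 layer
is part of the prior.  This choice fixes the DIC definition below.

## Model comparison, summaries, diagnostics

DIC uses the Spiegelhalter decomposition: `D̄` is the mean stored deviance,
the plug-in deviance is evaluated at the posterior mean of *all* sampled
quantities (latent pH0 included), `pD = D̄ − D(mean)` and
`DIC = D̄ + pD = 2·D̄ − D(mean)`.  Because other engines apply different
penalties to hierarchical models, absolute DIC values are not comparable
across implementations; model choice here rests on the within-implementation
ordering, with ties broken toward fewer free parameters.

Point estimates are pooled-chain medians; 95% credibility intervals are the
(2.5%, 97.5%) quantiles with linear interpolation between order statistics.
Goodness of fit reports `residual = observed − adjusted`, the adjusted value
being the two-phase mean at the medians with each batch's estimated pH0.

Convergence: classical Gelman–Rubin PSRF from between/within-chain variances
of the retained draws (reported with a floor at 1, since the finite-sample
deflation term can push the raw ratio marginally below unity for
well-mixed chains), and Geweke z comparing the first 10% of each chain with
its last 50%, with standard errors from a batch-means estimate (batch size
≈ √window) of the spectral density at zero — a robust, dependency-free
estimator.  Default pass thresholds are R-hat < 1.1 and |z| < 2; both are
conventional values and configurable, as the criteria themselves do not
prescribe thresholds.  A constant chain yields z = 0 with a warning.

## Posterior-predictive simulation

For a chosen condition, every pooled draw is pushed through the kinetic
model on a time grid; the band is the pointwise (2.5%, 50%, 97.5%) quantiles
across draws.  The default mode draws a *new* batch initial pH per draw from
N(μ_pH0, σ_pH0) and adds no measurement noise, so the band shows kinetic
uncertainty plus batch variability — the view relevant for a future
production batch.  Both toggles (mean-batch start, additive measurement
noise) are exposed; noise can only widen the band, and the pointwise
construction makes no claim of simultaneous coverage.

## Synthetic data generator

`generate_dataset` draws from exactly the generative model above under a
configurable `StudyDesign`; the default design is the monitoring campaign
the model was built for — 10 batches × 3 lactate doses (0, 1, 2 % w/w) ×
3 atmospheres (Air, 70%O₂-30%CO₂, 50%CO₂-50%N₂) × sampling days 2, 8, 15,
22, one value per cell, i.e. one averaged measurement per
(batch, condition, day), matching how technical replicates are reported in
such campaigns.  The default generating truth is the package's
`reference_estimates()` (θ = 12.9 d, λ = −0.095, δ_Air = −2.430,
δ_MAP1 = −2.487, δ_MAP2 = −2.339, μ_pH0 = 6.49, σ_pH0 = 0.10,
σ_pH = 0.15, n = 1).  Latent batch draws are kept as retrievable truth in a
separate sidecar so recovery tests can score estimates while the fitting
pipeline never sees them.

What the generator does **not** emulate: technical-replicate error structure
beyond iid Gaussian noise, occasional gross outliers (real campaigns show
them), day-to-day temperature shifts, or condition-dependent breakpoints.
Passing recovery tests therefore demonstrates the estimator is correct and
well calibrated *under the model's own assumptions*; it does not certify
those assumptions for any particular real product.

## Problem sizes used in tests

The shipped test-suite and acceptance runs use deliberately scaled problem
sizes chosen to make the checks sharp but quick: the standard recovery run
fits 3 chains × 20,000 iterations (thinning 4, burn-in 5,000) to one
360-observation dataset; the model-comparison experiment fits M1/M2/M3 to
ten datasets with 2 chains × 4,000 iterations each; prior-recovery and
conjugate-agreement checks use prior-only or pinned-parameter runs where
sweeps are cheap.  Full-scale defaults (3 × 60,000, thin 6) remain the
package defaults and are exercised for bookkeeping on a small dataset.

## Known limitations and open choices

* A single breakpoint θ across all conditions; condition-specific
  breakpoints would need denser sampling designs.
* O₂/CO₂ percentages are not continuous covariates; atmospheres are
  categorical offsets.
* Chain run lengths are user configuration; no automatic run-length
  determination is performed.
* Raw-data layouts from external monitoring campaigns are not parsed
  directly: map your columns to
  `batch_id, lactate_pct, atmosphere, day, pH` (atmosphere tokens Air /
  MAP1 / MAP2, case-insensitive) and feed the CSV to `read_dataset` — a
  deliberate decision to keep the package independent of any one data
  deposit's layout.
* Quantile-based bands are pointwise in time, not simultaneous.
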