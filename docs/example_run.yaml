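# Example end-to-end pipeline configuration for `phkinetics all --config ...`.
# Generates a synthetic monitoring campaign, fits all four model variants,
# runs convergence diagnostics, picks the lowest-DIC variant, summarises it
# and simulates two formulation scenarios under each atmosphere.
outdir: phkinetics_run
generate: true
seed: 7
variants: [M1, M2, M3, M4]
design:
  n_batches: 10
  lactate_doses: [0.0, 1.0, 2.0]
  atmospheres: [Air, MAP1, MAP2]
  sampling_days: [2, 8, 15, 22]
mcmc:
  n_chains: 3
  burn_in: 5000
  n_iterations: 20000
  thinning: 4
rhat_threshold: 1.1
geweke_threshold: 2.0
scenarios:
  - {lactate: 0.5, atmosphere: Air,  days: [0, 22, 0.5]}
  - {lactate: 1.5, atmosphere: Air,  days: [0, 22, 0.5]}
  - {lactate: 0.5, atmosphere: MAP1, days: [0, 22, 0.5]}
  - {lactate: 1.5, atmosphere: MAP1, days: [0, 22, 0.5]}
  - {lactate: 0.5, atmosphere: MAP2, days: [0, 22, 0.5]}
  - {lactate: 1.5, atmosphere: MAP2, days: [0, 22, 0.5]}
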