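# Demo pipeline: simulate a two-outcome dataset on a 10x10 rook lattice
# under the default shared-component scenario, fit the joint model and
# both BYM regressions, and compare the fitted risk surfaces.
seed: 7
simulate:
  rows: 10
  cols: 10
  contiguity: rook
  # scenario defaults: delta = 1, expected counts ~ (48, 21) per area,
  # field scales calibrated for shared-variance fractions near 0.66/0.91;
  # override any JointScenario field here, e.g.:
  # scenario:
  #   delta: 1.1
  #   mean_expected: [50, 50]
mcmc:
  n_iter: 6000
  burn_in: 1000
  thin: 5
  n_chains: 4
priors:
  sigma_upper: 2.0
  log_delta_sd: 0.3
  beta_variance: 1.0e5
comparison:
  threshold: 1.0
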