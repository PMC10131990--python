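# Full-pipeline configuration for the bundled Rwanda study aggregates.
# The direct tabulation reproduces the study's published estimates; use
# inclusion_exclusion (the default) for new data. Run with:
#   crc3s report --config examples/rwanda_report.yaml --seed 1 --out out/
marginals_csv: examples/rwanda_marginals.csv
policy: clamp
tabulation: direct
mcmc:
  k_star: 5
  a_alpha: 0.25
  b_alpha: 0.25
  n_samples: 2000
  burn_in: 10000
  thinning: 25
  seed: 1
write_draws: false
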