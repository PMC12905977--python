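# Desk-scale workflow config: completes on one CPU in a few minutes.
seed: 1
sim:
  n_individuals: 500
  n_probes: 500
  n_snps: 800
  var_frac_dnam: 0.25
  var_frac_snp: 0.55
  mqtl_frac: 0.3
  mqtl_r2: 0.2
mcmc:
  n_iter: 1500
  burn_in: 500
  thin: 2
  n_chains: 2
score:
  train_frac: 0.67
phewas:
  n_phenotypes: 20
  alpha: 0.05
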