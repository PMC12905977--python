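# Cohort-scale preset (n ~ 7600 individuals, array-scale marker counts).
#
# MEMORY WARNING: a float64 individuals-by-probes matrix at these
# dimensions is tens of gigabytes; run only on a machine with enough RAM
# (plan roughly 8 bytes * n * (n_probes + n_snps) for the marker matrices
# alone, plus two n x n relationship matrices for the REML stage), and
# expect the mixture-regression stage to take hours at the default chain
# length.
seed: 1
sim:
  n_individuals: 7600
  n_probes: 750000
  n_snps: 500000
  var_frac_dnam: 0.25
  var_frac_snp: 0.55
  mqtl_frac: 0.3
  mqtl_r2: 0.2
mcmc:
  n_iter: 10000
  burn_in: 5000
  thin: 5
  n_chains: 2
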