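# Example pipeline configuration (desk-scale defaults).
seed: 1
outdir: toxomix_out
syndata:
  modality_dims: {mrna: 2000, protein: 500, metabolite: 200, lipid: 150, mirna: 100}
  dropout_rate: 0.02
npa:
  n_perm: 500
  n_networks: 2
factors:
  k_init: 10
  tol: 1.0e-6
  max_iter: 300
sgcca:
  keep: 30
  ncomp: 2
pcsf:
  mu: 0.0005
  omega: 0.6
  beta: 1000.0
  ensemble_runs: 10
  noise: 0.1
  grid: true
enrich:
  n_perm: 1000
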