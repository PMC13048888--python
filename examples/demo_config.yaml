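# End-to-end synthetic demo: small enough to run in well under a minute.
out_dir: results/demo
seed: 0
log_level: INFO
spatial:
  n_samples_per_condition: 2
  n_spots_per_sample: 400
  rho_control: 0.0
  rho_disease: 0.8
sc:
  n_cells: 300
  frac_low_quality: 0.1
  frac_doublet: 0.05
roi: {}
qc: {}
deg: {}
module:
  n_bins: 24
  n_ctrl: 50   # bins of a 2,000-gene simulation hold ~83 genes
coloc:
  k_list: [3, 4, 5, 6, 8, 10, 12, 15]
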