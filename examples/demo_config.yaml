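# Demo pipeline configuration: canonical calibrated parameter set, the four
# characterized expression setups, 1 mM IPTG induction at 2 h over a 12-h
# batch.  Empty `parameters` inherits every default (the calibrated fixture);
# override any kinetic constant here by name.
seed: 7
parameters: {}
variants:
  - {label: NO_FB, promoter_scale: 0.0, rbs_scale: 1.0}
  - {label: WT_STRONG, promoter_scale: 1.0, rbs_scale: 1.0}
  - {label: MUT_STRONG, promoter_scale: 0.5, rbs_scale: 1.0}
  - {label: MUT_WEAK, promoter_scale: 0.5, rbs_scale: 0.4}
schedule:
  iptg_conc: 1.0   # mM
  t_induce: 2.0    # h
  t_end: 12.0      # h
noise:
  fluor_cv: 0.10
  od_cv: 0.05
  fraction_sd: 0.05
clone_variability:
  sigma_promoter: 0.2
  sigma_rbs: 0.2
  sigma_mu: 0.05
generate:
  n_clones: 4
  sampling_interval: 0.5
fit:
  free: [k_tx_G, K_tetR, k_agg]
  n_starts: 4
crossval:
  k: 4
  unit: clone
  n_starts: 2
stages:
  simulate: true
  generate: true
  compare: true
  fit: false        # enable for a full (slower) calibration run
  sensitivity: false
  crossval: false
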