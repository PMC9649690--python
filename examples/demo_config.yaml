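# Demo pipeline configuration: small synthetic study that runs end to end
# in well under a minute. All thresholds default to the printed analysis
# conventions (0.1 TPM prevalence, |FC|>1.5 & FDR<0.05, |rho|>0.2,
# score >= 0.7); the bootstrap is scaled to B=100 for a quick demo.
seed: 1
output_dir: runs/demo
stages: [simulate, specificity, annotate, network, drugassoc, axes]
atlas:
  n_transcripts: 400
  n_cell_lines: 66
  n_lineages: 22
  n_planted_specific: 40
  specific_ratio: 0.8
  dropout_prob: 0.2
drugs:
  n_drugs: 4
  n_driver_transcripts_per_drug: 3
  effect_size: 1.0
  noise_sd: 1.0
regulome:
  n_rbps: 6
  n_regulated_per_rbp: 40
  frac_bound_of_regulated: 0.7
thresholds:
  bootstrap_B: 100
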