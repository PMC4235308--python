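# Desk-scale synthetic run: 3 cohorts, 60 genes x 8 miRNAs, 40 samples each,
# with survival tables so every pipeline stage has inputs.
#   mirecur --config examples/synthetic_small.yaml run
outdir: mirecur_out
seed: 7
simulate:
  D: 3
  N: 60
  M: 8
  T: 40
  survival:
    censor_rate: 0.2
locfdr:
  min_n: 30
  n_bins: 40
  poly_df: 5
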