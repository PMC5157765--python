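# Demo pipeline run: coupled (lag-4) sibutramine-like scenario.
outdir: scratch/demo_out
seed: 1
simulate:
  preset: sibutramine
  n_months: 137
  coupling_coeff: 0.8
  true_lag: 4
specific_ae: cardiac
top_k: 20
level: hlt
include_trial_literature: false
prr: true
max_lag: 12
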