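# Demo pipeline run: two-state folding at moderate salt.
# fretfold run examples/demo_run.yaml out/demo
seed: 7
simulate:
  n_traces: 100
  n_frames: 600
  frame_interval: 0.050
  scheme:
    state_names: [U, F]
    fret_mean: [0.35, 0.89]
    fret_sd: [0.05, 0.05]
    rates:
      - [0.0, 0.84]
      - [0.64, 0.0]
condition:
  nacl_mM: 100.0
histogram:
  k: 2   # U and F by inspection; 10-frame averages of switching traces
         # otherwise tempt BIC into extra mixed-value components
hmm:
  k: 2
kinetics:
  censor_policy: mle_censored
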