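# Gap-sweep experiment: synthetic cohort, both structures, interp backend.
# Run:  slicefill sweep --config examples/sweep.yaml --seed 1 --out-dir results/
cohort:
  n_patients: 3          # remaining keys override PhantomConfig defaults
  shape: [24, 64, 64]
  spacing: [4.0, 1.0, 1.0]
gaps: [1, 5, 10]
backend: interp          # or: net
eval_scope: all          # or: withheld
network:                 # used only by the net backend
  depth: 3
  base_channels: 16
training:
  epochs: 30
  batch_size: 16
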