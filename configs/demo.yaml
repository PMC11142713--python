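# Deterministic synthetic demo: a 60x60 ~1-km grid with eight autocorrelated
# predictor layers (a built-in near-duplicate precipitation pair exercises the
# collinearity pruning), 998 presence points from a known logistic occurrence
# process, 1,000 background points, all five models, AUC-weighted consensus,
# the backward-selected incidence regression, and hospital-style case-table
# summaries. Runs in a few minutes on one CPU.
output_dir: runs/demo
seed: 1
models:
  n_trees: 100
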