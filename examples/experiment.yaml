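# Example experiment config for `strkin run --config examples/experiment.yaml --out bundle/`
# Scaled-down end-to-end run on a synthetic 21-locus table.
seed: 1
n_founders: 2000
synth:
  n_loci: 21
  alleles_per_locus: 10
  concentration: 1.0
dataset: pair
split: [0.90, 0.05, 0.05]
hyperparameters:
  iterations: 400
  learning_rate: 0.1
  depth: 10
  early_stopping_rounds: 50
similarity_pairs: 5000
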