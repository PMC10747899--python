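# Small tuning study on synthetic data (finishes in ~1 minute on one CPU).
# Drop `generator` and set `data_path: your_series.csv` to tune on real data.
generator:
  n_series: 2
  length: 1800
  anomalous_fraction_target: 0.85
optimizer:
  pop_size: 4
  iterations: 3
gipso:
  pc: 0.1
  md: 0.1
  pm: 0.1
variants: [gipso, pso]
control: gipso
repeats: 3
base_seed: 1
space_overrides:
  epochs: {lower: 5, upper: 10}
output_dir: results/demo
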