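# Small synthetic study: a 40 x 40 km landscape on a 1-km grid with the
# full stage sequence (fields, vectors, covariates, smoothing, bootstrap,
# stratified forests, prediction, summaries).
seed: 5
landscape:
  extent: [0.0, 0.0, 40000.0, 40000.0]
  cell_size: 1000.0
  n_wells: 10
  park_count: 2
  harvest_fraction: 0.08
  road_density_target: 0.4
n_points: 220
sampling_fraction: 0.65
smoothing:
  bandwidth: 9000.0
  cell_size: 1000.0
forest:
  n_trees: 300
  mtry: 18
  train_fraction: 0.5
bootstrap_replicates: 99
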