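# Default pipeline configuration: synthetic stroke-schema cohort with 10%
# MCAR missingness, auto-encoder imputation, golden-flower feature
# selection, water-drop delta tuning, GAN classification, evaluation.
# Any omitted key falls back to the library default.

cohort:
  n: 2000
  missing_rate: 0.1
  minority_fraction: 0.5

daem:
  epochs: 300
  weight_decay: 0.003

gfs:
  population_size: 20
  iterations: 50
  switch_probability: 0.8

colbgan:
  epochs: 120
  delta: 1.0
  feature_match_weight: 5.0

wdo:
  n_drops: 5
  max_iterations: 8

delta_grid: [0.0, 0.01, 0.1, 0.5, 1.0, 2.0]
tune_epochs: 25
accuracy_weight: 0.9
cv_folds: 3
test_fraction: 0.25
global_seed: 1
output_dir: dacl_output
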