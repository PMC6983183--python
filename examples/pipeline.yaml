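# Example end-to-end pipeline configuration (small, runs in ~1 min).
input_mode: synthetic
synthetic:
  n_subjects: 40
  night_duration_s: 14400.0   # 4 h
  seed: 0                     # overridden by the top-level seed
filter:
  min_rr_ms: 300.0
  max_rr_ms: 1500.0
  rel_tol: 0.20
  half_width_beats: 10
spectral:
  window_s: 300.0
  displacement_s: 10.0
  resample_hz: 4.0
  taper: hamming
classification:
  responses: [ahi, odi, ess]
  classifiers:
    - name: svm
  percentiles: [25, 50, 75]
  folds: 5
  repeats: 2
conditions:
  - [belt, true]
  - [belt, false]
  - [patch, true]
  - [patch, false]
ordination_sensor: belt
ordination_filtered: true
n_permutations: 999
out_dir: apneahrv_out
seed: 1
make_plots: true
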