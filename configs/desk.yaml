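# Desk-scale demo: full simulate -> split -> train -> extract -> evaluate
# pipeline on one CPU in a couple of minutes.
#
#   brainid run-all --config configs/desk.yaml --out runs/desk
#
seed: 1
out_dir: runs/desk
simulate:
  grid_shape: [24, 28, 24]
  n_timepoints: 40
  signature_amplitude: 5.0   # identity signal, in units of noise_sd
  group_amplitude: 3.0       # patient-vs-control spatial effect
  age_amplitude: 1.0
  noise_sd: 1.0
  smoothing_sigma_vox: 1.5
  n_patients: 24
  n_controls: 24
  age_range: [18.0, 65.0]
split:
  counts:
    train1: [6, 6]    # encoder pretext task
    train2: [9, 9]    # linear probe fitting
    test: [9, 9]      # held-out evaluation
encoder:
  crop_shape: [24, 28, 24]
  n_blocks: 2
  base_channels: 4
  n_tail_convs: 2
  dense_input: flatten
  double_at_entry: false
train:
  lr_schedule: [[0.001, 250], [0.0001, 100]]
  batch_size: 8
  eval_every: 50
baselines:
  atlas_blocks: [3, 3, 3]
  pca_components: 3
evaluate:
  precision_k: 40     # per-subject timepoint count
  eval_splits: [train2, test]
  logistic_c: 1.0
  ridge_alpha: 1.0
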