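# Desk-scale end-to-end demo: synthetic cohort -> tiling -> QC -> CV.
out_dir: scratch/demo_run
mode: synth
seed: 1
synth:
  n_patients: 10
  scans_per_patient: 2
  scan_width_range: [512, 768]
  scan_height_range: [512, 768]
grid:
  patch_size: 256
  overlap: 0.25
  resize_to: 32
qc:
  artifact_threshold: 0.5
  min_tissue_fraction: 0.2
cnn:
  input_size: 32
  filters: [8, 16, 32, 64]
  dense_units: 64
  learning_rate: 0.001
  batch_size: 32
  max_epochs: 4
  early_stop_patience: 4
  bn_momentum: 0.9
n_folds: 2
n_val: 1
tasks: [abnormal, active_inflammation, chronic_changes]
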