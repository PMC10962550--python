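# Feature-level synthetic study, scaled for a quick desk run.
out_dir: scratch/example_run
seed: 1
entry: features
synthetic:
  n_normative_subjects: 60
  n_patients_good: 5
  n_patients_poor: 5
  n_regions: 40
  n_regions_covered_range: [18, 28]
  n_resected_range: [4, 7]
  recording_hours: 4.0
min_subjects: 5
line_hz: 50.0
relative_mode: log_then_normalize
run_subsampling: true
k_grid: [1, 5, 30]
subsample_reps: 100
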