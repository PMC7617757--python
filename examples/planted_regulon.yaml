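# Full planted-regulon demo: 31 genes with the OxyR-regulon category
# structure (11 sustained up, 2 transient up, 8 sustained down, 7 transient
# down, 3 unchanged), classified from growth-corrected promoter activity.
mode: planted_regulon
seed: 7
templates: regulon_panel
layout:
  n_trenches: 300       # ~2500 frontier-cell tracks per gene
  cells_per_trench: 2
  frame_interval: 3.0
  t_pre: 120.0
  t_post: 360.0
noise:
  meas_cv: 0.05
  ou_cv: 0.15
  ou_tau: 30.0
  shared_fraction: 0.0
classify:
  alpha: 0.05
  threshold: 2.12
  min_frames: 10
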