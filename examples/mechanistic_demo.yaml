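# Mechanistic demo: two OxyR-driven reporters under a 100 uM step.
# The high-K_D reporter responds pulsatile (strong early activity that
# relaxes), the low-K_D reporter gradually; the dynamics call comes from the
# peak-vs-steady regression of reconstructed promoter activity across doses.
mode: mechanistic
seed: 11
genes:
  - {name: reporter_hiKD, K_D: 0.1,  K_ind: 3.0,  R_basal: 0.05}
  - {name: reporter_loKD, K_D: 0.01, K_ind: 0.3,  R_basal: 0.05}
protocol:
  label: step
  concentration: 100.0
layout:
  n_trenches: 30
  cells_per_trench: 4
trench:
  attenuation_per_cell: 0.3
noise:
  meas_cv: 0.05
  ou_cv: 0.15
  ou_tau: 30.0
classify:
  alpha: 0.05
  threshold: 2.12
  doses: [25.0, 50.0, 100.0]
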