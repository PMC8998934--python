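# Shared conditions for the analysis scripts (01-07).
# Down-scaled acquisition grid; acquisition constants (FOV, slice thickness,
# TE list, tissue T2) keep the package defaults.
cohort_dir: results/cohort
matrix_size: [48, 48]
n_slices: 6
noise_sd: 3.0
n_animals: 4
weeks: [1, 2, 3, 4, 5, 6, 7, 8]
seed: 20260921
# BLI generator (power law on the log10 scale)
flux_log10_intercept: 5.81
flux_slope: 1.04
flux_log_resid_sd: 0.10
# survival cohort: sham vs irradiation vs multimodal arms
groups:
  sham: 44.0
  RT: 50.0
  RT/DEC/ABC: 66.0
control_group: sham
n_per_group: 10
censor_day: 139.0
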