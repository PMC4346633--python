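[run]
seed = 0
generation_offset = 1
n_founders = 100

[imaging]
window_lo_min = 3960.0
window_hi_min = 5400.0
frame_lo_min = 3.0
frame_hi_min = 4.0
max_depth = 3
activation_lag_min = 1440.0

[distributions]
gen1_mean_h = 13.4
gen1_sd_h = 5.4
gen3_mean_h = 14.3
gen3_sd_h = 4.4
slow_median_min = 1800.0
slow_sigma_log = 0.45

[heritability]
frac_family = 0.05
frac_drift = 0.06
frac_division = 0.79
frac_individual = 0.1

[slow_state]
g_onset = 8
p_on = 0.25
p_stay = 0.8
p_arrest = 0.35

[reporter]
plateau_au = 1000.0
ko_high_plateau_au = 2500.0
rise_min = 8.0
decay_min = 8.0
noise_cv = 0.05
dn_duration_min = 60.0
g1_frac_fast = 0.25
g1_frac_slow = 0.7

[ctv]
ctv_founder_au = 10000.0
ctv_cv = 0.15
ctv_floor_generation = 9

[brdu]
f_s = 0.6

[death]
death_hazard_per_min = 0.0
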