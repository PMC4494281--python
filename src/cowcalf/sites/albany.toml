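[site]
name = "Albany"
latitude = -34.9
pasture = "kikuyu"
stocking_rate = 0.6
seasonality = "temperate"

[climate]
monthly_tmin_mean = [13.98, 13.98, 13.1, 11.58, 9.82, 8.3, 7.42, 7.42, 8.3, 9.82, 11.58, 13.1]
monthly_tmax_mean = [24.56, 24.56, 23.47, 21.59, 19.41, 17.53, 16.44, 16.44, 17.53, 19.41, 21.59, 23.47]
monthly_rain_mean = [16.2, 22.8, 40.6, 65.0, 89.4, 107.2, 113.8, 107.2, 89.4, 65.0, 40.6, 22.8]
annual_rain_target = 780.0
rain_day_probability = [0.07, 0.109, 0.175, 0.289, 0.385, 0.476, 0.489, 0.461, 0.397, 0.28, 0.18, 0.098]
temp_sd = 2.0
rain_autocorr = 0.3

[soil]
capacity = 70.0
wfps_at_capacity = 0.85
leach_eff = 0.001
k_denit = 0.0005
k_mineralisation = 0.0015
wfps_anaerobic = 0.6
urine_volat_frac = 0.1

[species]
pathway = "C4"
rue = 0.59
t_base = 5.0
t_opt = 22.0
t_max = 40.0
max_growth = 65.0
senescence_rate = 0.02
digestibility_new = 67.0
digestibility_floor = 48.0
quality_decay = 0.1
legume_fraction = 0.21
fixation_coeff = 0.04
n_new = 3.0
n_half_sat = 6.0
dead_digestibility = 45.0
dead_decay = 0.015

[management]
residual = 1.0
supplement_me = 10.0
supplement_n = 2.0
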