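[site]
name = "Dookie"
latitude = -36.37
pasture = "phalaris"
stocking_rate = 0.8
seasonality = "mediterranean"

[climate]
monthly_tmin_mean = [13.9, 13.9, 12.34, 9.65, 6.55, 3.86, 2.3, 2.3, 3.86, 6.55, 9.65, 12.34]
monthly_tmax_mean = [27.54, 27.54, 25.6, 22.24, 18.36, 15.0, 13.06, 13.06, 15.0, 18.36, 22.24, 25.6]
monthly_rain_mean = [21.6, 25.1, 34.8, 48.0, 61.2, 70.9, 74.4, 70.9, 61.2, 48.0, 34.8, 25.1]
annual_rain_target = 576.0
rain_day_probability = [0.116, 0.149, 0.187, 0.267, 0.329, 0.394, 0.4, 0.381, 0.34, 0.258, 0.193, 0.135]
temp_sd = 2.6
rain_autocorr = 0.3

[soil]
capacity = 110.0
wfps_at_capacity = 0.95
leach_eff = 0.007
k_denit = 0.004
k_mineralisation = 0.0015
wfps_anaerobic = 0.6
urine_volat_frac = 0.1

[species]
pathway = "C3"
rue = 0.7
t_base = 3.5
t_opt = 17.0
t_max = 33.0
max_growth = 55.0
senescence_rate = 0.02
digestibility_new = 73.0
digestibility_floor = 52.0
quality_decay = 0.1
legume_fraction = 0.07
fixation_coeff = 0.04
n_new = 3.0
n_half_sat = 6.0
dead_digestibility = 45.0
dead_decay = 0.015

[management]
residual = 0.5
supplement_me = 10.5
supplement_n = 2.5
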