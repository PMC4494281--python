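[site]
name = "Vasey"
latitude = -37.4
pasture = "phalaris"
stocking_rate = 0.9
seasonality = "mediterranean"

[climate]
monthly_tmin_mean = [12.04, 12.04, 10.79, 8.64, 6.16, 4.01, 2.76, 2.76, 4.01, 6.16, 8.64, 10.79]
monthly_tmax_mean = [25.38, 25.38, 23.7, 20.78, 17.42, 14.5, 12.82, 12.82, 14.5, 17.42, 20.78, 23.7]
monthly_rain_mean = [20.8, 25.0, 36.4, 52.0, 67.6, 79.0, 83.2, 79.0, 67.6, 52.0, 36.4, 25.0]
annual_rain_target = 623.9999999999999
rain_day_probability = [0.122, 0.162, 0.213, 0.315, 0.396, 0.479, 0.488, 0.463, 0.41, 0.305, 0.221, 0.147]
temp_sd = 2.3
rain_autocorr = 0.3

[soil]
capacity = 90.0
wfps_at_capacity = 0.9
leach_eff = 0.005
k_denit = 0.003
k_mineralisation = 0.0015
wfps_anaerobic = 0.6
urine_volat_frac = 0.1

[species]
pathway = "C3"
rue = 0.75
t_base = 3.5
t_opt = 17.0
t_max = 33.0
max_growth = 60.0
senescence_rate = 0.02
digestibility_new = 73.0
digestibility_floor = 52.0
quality_decay = 0.1
legume_fraction = 0.08
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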