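[site]
name = "Wagga Wagga"
latitude = -35.12
pasture = "phalaris"
stocking_rate = 0.8
seasonality = "mediterranean"

[climate]
monthly_tmin_mean = [15.88, 15.88, 14.2, 11.28, 7.92, 5.0, 3.32, 3.32, 5.0, 7.92, 11.28, 14.2]
monthly_tmax_mean = [29.93, 29.93, 27.86, 24.27, 20.13, 16.54, 14.47, 14.47, 16.54, 20.13, 24.27, 27.86]
monthly_rain_mean = [25.2, 27.9, 35.5, 45.8, 56.0, 63.6, 66.3, 63.5, 56.0, 45.8, 35.5, 27.9]
annual_rain_target = 548.9999999999999
rain_day_probability = [0.125, 0.153, 0.176, 0.235, 0.278, 0.326, 0.329, 0.315, 0.287, 0.227, 0.182, 0.138]
temp_sd = 2.8
rain_autocorr = 0.3

[soil]
capacity = 120.0
wfps_at_capacity = 0.97
leach_eff = 0.01
k_denit = 0.005
k_mineralisation = 0.0015
wfps_anaerobic = 0.6
urine_volat_frac = 0.1

[species]
pathway = "C3"
rue = 0.7
t_base = 3.5
t_opt = 17.5
t_max = 34.0
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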