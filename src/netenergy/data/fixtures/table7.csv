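diet_id,bw_avg_kg,w_meta_kg075,nem_kcal_day,re_kcal_day,ne_est_kcal_day,ne_det_kcal_day,ne_obs_kcal_day
basal,0.539,0.629,50.12,95.79,145.91,142.33,142.33
corn,0.509,0.603,48.00,112.80,160.80,155.09,155.09
wheat_byproduct,0.458,0.557,44.33,72.81,117.14,110.76,110.76
soybean_meal,0.520,0.612,48.78,76.36,125.14,122.42,122.09
fish_meal,0.565,0.651,51.89,77.23,129.11,123.13,123.13
soybean_oil,0.563,0.650,51.77,118.47,170.24,168.98,168.98
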