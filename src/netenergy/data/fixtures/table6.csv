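diet_id,bw_avg_kg,w_meta_kg075,fi_g_dm_day,mei_kcal_day,re_kcal_day,k_determined_pct,nem_kcal_day,ne_kcal_day
basal,0.539,0.629,71.74,226.51,95.79,73.98,46.54,142.33
corn,0.509,0.603,74.04,238.01,112.80,70.19,42.30,155.09
wheat_byproduct,0.458,0.557,69.28,201.03,72.81,68.19,37.95,110.76
soybean_meal,0.520,0.612,62.43,171.12,76.36,74.68,45.73,122.09
fish_meal,0.565,0.651,62.07,194.25,77.23,70.48,45.91,123.13
soybean_oil,0.563,0.650,69.54,258.40,118.47,77.71,50.50,168.98
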