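diet_id,bw_end_kg,bw_start_kg,bw_avg_kg,w_meta_kg075,adg_g_day,mei_kcal_day,ne_kcal_day,re_kcal_day,nem_kcal_day,hp_kcal_day,hi_kcal_day
basal,0.813,0.158,0.486,0.582,46.80,174.47,127.24,83.44,43.80,91.03,47.23
corn,0.798,0.163,0.480,0.577,45.32,210.48,145.01,95.64,49.36,114.83,65.47
wheat_byproduct,0.796,0.171,0.484,0.580,44.66,184.58,130.87,77.93,52.95,106.66,53.71
soybean_meal,0.876,0.161,0.518,0.611,51.08,171.40,123.59,77.22,46.37,94.17,47.80
fish_meal,0.964,0.156,0.560,0.647,57.73,183.85,117.71,77.31,40.40,106.54,66.14
soybean_oil,0.969,0.166,0.568,0.654,57.36,234.63,174.66,120.35,54.31,114.28,59.97
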