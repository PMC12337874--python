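feeding_level,bw_end_kg,bw_start_kg,bw_avg_kg,w_meta_kg075,adg_g_day,mei_kcal_day,ne_kcal_day,nem_kcal_day,hi_kcal_day,hp_kcal_day,re_kcal_day,rep_kcal_day,rel_kcal_day
1.00,0.813,0.158,0.486,0.582,46.80,174.47,127.24,43.80,47.23,91.03,83.44,46.25,37.18
0.85,0.693,0.168,0.427,0.529,37.94,144.56,95.85,39.80,48.71,88.51,56.05,40.29,14.82
0.70,0.574,0.165,0.369,0.474,29.25,109.87,79.66,35.67,30.21,65.88,43.99,32.21,9.31
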