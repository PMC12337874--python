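feeding_level,mei_per_w075_kcal_kg075_day,re_per_w075_kcal_kg075_day
1.00,299.83,143.39
0.70,231.85,92.82
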