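diet_id,equation,nem_coef_kcal_kg075_day,mem_coef_kcal_kg075_day,k,r2
basal,RE=-75.28+0.71·MEI,75.28,106.68,0.71,0.85
corn,RE=-85.55+0.68·MEI,85.55,125.02,0.68,0.99
wheat_byproduct,RE=-91.31+0.69·MEI,91.31,132.75,0.69,0.83
soybean_meal,RE=-75.89+0.71·MEI,75.89,107.03,0.71,0.94
fish_meal,RE=-62.43+0.65·MEI,62.43,96.68,0.65,0.93
soybean_oil,RE=-83.02+0.73·MEI,83.02,114.34,0.73,0.93
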