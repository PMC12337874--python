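# Reference fixtures

Hand-transcribed reference values from a published comparative-slaughter
net-energy study in Cobb 500 male broilers (7–21 days of age; six diets
built from a corn–soybean basal by weight/weight substitution; three
feeding levels: ad libitum, 85 % and 70 % of ad libitum; two replicate
pens of five birds). All energies are kcal, masses kg, intakes g dry
matter; rates are per bird and per day.

- `table3.csv` — per-diet linear regressions of retained energy on
  metabolizable energy intake (metabolic units): NEm, MEm, k, R².
- `table4.csv` — ad-libitum energy partition per diet (experiment 1).
- `table5.csv` — basal-diet partition by feeding level (experiment 1),
  used to build the two-level simultaneous-equation system.
- `table6.csv` — determined (observed) energy values per diet
  (experiment 2, ad libitum).
- `table7.csv` — model validation table: predicted vs determined NE.
  The published validation table prints 122.42 kcal/day as the
  determined NE for the soybean-meal diet while the determined-values
  table prints 122.09; the published summary mean 137.07 is only
  consistent with 122.09. `ne_det_kcal_day` carries the validation
  table's figure, `ne_obs_kcal_day` the determined-table figure used
  for summary statistics.
- `farrell_system.csv` — the two published metabolic-unit (MEI/W^0.75,
  RE/W^0.75) pairs for the basal diet at ad libitum and 70 % feeding,
  as printed (computed by the original authors from unrounded data;
  re-deriving them from the rounded `table5.csv` cells gives values
  within 0.1).
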