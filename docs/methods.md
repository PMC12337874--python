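# Methods

## The energy system

The package models the linear net-energy system for growing broilers
over a 7-to-21-day balance period. Per bird and per day, metabolizable
energy intake (MEI) splits into retained energy (RE, measured by
comparative slaughter as the difference in whole-body combustible energy
between the start and end groups divided by the period length) and heat
production (HP = MEI − RE). Heat production further splits into the net
energy for maintenance (NEm) and the heat increment (HI = HP − NEm); the
net energy of the diet is NE = NEm + RE. All masses are kept in kg
internally, gains are reported in g/day, energies in kcal; metabolic
body weight is W^0.75 with W the mean of the start and end weights.

Two derived conventions are worth stating explicitly because the source
tables they mirror are ambiguous about them:

* **Average weight** is the arithmetic mean (start + end)/2. The
  reference report typesets this formula with a minus sign, but every
  tabulated value is the arithmetic mean; the minus sign is treated as a
  typographical error.
* **Records are per bird.** A `PenRecord` carries per-bird weights and
  per-bird intake/carcass energies; pen-total entry is supported via
  `balance_pen(..., pen_totals=True)`, which divides intake, carcass
  energies and tissue gains by the pen size. All reference tables are on
  the per-bird daily scale.

Tunable constants, all exposed as function parameters:

| constant | default | units | role |
|---|---|---|---|
| nitrogen-correction energy | 8.22 | kcal/g retained N | N-corrected apparent ME (Hill–Anderson value) |
| protein combustion equivalent | 5.66 | kcal/g | RE split into protein fraction |
| lipid combustion equivalent | 9.35 | kcal/g | RE split into lipid fraction |

When protein/lipid gains are absent the split fields stay NaN rather
than being imputed.

## Maintenance estimation

Both estimators address the same line, RE/W^0.75 = −NEm + k·MEI/W^0.75.

**Regression** (`MaintenanceRegression`): unweighted OLS (statsmodels)
of RE on MEI, by default in metabolic units (per kg^0.75), with
replicate pens entering as separate points. k is the slope, NEm the
negated intercept, MEm = NEm/k (computed lazily from the stored NEm and
k so the identity MEm·k = NEm is exact). A whole-animal fit is available
via `metabolic=False` for comparison. A non-negative intercept (implying
NEm ≤ 0) is flagged on the result rather than raised, so simulation
studies can count such fits. A design with all MEI equal is singular and
rejected.

**Two-level solve** (`FarrellSystem` / `farrell_solve`): the line is
forced through the metabolic-unit balances at two feeding levels —
by convention the extreme levels, ad libitum and 70 % of ad libitum —
giving a closed-form 2×2 linear solve for (k, −a). Estimates of k
outside (0, 1) or a ≤ 0 are flagged, not raised.

`build_farrell_inputs` converts two `EnergyBalance` objects from the
same diet at distinct levels into the system's (MEI/W^0.75, RE/W^0.75)
pairs, ordering by feeding level.

## The prediction model and its validation

`NetEnergyModel` carries the maintenance coefficient `a`
(kcal/kg^0.75/day) at full precision together with the efficiency k and
a provenance string; it predicts NEm = a·W^0.75 and NE = a·W^0.75 + RE.
`prediction_table` reports per-group predictions with means and *sample*
(n−1) standard deviations — the convention that reproduces the bundled
reference summary exactly.

`validate` computes MSPE, its decomposition and Lin's concordance
correlation. Numerical conventions:

* The decomposition ECT = (P̄−Ō)², ER = (Sp−R·So)², ED = (1−R²)·So² and
  the CCC components υ = So/Sp, µ = (Ō−P̄)/√(So·Sp), Cb = 2/(υ+1/υ+µ²)
  use **population (n-denominator) moments**; this is what makes
  ECT+ER+ED equal the MSPE exactly and makes R·Cb equal Lin's direct
  form 2·cov/(var_o+var_p+(Ō−P̄)²). Descriptive sd_obs/sd_pred in the
  report use n−1.
* With the sign convention chosen for µ, predictions exceeding
  observations give µ < 0.
* **Percent error is 100·√MSPE/Ō** (root-MSPE relative to the observed
  mean). The raw-MSPE variant is available behind `rmspe=False`; the
  RMSPE form is the one consistent with the bundled reference summary.
* Perfect prediction makes the decomposition total zero; the component
  percentages are then reported as 0 rather than dividing by zero.
* n < 3 (or zero variance) is rejected for the decomposition and the
  CCC; MSPE accepts n ≥ 2.

The bundled validation fixture is scored at the diet-mean level (n = 6).
Its published lower block (MSPE 17.68, CCC 0.988) was evidently computed
on replicate-level data that was never published and cannot be
reproduced from the six printed means (direct arithmetic gives MSPE
22.13, % error 3.43); the `reproduce` command therefore reports that
block as informational and asserts only quantities that are recomputable
from published cells.

## Synthetic trials

`simulate_trial` emulates the reference design: six diets × feeding
levels (1.00, 0.85, 0.70 of ad libitum) × 2 replicate pens of 5 birds
over 14 days. Per pen: the start weight and the ad-libitum intake are
drawn (intake noise is off by default), restricted intake is the level
fraction of the ad-libitum draw, and growth follows a feed-conversion
map bw_end = bw_start + gain·FI·period — sufficient because the pipeline
only consumes endpoint weights, so a growth-curve model would add
parameters without adding information. Retained energy follows the
generating line RE = k·MEI − NEm·W^0.75 + ε with Gaussian ε on RE only
(carcass-energy measurement dominates error in this design); start/end
body energies are then back-constructed so the comparative-slaughter
arithmetic recovers the generated RE exactly. `paper_like_design()`
parameterises the six diets from the bundled tables: (k, NEm) truths
from the regression table, diet ME densities and the intake/growth
calibration back-calculated so ad-libitum trajectories land in the
reference range (~0.16 kg to 0.80–0.97 kg).

Defaults: bw_start 0.16 ± 0.006 kg, ad-libitum intake 58 g DM/day
(sd 0 by default), RE noise sd 3.0 kcal/day, common start energy
200 kcal. The reference report publishes no variance components, so the
RE noise default was set by calibration: 3.0 kcal/day centres the
realized per-diet regression R² near 0.9 with a spread (~0.80–0.99)
matching the range of the published fits. A consequence worth knowing:
with only 6 points per diet and the design's MEI/W^0.75 spread
(sd ≈ 22 kcal/kg^0.75), the slope standard error at that noise is
se(k) = σ/√SSx ≈ 0.10, so individual per-diet k estimates scatter well
beyond ±0.05; tight k recovery at this design requires R² ≈ 0.99.
Simulated trials therefore reproduce the *shape* of the reference
tables, not the unusually tight k spread across its diets.

Seeding: a master seed fans out through `SeedSequence(seed,
spawn_key=(diet, level, replicate))`, so identical seeds give
byte-identical outputs and enlarging the design (more replicates or
diets) never perturbs already-generated pens.

What the generator does **not** emulate: temperature and
thermoregulation, sex/genotype effects, mortality, within-pen bird
heterogeneity, curvature of the RE–MEI relationship near and below
maintenance, and diet-by-level interactions. Passing recovery tests
therefore show the estimators are correct under the linear model's own
assumptions, not that real trials satisfy them.

## Problem sizes

The test suite runs the estimators on 6-point per-diet fits; the
Monte-Carlo recovery study uses 200 seeded trials × 6 diets; property
checks of the validation algebra use 1000 randomized vectors of length
3–30; ME-recovery unbiasedness uses 1000 noisy draws. These sizes give
Monte-Carlo errors comfortably below the assertion tolerances.

## Known limitations

* The two-level solve has no replication and hence no standard errors;
  its result object reports NaN for them.
* Nonlinear (logarithmic) heat-production regression, an alternative
  maintenance estimator in the literature, is not implemented.
* No confidence intervals or hypothesis tests accompany the CCC.
* The bundled reference tables carry 2-dp rounding; reproduction checks
  use absolute tolerances of 0.02 kcal/day for arithmetic identities,
  0.05 for model predictions and summary statistics, and 0.1 for the
  metabolic-unit system re-derived from rounded cells.
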