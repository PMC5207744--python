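# Methods

## Model structure

The simulation is an annual-cycle, individual-level (microsimulation)
model of US adults stratified into four race-sex subgroups (white/black
× male/female). One cohort is generated at baseline and followed for 15
years as a closed cohort: no one enters, people leave only by death.
Within a simulated year the update order is fixed: intake → weight →
age → survival draw → accrual. The order affects results at the margin,
so it is frozen rather than configurable.

## Cohort generation

Joint (age, sex, race) is drawn from a demographic-marginals table
(packaged: a synthetic piecewise-uniform age distribution over 18–85
within sex × race cells approximating the 2013 US adult mix; any
`age,sex,race,weight` CSV can replace it). Within each subgroup:

- **BMI** follows the subgroup's published 4-band distribution
  (underweight [15,18.5), normal [18.5,25), overweight [25,30), obese
  [30,60]). The published band masses are rounded percentages and two
  columns sum to 99%/101%; they are stored verbatim and renormalized
  when used as sampling probabilities. Within a band, BMI is truncated
  normal with mean at the band midpoint and sd = width/4, except the
  open-ended obese band (mean 33, sd 4, truncated to [30,60]) to
  reproduce the right skew of adult BMI. Only the band masses are
  externally constrained; the within-band law is a package choice and
  is isolated in one table (`population.BMI_BAND_LAWS`).
- **Height** is truncated normal by sex (male 1.763 ± 0.073 m, female
  1.622 ± 0.068 m, bounds [1.40, 2.10]), approximating US adult
  anthropometry; weight is BMI·height².
- **PAL** (physical activity level, total expenditure ÷ RMR) is uniform
  on [1.4, 1.7] per individual and held constant over the horizon.
- **Meat calorie share** is truncated normal with the subgroup's
  published mean and sd = (CI width)/3.92, i.e. the published 95% CI is
  reused as a between-individual heterogeneity scale. This is an
  interpretation (the CI is strictly an uncertainty on the mean); a
  `fixed` mode pins everyone at the subgroup mean instead. Default:
  sampled.
- **Baseline intake** is inferred from energy balance:
  intake = PAL × RMR(weight, height, age, sex). Every individual
  therefore starts at the fixed point of the weight dynamics, so any
  simulated weight change is attributable to the price shock and the
  secular creep, not to generation artifacts.

BMI is sampled independently of age within subgroup (the joint
age-BMI structure is not published).

## Price response

Own-price elasticities of demand (red meat −0.52, white meat −0.46,
seafood −0.53) translate a uniform fractional price change Δp into a
fractional quantity change e·Δp (linear convention, matching the
standard illustration: e = −0.5 and Δp = +10% give −5%). A log-log
alternative ((1+Δp)^e − 1) is config-selectable; the two agree to first
order and diverge only for the 50% shock. Quantity change is floored at
−1. The split of meat calories across the three subtypes is not
published; the default is equal thirds, and only the split-weighted
mean elasticity (range −0.46..−0.53) enters the result, so the
sensitivity to this choice is small.

The one-time intake change is baseline_intake · meat_share · Σ wₖ·eₖ·Δp,
applied from year 0 onward. An optional complementarity channel adds
baseline_intake · (1 − meat_share) · e_cross · Δp for non-meat calories;
the base case has it off, and the packaged e_cross = −0.1 is a
placeholder magnitude (no published value exists), exposed in config.

Caloric creep adds κ kcal/day per elapsed year (first accruing at
t = 1), scaled by the scenario's creep multiplier. Total intake is
floored at 500 kcal/day to prevent pathological starvation under
extreme configured shocks.

## Weight dynamics

A one-compartment energy-balance ODE with RMR feedback:

    dW/dt = (intake − PAL · RMR(W, H, age, sex)) / ρ,   ρ = 7700 kcal/kg

with Mifflin–St Jeor RMR (10W + 6.25H[cm] − 5·age + {+5 male, −161
female}). Mifflin–St Jeor is used because it depends on exactly the
stated covariates (weight, height, age, sex) and is the standard
clinical choice. Because RMR is linear in W, the model has a
closed-form steady state W* = (I/PAL − 6.25H + 5·age − s)/10, and the
daily explicit-Euler integration over a year (constant coefficients
within the year) collapses to the geometric form
W(m) = W* + (W₀ − W*)·rᵐ with r = 1 − 10·PAL·dt/ρ. This is evaluated
directly — bit-equivalent to the daily loop (checked against an
independent loop oracle in the tests) and O(1) per individual-year,
which is what makes grid-search calibration cheap. Step size dt = 1 day
by default; dt = 0.1 changes one-year results by < 0.05 kg. ρ and dt
are config-exposed for users who prefer other coefficient sets.

**Metabolic age is frozen at baseline.** With Mifflin–St Jeor, letting
age advance inside RMR adds +0.5 kg/year to the steady state at
constant intake (~7.5 kg over the horizon), which would both break the
baseline fixed point and confound the calibrated creep with an aging
artifact. Chronological age still advances for mortality lookup; the
RMR age is the baseline value. Under zero shock and zero creep, every
individual's weight is exactly constant — this invariant is tested.

Simulated BMI is hard-clamped to [12, 70] (with a logged warning); all
band lookups clamp further to [15, 60], the instantiated range.

Weight trajectories are integrated for every individual regardless of
vital status (the BMI path is a deterministic function of the intake
path and mortality does not feed back on weight), so the per-individual
BMI path is identical across scenarios sharing random numbers and
per-individual contrasts are well-defined. Vital status enters only
through accrual and aggregation.

## Mortality and quality of life

Annual death probability is q(age, sex, race) from a life table times a
9-band J-shaped BMI relative risk (reference band 22.5–24.9, RR = 1),
capped at 1: p = min(1, q·RR). A rate-based alternative
(1 − (1−q)^RR, i.e. hazard scaling) is available behind a flag; the
choice is unstated in the source material and matters only where q·RR
approaches 1 (ages ≳ 100). By default the RRs multiply the raw table
directly; an optional `recalibrate_mortality` mode rescales q per
subgroup so the cohort-average adjusted rate at baseline matches the
raw table (naive multiplication otherwise inflates average mortality in
high-BMI subgroups).

The packaged life table is a synthetic Gompertz-style fixture
(h = a·e^{0.09·(age−18)}, with level a ordered male > female and black
> white, terminal age 110 where q = 1 to bound the simulation); any
`age,sex,race,q` CSV of real period rates drops in.

Survivors accrue 1 life-year per year and decedents 0.5 (half-cycle
correction, applied identically in all scenarios); QALYs weight each
accrual by a 3-band EQ-5D utility (bands [15,25), [25,30), [30,60])
specific to subgroup. The year's post-update BMI is used for both the
death draw and the utility.

## Common random numbers

All randomness descends from per-purpose streams:
SeedSequence([seed, tag]) with separate tags for generation, survival,
and calibration. Survival uniforms are drawn once as an (n × horizon)
matrix, so the draw for individual i in year t is fixed regardless of
scenario — scenarios differ only through the price channel, and a
scenario contrasted with itself is exactly zero. An independent-seeds
mode is simply a different seed per scenario if uncertainty
quantification rather than contrast is wanted.

## Calibration

The per-subgroup yearly increment κ is fitted by exhaustive grid search
(default 0–20 kcal/day/yr, step 0.1): for each candidate, the target
window (default 14 years) is simulated at zero price change and the
mean squared error against all (year, threshold) prevalence targets
(BMI > 25, 30, 35, 40, equally weighted) is minimized. Grid search is
used because the objective is a noisy, stepwise function of a scalar —
a grid is exact and reproducible where gradient methods are not. All
candidates share one cohort and one survival-uniform matrix, which
makes the MSE profile smooth in κ and the argmin stable; ties break to
the lower increment with a warning, and a flat profile raises a
non-identifiability warning. Each subgroup is fitted independently.

The packaged targets fixture is self-generated by the model at its
configured increments (real 1999–2012 survey prevalence series are not
redistributable here), with normal-approximation 95% CIs; recovery
tests are therefore self-consistency checks: they show the calibration
machinery can identify a known increment from data the model itself
produced, with recovery error dominated by binomial noise in the
targets (sd ≈ 0.004 at n = 20,000, the same order as one 0.5 kcal grid
step's effect on late-window prevalence — hence the median-over-seeds
acceptance form). Calibration cohorts are instantiated from the target
window's start; if window-specific BMI-band probabilities are not
supplied, the default distribution is used.

## Sensitivity variants

Variants are pure transformations of the parameter set, composed
left-to-right, each re-validated: complementarity_on (sets e_cross),
flat_mortality (all RR = 1), swap_race_rr / swap_race_bmi (black
subgroups adopt sex-matched white values), zero_creep, price_decrease
(negative Δp), meat_share_scaled and elasticity_scaled (magnitudes for
the scaled sweeps default to ±25% in the battery and are package
choices). Smoking-status and disease-prevalence sensitivities are
deliberately not implemented: no parameters for them are published, and
inventing a parameterization would imply a fidelity the model cannot
have. Each variant battery is contrasted against its own
variant-matched status quo.

## Problem sizes and defaults

Base case: n = 100,000 individuals, 15-year horizon, prices {0, 5, 10,
25, 50}%. The test suite and acceptance script run the stochastic
checks at n = 20,000 with 10 seeds and the structural checks at
n = 5,000 — sizes at which the monitored binomial standard errors are
small relative to the effects being checked while the whole suite runs
in well under a minute of simulation time. Calibration recovery uses
grid step 0.5 kcal/day/yr over 0–20.

## What the synthetic fixtures do and do not show

The demographic marginals, life table, and calibration targets shipped
with the package are synthetic. They preserve the structure the model's
conclusions rely on (subgroup ordering of mortality levels, Gompertz
age-gradient, the published BMI-band and meat-share differences) but
not the exact US 2013 levels. Passing tests therefore demonstrate the
model's internal correctness and the qualitative subgroup contrasts
(direction and ordering of effects), not calibrated US point estimates;
for those, supply real Census marginals, CDC life tables, and survey
prevalence series in the documented CSV schemas.

## Known limitations

- Total calories are the only dietary quantity modeled; macronutrient
  composition and substitution toward specific foods are out of scope.
- One-compartment weight dynamics: no fat/lean partitioning, no
  adaptive thermogenesis; PAL constant per individual.
- The BMI-mortality relative risks are taken as causal within the
  model; confounding (smoking, occult disease) is acknowledged but not
  modeled.
- Closed cohort: no 18-year-old entrants, no migration; children are
  excluded by design.
- No discounting of life-years or QALYs; no cost accounting.
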