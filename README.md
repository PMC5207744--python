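# meatshift

A race- and gender-stratified microsimulation of how a change in US meat
prices propagates through caloric intake, body weight, mortality, and
quality of life over a 15-year horizon.

Food-price policies (fat taxes, restrictions on sellers) and exogenous
shocks (climate, feed prices) change what people eat, and hence obesity
and its health consequences — but not uniformly. The burden of obesity,
the share of calories from meat, the BMI–mortality relationship, and the
quality-of-life cost of obesity all differ by race and gender, so a
single population-mean estimate can hide harms concentrated in
subpopulations. This package simulates individual adults (white/black ×
male/female) and reports obesity prevalence, life years, and
quality-adjusted life years (QALYs) per subgroup under meat-price
changes of ±5–50%.

## Model

For each simulated adult *i* with baseline intake *I₀ᵢ* (kcal/day), meat
calorie share *mᵢ*, and physical activity level *PALᵢ*:

- **Price response.** A one-time, permanent price change Δp applied
  uniformly to red meat, white meat, and seafood changes quantity via
  the own-price elasticity of demand: ΔQ/Q = e·Δp (e = −0.52, −0.46,
  −0.53 respectively). The one-time intake change is
  I₀ᵢ·mᵢ·Σₖ wₖ·eₖ·Δp. An optional cross-price (complement) channel
  shifts non-meat calories; the base case assumes no complementarity.
- **Caloric creep.** Each subgroup adds a fixed κ kcal/day every year
  (calibrated: 5.7 / 12.3 / 4.7 / 8.7 for white males / black males /
  white females / black females), so intake at year *t* is
  I₀ᵢ + ΔIᵢ + κ·t, floored at 500 kcal/day.
- **Weight dynamics.** A one-compartment energy-balance ODE,
  dW/dt = (I − PAL·RMR(W))/ρ with ρ = 7700 kcal/kg and Mifflin–St Jeor
  RMR = 10W + 6.25H − 5·age + s (W kg, H cm, s = +5 male / −161
  female), integrated in daily Euler steps (evaluated in closed form).
  Cohorts are generated in energy balance (I₀ = PAL·RMR), so weight
  moves only in response to price and creep.
- **Mortality.** Annual death probability q(age, sex, race) from a life
  table, multiplied by a J-shaped 9-band BMI relative risk (reference
  band 22.5–24.9 kg/m², RR = 1), capped at 1.
- **Quality of life.** Each life-year is weighted by a 3-band EQ-5D
  utility specific to subgroup and BMI; decedents credit half a year
  (half-cycle correction).

Price scenarios share one cohort and common random numbers, so contrasts
against the status quo isolate the price channel. The creep increments
are calibrated per subgroup by grid search, minimizing mean squared
error between simulated and target prevalences of BMI > 25/30/35/40
over a 14-year window.

The packaged demographic marginals and life table are synthetic fixtures
with realistic structure; the CSV schemas accept real Census/CDC exports
as drop-in replacements.

## Worked example

```python
import meatshift as ms
from meatshift.engine import run_scenario, contrast_vs_status_quo, obesity_prevalence

params = ms.default_params()
demo = ms.default_demographics()
lt = ms.default_life_table()

cohort = ms.sample_population(20_000, demo, params, seed=1)
sq  = run_scenario(cohort, ms.Scenario(0.00, seed=1, n_individuals=20_000), params, lt)
r25 = run_scenario(cohort, ms.Scenario(0.25, seed=1, n_individuals=20_000), params, lt)

print(obesity_prevalence(sq, 0, "black_female"))    # 0.556
print(obesity_prevalence(sq, 15, "black_female"))   # 0.716
print(obesity_prevalence(r25, 15, "black_female"))  # 0.591
print(contrast_vs_status_quo(r25, sq).query("stratum == 'all'"))
```

The contrast table (one seed, n = 20,000):

```
    subgroup  price_change stratum    n  delta_obesity_prev  delta_ly_per_1000  delta_qaly_per_1000
  white_male          0.25     all 8331           -0.081               19.3                 38.9
  black_male          0.25     all 1433           -0.169               25.8                 88.3
white_female          0.25     all 8715           -0.054               11.8                 31.5
black_female          0.25     all 1521           -0.125               21.7                118.3
```

Reading it: under a +25% meat price, 2030 obesity prevalence among black
females is 12.5 percentage points lower than it would be under the
status quo (0.591 vs 0.716 — still above the 2015 level of 0.556,
because caloric creep keeps pushing weights up); the subgroup gains
21.7 life-years and 118 QALYs per 1000 people over the 15 years. White
females show the smallest prevalence response (low initial obesity and
the lowest meat share). Stratified rows (`bmi_ge_25` / `bmi_lt_25`) show
that the life-year gains are concentrated in the initially overweight,
while the initially lean lose life-years as they are pushed toward
low-BMI, high-mortality ranges — the mechanism behind the small average
benefit of black males, whose mortality is relatively high at low BMI
and relatively flat at high BMI.

The same battery is available from the shell:

```sh
meatshift simulate --prices 0,0.05,0.10,0.25,0.50 --n 100000 --seed 7 --out results/
meatshift summarize --results results/
meatshift make-fixtures --out fixtures/
meatshift calibrate --targets fixtures/targets.csv --grid 0:20:0.5 --seed 7
meatshift sensitivity --variants flat_mortality,zero_creep --prices 0.25,0.50 --seed 7
```

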