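"""Synthetic cohort generation.

Builds the simulated adult population: joint (age, sex, race) drawn from
demographic marginals, BMI from the published 4-band mixture with a
truncated-normal law within each band, anthropometric height by sex,
a physical activity level (PAL — total energy expenditure divided by
resting metabolic rate), and a per-individual meat calorie share whose
spread reuses the published 95% CI.  Baseline caloric intake is inferred
from energy balance: intake = PAL × RMR, so every individual starts at
the fixed point of the weight dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    BAND4_EDGES,
    Demographics,
    ModelParams,
    RACES,
    SEXES,
    SUBGROUPS,
    subgroup_index,
)
from .weight import rmr

# Stream tags: all randomness descends from SeedSequence([seed, tag]).
STREAM_GENERATION = 1
STREAM_SURVIVAL = 2
STREAM_CALIBRATION = 3

#: Within-band BMI law: truncated normal, mean at the band midpoint and
#: sd = width/4 — except the open-ended obese band [30, 60], where mean 33
#: and sd 4 reproduce the right skew of adult BMI distributions.
BMI_BAND_LAWS = (
    # (lo, hi, mean, sd)
    (15.0, 18.5, 16.75, 0.875),
    (18.5, 25.0, 21.75, 1.625),
    (25.0, 30.0, 27.5, 1.25),
    (30.0, 60.0, 33.0, 4.0),
)

#: Height: truncated normal by sex (meters), approximating US adult
#: anthropometry.
HEIGHT_LAWS = {"male": (1.763, 0.073), "female": (1.622, 0.068)}
HEIGHT_BOUNDS = (1.40, 2.10)

#: Physical activity level: uniform per individual.
PAL_BOUNDS = (1.4, 1.7)

#: Meat-share truncation bounds (fractions of daily calories).
MEAT_SHARE_BOUNDS = (0.01, 0.9)


@dataclass
class Individual:
    """One simulated adult (scalar view; the engine works on arrays)."""

    id: int
    age: int
    sex: str
    race: str
    height: float          # meters
    weight: float          # kg
    pal: float             # total expenditure / RMR, dimensionless
    meat_share: float      # fraction of baseline calories from meats
    baseline_intake: float = 0.0   # kcal/day
    alive: bool = True
    life_years: float = 0.0
    qalys: float = 0.0

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


@dataclass
class Cohort:
    """Array-of-columns container for n simulated individuals."""

    age: np.ndarray          # int, years
    sex: np.ndarray          # int8: 0 male, 1 female
    race: np.ndarray         # int8: 0 white, 1 black
    subgroup: np.ndarray     # int8: index into SUBGROUPS
    height: np.ndarray       # float, m
    weight: np.ndarray       # float, kg (baseline)
    pal: np.ndarray
    meat_share: np.ndarray
    baseline_intake: np.ndarray   # kcal/day
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.age)

    @property
    def bmi(self) -> np.ndarray:
        return self.weight / self.height**2

    def individual(self, i: int) -> Individual:
        return Individual(
            id=i,
            age=int(self.age[i]),
            sex=SEXES[self.sex[i]],
            race=RACES[self.race[i]],
            height=float(self.height[i]),
            weight=float(self.weight[i]),
            pal=float(self.pal[i]),
            meat_share=float(self.meat_share[i]),
            baseline_intake=float(self.baseline_intake[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "age": self.age,
                "sex": np.array(SEXES)[self.sex],
                "race": np.array(RACES)[self.race],
                "height_m": self.height,
                "weight_kg": self.weight,
                "pal": self.pal,
                "meat_share": self.meat_share,
                "baseline_intake_kcal": self.baseline_intake,
            }
        )


def _truncnorm(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_bmi(band_probs, rng, size=None):
    """Draw BMI values from the 4-band mixture.

    ``band_probs`` are renormalized to sum to one (published rounded
    percentages can be off by 1%).  Each draw picks a band, then a value
    from that band's truncated-normal law; returned values always lie in
    the sampled band.
    """
    p = np.asarray(band_probs, dtype=float)
    if len(p) != 4 or np.any(p < 0) or p.sum() <= 0:
        raise ValueError(f"band_probs must be 4 non-negative values, got {p}")
    p = p / p.sum()
    scalar = size is None
    n = 1 if scalar else int(size)
    bands = rng.choice(4, size=n, p=p)
    out = np.empty(n)
    for b, (lo, hi, mean, sd) in enumerate(BMI_BAND_LAWS):
        mask = bands == b
        if mask.any():
            out[mask] = _truncnorm(rng, lo, hi, mean, sd, int(mask.sum()))
    return float(out[0]) if scalar else out


def infer_baseline_intake(individual: Individual) -> float:
    """Baseline daily intake from energy balance: PAL × RMR (kcal/day)."""
    return float(
        individual.pal
        * rmr(individual.weight, individual.height, individual.age, individual.sex)
    )


def sample_population(
    n: int,
    demographics: Demographics,
    params: ModelParams,
    seed: int,
    meat_share_mode: str | None = None,
) -> Cohort:
    """Generate a cohort of ``n`` individuals.

    Reproducible given ``seed``: all draws descend from per-purpose child
    streams of SeedSequence([seed, generation-tag]), so the same seed
    yields bit-identical cohorts.

    ``meat_share_mode`` overrides the parameter file's setting
    ("sampled": per-individual truncated normal with sd = CI width / 3.92;
    "fixed": subgroup mean for everyone).
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    mode = meat_share_mode or params.meat_share_mode
    if mode not in ("sampled", "fixed"):
        raise ValueError(f"unknown meat_share_mode {mode!r}")

    ss = np.random.SeedSequence([int(seed), STREAM_GENERATION])
    r_demo, r_bmi, r_height, r_pal, r_meat = map(np.random.default_rng, ss.spawn(5))

    rows = r_demo.choice(len(demographics.probs), size=n, p=demographics.probs)
    age = demographics.ages[rows]
    sex = demographics.sex_codes[rows]
    race = demographics.race_codes[rows]
    sg = subgroup_index(race.astype(int), sex.astype(int)).astype(np.int8)

    bmi = np.empty(n)
    meat = np.empty(n)
    for gi, key in enumerate(SUBGROUPS):
        sp = params.subgroups[key]
        mask = sg == gi
        m = int(mask.sum())
        if m == 0:
            continue
        bmi[mask] = sample_bmi(sp.bmi_band_probs, r_bmi, size=m)
        if mode == "fixed":
            meat[mask] = sp.meat_share_mean
        else:
            lo_ci, hi_ci = sp.meat_share_ci
            sd = (hi_ci - lo_ci) / 3.92   # 95% CI width → 1 sd
            meat[mask] = _truncnorm(
                r_meat, *MEAT_SHARE_BOUNDS, sp.meat_share_mean, sd, m
            )

    height = np.empty(n)
    for s, sex_name in enumerate(SEXES):
        mask = sex == s
        if mask.any():
            mean, sd = HEIGHT_LAWS[sex_name]
            height[mask] = _truncnorm(r_height, *HEIGHT_BOUNDS, mean, sd, int(mask.sum()))

    pal = r_pal.uniform(*PAL_BOUNDS, size=n)
    weight = bmi * height**2
    baseline_intake = pal * rmr(weight, height, age, sex)

    return Cohort(
        age=age.astype(int),
        sex=sex,
        race=race,
        subgroup=sg,
        height=height,
        weight=weight,
        pal=pal,
        meat_share=meat,
        baseline_intake=baseline_intake,
        seed=int(seed),
    )
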