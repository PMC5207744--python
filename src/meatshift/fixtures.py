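"""Synthetic input fixtures: demographics, life table, calibration targets.

These stand in for the real Census marginals, CDC life tables and NHANES
prevalence series, which are not redistributable here; all three writers
emit the same CSV schemas that real exports can use.  Every fixture is
labelled synthetic in its header comment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import run_scenario
from .params import (
    Demographics,
    LifeTable,
    MIN_ADULT_AGE,
    ModelParams,
    RACES,
    SEXES,
    Scenario,
    SUBGROUPS,
    TERMINAL_AGE,
    default_params,
)
from .population import sample_population

logger = logging.getLogger(__name__)

# -- demographics ------------------------------------------------------------

#: Share of the two-race adult population by race (white, black) and of
#: each race by sex (male, female); rough 2013-US-adult proportions.
RACE_SHARES = {"white": 0.85, "black": 0.15}
SEX_SHARES = {"male": 0.49, "female": 0.51}

#: Piecewise-uniform age bands (lo, hi inclusive, mass).
AGE_BANDS = ((18, 24, 0.13), (25, 44, 0.35), (45, 64, 0.34), (65, 85, 0.18))


def make_demographics() -> pd.DataFrame:
    """Piecewise-uniform age × sex × race marginals (synthetic)."""
    rows = []
    for race, rw in RACE_SHARES.items():
        for sex, sw in SEX_SHARES.items():
            for lo, hi, mass in AGE_BANDS:
                per_age = rw * sw * mass / (hi - lo + 1)
                for age in range(lo, hi + 1):
                    rows.append((age, sex, race, per_age))
    return pd.DataFrame(rows, columns=["age", "sex", "race", "weight"])


# -- life table --------------------------------------------------------------

#: Gompertz hazard h(age) = a · exp(b·(age − 18)) with subgroup-level a:
#: males above females, black above white — mirroring the ordering (not
#: the exact values) of US period life tables.
GOMPERTZ_A = {
    ("male", "white"): 2.8e-4,
    ("male", "black"): 4.4e-4,
    ("female", "white"): 1.6e-4,
    ("female", "black"): 2.6e-4,
}
GOMPERTZ_B = 0.09


def make_life_table() -> pd.DataFrame:
    """Synthetic Gompertz-style life table, q = 1 at the terminal age."""
    rows = []
    ages = np.arange(MIN_ADULT_AGE, TERMINAL_AGE + 1)
    for sex in SEXES:
        for race in RACES:
            a = GOMPERTZ_A[(sex, race)]
            h = a * np.exp(GOMPERTZ_B * (ages - MIN_ADULT_AGE))
            q = 1.0 - np.exp(-h)
            q[-1] = 1.0
            for age, qi in zip(ages, q):
                rows.append((int(age), sex, race, float(np.round(qi, 8))))
    return pd.DataFrame(rows, columns=["age", "sex", "race", "q"])


# -- calibration targets -----------------------------------------------------


def make_targets(
    params: ModelParams,
    demographics: Demographics,
    life_table: LifeTable,
    seed: int = 0,
    n: int = 20_000,
    start_year: int = 1999,
    end_year: int = 2012,
    subgroups=SUBGROUPS,
) -> tuple[pd.DataFrame, dict]:
    """Self-simulated prevalence targets for calibration recovery tests.

    Simulates each subgroup at zero price change under its configured
    yearly increment and records prevalence of BMI ≥ 25/30/35/40 with
    normal-approximation 95% CIs.  The returned meta records the
    generating increments so recovery tests can check themselves.
    """
    horizon = end_year - start_year
    rows = []
    for g, key in enumerate(SUBGROUPS):
        if key not in subgroups:
            continue
        race, sex = key.split("_")
        demo_g = demographics.restrict(race, sex)
        cohort = sample_population(n, demo_g, params, seed=seed + g)
        scenario = Scenario(
            price_change=0.0, horizon_years=horizon, n_individuals=n, seed=seed + g
        )
        res = run_scenario(cohort, scenario, params, life_table)
        for t in range(horizon + 1):
            rec = res.table[(res.table.year == t) & (res.table.subgroup == key)]
            living = int(rec["living"].iloc[0])
            for thr in (25, 30, 35, 40):
                p = float(rec[f"thr{thr}"].iloc[0])
                se = np.sqrt(max(p * (1 - p), 1e-12) / max(living, 1))
                rows.append(
                    {
                        "year": start_year + t,
                        "subgroup": key,
                        "threshold": float(thr),
                        "prevalence": round(p, 6),
                        "ci_low": round(max(0.0, p - 1.96 * se), 6),
                        "ci_high": round(min(1.0, p + 1.96 * se), 6),
                    }
                )
    meta = {
        "synthetic": "self-simulated calibration targets",
        "start_year": str(start_year),
        "n": str(n),
        "seed": str(seed),
        "generating_increments": " ".join(
            f"{key}={params.subgroups[key].yearly_kcal_increase}" for key in SUBGROUPS
        ),
    }
    return pd.DataFrame(rows), meta


def write_fixtures(out_dir, seed: int = 0, params: ModelParams | None = None,
                   targets_n: int = 20_000) -> dict[str, Path]:
    """Write demographics.csv, lifetable.csv and targets.csv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or default_params()

    demo_df = make_demographics()
    demo_path = out / "demographics.csv"
    with open(demo_path, "w") as fh:
        fh.write("# synthetic piecewise-uniform age x sex x race marginals\n")
        demo_df.to_csv(fh, index=False)

    lt_df = make_life_table()
    lt_path = out / "lifetable.csv"
    with open(lt_path, "w") as fh:
        fh.write("# synthetic Gompertz-style life table (not CDC data)\n")
        lt_df.to_csv(fh, index=False)

    demographics = Demographics(demo_df)
    life_table = LifeTable.from_csv(lt_path)
    targets_df, meta = make_targets(params, demographics, life_table, seed=seed, n=targets_n)
    targets_path = out / "targets.csv"
    with open(targets_path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        targets_df.to_csv(fh, index=False)

    logger.info("wrote fixtures to %s", out)
    return {"demographics": demo_path, "lifetable": lt_path, "targets": targets_path}
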