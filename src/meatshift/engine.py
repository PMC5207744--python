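"""Annual-cycle simulation engine and scenario contrasts.

Runs the yearly loop over the horizon for one scenario: update intake
(price shock + creep, floored), integrate weight over the year, advance
age, draw survival against the BMI-adjusted death probability, and accrue
life-years and QALYs (half-cycle correction for decedents).

Scenarios intended for contrast share common random numbers: survival
uniforms are a (n × horizon) matrix drawn once from a dedicated stream
keyed by the scenario seed, so that an individual-year's draw is
identical across scenarios and contrasts isolate the price channel.

Update order within a year is fixed: intake → weight → age → death →
accrual.  The BMI used for a year's mortality and utility is the
post-update value.  Prevalences are computed among the living.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .mortality import MortalityModel, bmi_band3, bmi_band4
from .params import (
    LifeTable,
    ModelParams,
    Scenario,
    SUBGROUPS,
    params_to_dict,
)
from .population import Cohort, STREAM_SURVIVAL
from .pricing import (
    complementarity_delta,
    floored_intake,
    meat_calorie_delta,
)
from .weight import EnergyModelConfig, clamp_bmi, update_weight

logger = logging.getLogger(__name__)

#: Thresholds tracked for calibration (prevalence of BMI ≥ threshold).
CALIBRATION_THRESHOLDS = (25.0, 30.0, 35.0, 40.0)

BAND_COLUMNS = ("underweight", "normal", "overweight", "obese")


@dataclass
class TrajectoryResult:
    """Per-year, per-subgroup outcome panel plus per-individual totals."""

    table: pd.DataFrame
    life_years: np.ndarray      # per individual, accrued over the horizon
    qalys: np.ndarray
    final_bmi: np.ndarray       # BMI at the last simulated year (clamped)
    final_alive: np.ndarray
    yearly_bmi: np.ndarray      # (n × horizon+1) BMI trace incl. baseline
    cohort: Cohort
    scenario: Scenario
    meta: dict = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return self.scenario.horizon_years


def survival_uniforms(seed: int, n: int, horizon: int) -> np.ndarray:
    """Per-individual-per-year uniforms from a dedicated survival stream.

    Drawing the full matrix up front keys every draw by (individual, year)
    independently of who is alive, which is what makes common random
    numbers work across scenarios.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), STREAM_SURVIVAL]))
    return rng.random((n, horizon))


def _config_hash(scenario: Scenario, params: ModelParams) -> str:
    doc = {"scenario": scenario.__dict__, "params": params_to_dict(params)}
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _scenario_rr_matrix(scenario: Scenario, params: ModelParams) -> np.ndarray:
    rr = params.rr_matrix().copy()
    if scenario.swap_race_rr:
        # black subgroups adopt the sex-matched white RR columns
        rr[1] = rr[0]   # black_male <- white_male
        rr[3] = rr[2]   # black_female <- white_female
    return rr


def run_scenario(
    cohort: Cohort,
    scenario: Scenario,
    params: ModelParams,
    life_table: LifeTable,
    energy: EnergyModelConfig = EnergyModelConfig(),
) -> TrajectoryResult:
    """Simulate one scenario over its horizon on a shared cohort.

    The cohort is treated as read-only, so the same cohort object can be
    reused across scenarios (common random numbers).  Identical (cohort,
    scenario) inputs produce bit-identical results.

    Note ``scenario.swap_race_bmi`` acts at cohort generation and is
    ignored here; use :func:`meatshift.variants.apply_variant` (or
    :func:`simulate_scenario`) so the cohort is built from the swapped
    distribution.
    """
    scenario.validate()
    params.validate()
    n = cohort.n
    horizon = scenario.horizon_years

    model = MortalityModel(
        life_table=life_table,
        rr_matrix=_scenario_rr_matrix(scenario, params),
        flat_curve=scenario.flat_mortality_curve,
        rate_based=scenario.rate_based_rr,
        recalibrate=scenario.recalibrate_mortality,
    )
    base_bmi, _ = clamp_bmi(cohort.weight, cohort.height)
    model.calibrate_baseline(cohort.age, cohort.sex, cohort.race, cohort.subgroup, base_bmi)

    one_time = meat_calorie_delta(
        cohort.baseline_intake,
        cohort.meat_share,
        params.elasticities,
        scenario.price_change,
        params.subtype_split,
        params.elasticity_form,
    ) + complementarity_delta(
        cohort.baseline_intake,
        cohort.meat_share,
        params.elasticities.cross,
        scenario.price_change,
        enabled=scenario.complementarity,
    )
    yearly = params.increments()[cohort.subgroup] * scenario.creep_multiplier

    uniforms = survival_uniforms(scenario.seed, n, horizon)

    weight = cohort.weight.copy()
    alive = np.ones(n, dtype=bool)
    life_years = np.zeros(n)
    qalys = np.zeros(n)
    util_matrix = params.utility_matrix()
    yearly_bmi = np.empty((n, horizon + 1))
    yearly_bmi[:, 0] = base_bmi
    n_clamped_total = 0

    records = []

    def record(t, bmi, alive_now, deaths_mask, intake):
        for g, key in enumerate(SUBGROUPS):
            in_g = cohort.subgroup == g
            living_mask = in_g & alive_now
            living = int(living_mask.sum())
            bands = np.zeros(4, dtype=int)
            if living:
                bands = np.bincount(bmi_band4(bmi[living_mask]), minlength=4)
            row = {
                "year": t,
                "subgroup": key,
                "living": living,
                "deaths": int((in_g & deaths_mask).sum()),
                **dict(zip(BAND_COLUMNS, bands.tolist())),
                "cum_life_years": float(life_years[in_g].sum()),
                "cum_qalys": float(qalys[in_g].sum()),
                "mean_bmi": float(bmi[living_mask].mean()) if living else np.nan,
                "mean_intake": float(intake[living_mask].mean()) if living else np.nan,
            }
            for thr in CALIBRATION_THRESHOLDS:
                row[f"thr{int(thr)}"] = (
                    float((bmi[living_mask] >= thr).mean()) if living else np.nan
                )
            records.append(row)

    intake0 = floored_intake(cohort.baseline_intake, one_time)
    record(0, base_bmi, alive, np.zeros(n, dtype=bool), intake0)

    for t in range(1, horizon + 1):
        intake = floored_intake(cohort.baseline_intake, one_time + yearly * t)
        # Weight is integrated for everyone, dead or alive: the BMI path is
        # a deterministic function of the intake path, so this keeps it
        # identical across scenarios sharing random numbers (per-individual
        # contrasts stay well-defined).  Vital status enters only through
        # accrual and aggregation.  Metabolic age is frozen at baseline so
        # energy balance is exact and all secular weight change is
        # attributable to creep + price.
        weight = update_weight(
            weight,
            intake,
            cohort.pal,
            cohort.height,
            cohort.age,
            cohort.sex,
            duration_years=1.0,
            config=energy,
        )
        bmi, n_clamped = clamp_bmi(weight, cohort.height)
        if n_clamped:
            n_clamped_total += n_clamped
            weight = bmi * cohort.height**2
        yearly_bmi[:, t] = bmi

        age_t = cohort.age + t
        p = model.annual_death_prob(age_t, cohort.sex, cohort.race, cohort.subgroup, bmi)
        dies = alive & (uniforms[:, t - 1] < p)

        util = util_matrix[cohort.subgroup, bmi_band3(bmi)]
        person_time = np.where(dies, 0.5, 1.0) * alive
        life_years += person_time
        qalys += person_time * util
        alive = alive & ~dies

        record(t, bmi, alive, dies, intake)

    if n_clamped_total:
        logger.warning(
            "clamped %d individual-year BMI values to [%.0f, %.0f]",
            n_clamped_total, 12, 70,
        )

    table = pd.DataFrame.from_records(records)
    meta = {
        "price_change": scenario.price_change,
        "seed": scenario.seed,
        "n": n,
        "horizon_years": horizon,
        "version": _pkg_version,
        "config_hash": _config_hash(scenario, params),
    }
    return TrajectoryResult(
        table=table,
        life_years=life_years,
        qalys=qalys,
        final_bmi=yearly_bmi[:, -1],
        final_alive=alive,
        yearly_bmi=yearly_bmi,
        cohort=cohort,
        scenario=scenario,
        meta=meta,
    )


def obesity_prevalence(
    result: TrajectoryResult, t: int, subgroup: str, denominator: str = "living"
) -> float:
    """Fraction of subgroup members with BMI in [30, 60] at year t.

    ``denominator="living"`` (default) divides by survivors at year t;
    ``"initial"`` divides by the subgroup's starting size, counting the
    dead as non-obese.
    """
    row = result.table[(result.table.year == t) & (result.table.subgroup == subgroup)]
    if row.empty:
        raise ValueError(f"no record for year {t}, subgroup {subgroup}")
    if denominator == "initial":
        start = result.table[
            (result.table.year == 0) & (result.table.subgroup == subgroup)
        ]
        denom = int(start["living"].iloc[0])
    elif denominator == "living":
        denom = int(row["living"].iloc[0])
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        logger.warning("obesity prevalence undefined: subgroup %s empty at year %d", subgroup, t)
        return np.nan
    return float(row["obese"].iloc[0]) / denom


STRATA = ("all", "bmi_ge_25", "bmi_lt_25")


def contrast_vs_status_quo(
    result_s: TrajectoryResult, result_sq: TrajectoryResult
) -> pd.DataFrame:
    """Per-subgroup scenario-minus-status-quo deltas at the final year.

    Returns one row per subgroup × baseline-BMI stratum with the change in
    final-year obesity prevalence (among the living), and life-years and
    QALYs per 1000 people over the horizon.  Both results must share the
    cohort, seed, n and horizon — the contrast is only meaningful under
    common random numbers.
    """
    for attr in ("seed", "n_individuals", "horizon_years"):
        if getattr(result_s.scenario, attr) != getattr(result_sq.scenario, attr):
            raise ValueError(f"contrast invalid: scenarios differ in {attr}")
    if result_s.cohort is not result_sq.cohort and result_s.cohort.seed != result_sq.cohort.seed:
        raise ValueError("contrast invalid: results come from different cohorts")

    cohort = result_s.cohort
    base_bmi = cohort.bmi
    rows = []
    for g, key in enumerate(SUBGROUPS):
        in_g = cohort.subgroup == g
        for stratum in STRATA:
            if stratum == "all":
                mask = in_g
            elif stratum == "bmi_ge_25":
                mask = in_g & (base_bmi >= 25.0)
            else:
                mask = in_g & (base_bmi < 25.0)
            m = int(mask.sum())
            if m == 0:
                continue

            def prev(res):
                living = mask & res.final_alive
                if not living.any():
                    return np.nan
                return float((res.final_bmi[living] >= 30.0).mean())

            rows.append(
                {
                    "subgroup": key,
                    "price_change": result_s.scenario.price_change,
                    "stratum": stratum,
                    "n": m,
                    "delta_obesity_prev": prev(result_s) - prev(result_sq),
                    "delta_ly_per_1000": (
                        result_s.life_years[mask].sum() - result_sq.life_years[mask].sum()
                    )
                    / m
                    * 1000.0,
                    "delta_qaly_per_1000": (
                        result_s.qalys[mask].sum() - result_sq.qalys[mask].sum()
                    )
                    / m
                    * 1000.0,
                }
            )
    return pd.DataFrame(rows)
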