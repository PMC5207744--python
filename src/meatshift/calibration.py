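"""Calibration of the secular caloric increase ("caloric creep").

Each race-sex subgroup is assumed to add a fixed number of daily calories
every year.  The increment is fitted, independently per subgroup, so that
status-quo simulated prevalences of BMI > 25, 30, 35 and 40 kg/m² best
match historical target trajectories by mean squared error over all
(year, threshold) target points.  The fit is an exhaustive grid search:
the objective is a noisy step-ish function of one scalar, so a grid is
exact, reproducible and cheap.

All candidate simulations within one fit share a cohort and survival
draws (common random numbers), which makes the MSE profile smooth in the
candidate increment and the argmin stable.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_scenario
from .params import (
    Demographics,
    LifeTable,
    ModelParams,
    ParameterError,
    Scenario,
    SUBGROUPS,
)
from .population import STREAM_CALIBRATION, sample_population

logger = logging.getLogger(__name__)

VALID_THRESHOLDS = (25.0, 30.0, 35.0, 40.0)

#: Candidate increments whose MSEs all lie within this of each other
#: trigger a non-identifiability warning (prevalence-fraction² units).
FLAT_PROFILE_TOL = 1e-8


@dataclass
class CalibrationTargets:
    """Historical prevalence targets: (year, subgroup, threshold) points.

    ``start_year`` anchors simulation time: t = year − start_year.  The
    optional ``meta`` carries fixture provenance (e.g. the increments that
    generated self-simulated targets) parsed from ``# key: value`` header
    comments.
    """

    df: pd.DataFrame
    start_year: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"year", "subgroup", "threshold", "prevalence"}
        if not required.issubset(self.df.columns):
            raise ParameterError(f"targets need columns {sorted(required)}")
        bad = ~self.df["threshold"].isin(VALID_THRESHOLDS)
        if bad.any():
            raise ParameterError(
                f"targets contain unsupported thresholds: "
                f"{sorted(self.df.loc[bad, 'threshold'].unique())}"
            )
        p = self.df["prevalence"]
        if ((p < 0) | (p > 1)).any():
            raise ParameterError("target prevalences must lie in [0, 1]")
        if self.has_cis:
            lo, hi = self.df["ci_low"], self.df["ci_high"]
            if ((lo > p) | (hi < p)).any():
                raise ParameterError("target CI must bracket the prevalence")
        for key, sub in self.df.groupby("subgroup"):
            if sub["year"].nunique() < 2:
                raise ParameterError(f"targets for {key} span fewer than 2 years")

    @property
    def has_cis(self) -> bool:
        return {"ci_low", "ci_high"}.issubset(self.df.columns) and not (
            self.df[["ci_low", "ci_high"]].isna().any().any()
        )

    def for_subgroup(self, key: str) -> pd.DataFrame:
        return self.df[self.df.subgroup == key]

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    meta[k.strip()] = v.strip()
        df = pd.read_csv(path, comment="#")
        start_year = int(meta.get("start_year", df["year"].min()))
        return cls(df=df, start_year=start_year, meta=meta)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            self.df.to_csv(fh, index=False)


@dataclass
class CalibrationResult:
    """Grid-search outcome for one subgroup."""

    subgroup: str
    increment: float            # fitted kcal/day per year
    mse: float
    grid: np.ndarray
    mse_profile: np.ndarray
    residuals: pd.DataFrame     # per target point: simulated − target

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({"increment": self.grid, "mse": self.mse_profile})


def mse(simulated: pd.Series | np.ndarray, targets: pd.Series | np.ndarray) -> float:
    """Mean squared error over target points, prevalence-fraction units."""
    s = np.asarray(simulated, dtype=float)
    t = np.asarray(targets, dtype=float)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: simulated {s.shape} vs targets {t.shape}")
    if np.any(np.isnan(s)):
        raise ValueError("simulated series has missing values for some target points")
    return float(np.mean((s - t) ** 2))


def check_fit_coverage(simulated, targets: CalibrationTargets, subgroup: str | None = None) -> float:
    """Fraction of target 95% CIs containing the simulated value."""
    if not targets.has_cis:
        raise ValueError(
            "targets carry no confidence intervals; report point MSE instead"
        )
    df = targets.df if subgroup is None else targets.for_subgroup(subgroup)
    s = np.asarray(simulated, dtype=float)
    if s.shape != (len(df),):
        raise ValueError(f"need one simulated value per target point ({len(df)})")
    inside = (df["ci_low"].to_numpy() <= s) & (s <= df["ci_high"].to_numpy())
    return float(inside.mean())


def simulated_prevalences(
    result_table: pd.DataFrame, sub_targets: pd.DataFrame, start_year: int, subgroup: str
) -> np.ndarray:
    """Extract the simulated counterpart of each target point.

    Raises if any (year, threshold) point has no simulated value.
    """
    out = np.empty(len(sub_targets))
    for i, row in enumerate(sub_targets.itertuples()):
        t = int(row.year) - start_year
        rec = result_table[
            (result_table.year == t) & (result_table.subgroup == subgroup)
        ]
        if rec.empty:
            raise ValueError(
                f"no simulated counterpart for target point "
                f"(year={row.year}, threshold={row.threshold})"
            )
        out[i] = rec[f"thr{int(row.threshold)}"].iloc[0]
    return out


def _grid(search) -> np.ndarray:
    lo, hi, step = search
    if lo < 0:
        raise ValueError(f"grid lower bound must be >= 0, got {lo}")
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def calibrate_increment(
    targets: CalibrationTargets,
    params: ModelParams,
    demographics: Demographics,
    life_table: LifeTable,
    search=(0.0, 20.0, 0.1),
    seed: int = 0,
    n: int = 20_000,
    subgroups=SUBGROUPS,
) -> dict[str, CalibrationResult]:
    """Grid-search the yearly kcal increment per subgroup.

    For each subgroup, a cohort of ``n`` members is generated once and the
    target window is simulated under each candidate increment at zero
    price change; the returned increment minimizes MSE over all target
    points (ties break toward the lower increment).  Deterministic given
    ``seed``.
    """
    grid = _grid(search)
    results: dict[str, CalibrationResult] = {}
    for g, key in enumerate(SUBGROUPS):
        if key not in subgroups:
            continue
        sub_targets = targets.for_subgroup(key)
        if sub_targets.empty:
            logger.warning("no targets for subgroup %s; skipping", key)
            continue
        race, sex = key.split("_")
        demo_g = demographics.restrict(race, sex)
        horizon = int(sub_targets["year"].max()) - targets.start_year
        sub_seed = int(
            np.random.SeedSequence([int(seed), STREAM_CALIBRATION, g]).generate_state(1)[0]
            % (2**31)
        )
        cohort = sample_population(n, demo_g, params, seed=sub_seed)

        profile = np.empty(len(grid))
        best = None
        for ci, cand in enumerate(grid):
            cand_params = dataclasses.replace(
                params,
                subgroups={
                    **params.subgroups,
                    key: dataclasses.replace(
                        params.subgroups[key], yearly_kcal_increase=float(cand)
                    ),
                },
            )
            scenario = Scenario(
                price_change=0.0,
                horizon_years=horizon,
                n_individuals=n,
                seed=sub_seed,
            )
            res = run_scenario(cohort, scenario, cand_params, life_table)
            sim = simulated_prevalences(res.table, sub_targets, targets.start_year, key)
            profile[ci] = mse(sim, sub_targets["prevalence"].to_numpy())
            if best is None or profile[ci] < best[1]:
                best = (ci, profile[ci], sim)

        n_tied = int(np.sum(profile <= profile.min() + FLAT_PROFILE_TOL))
        if n_tied == len(grid):
            warnings.warn(
                f"calibration for {key}: MSE profile is flat across the grid "
                "(increment not identifiable from these targets)",
                stacklevel=2,
            )
        elif n_tied > 1:
            warnings.warn(
                f"calibration for {key}: {n_tied} candidate increments tie in "
                "MSE; returning the lowest",
                stacklevel=2,
            )
        ci, best_mse, best_sim = best
        residuals = sub_targets[["year", "threshold", "prevalence"]].copy()
        residuals["simulated"] = best_sim
        residuals["residual"] = best_sim - sub_targets["prevalence"].to_numpy()
        results[key] = CalibrationResult(
            subgroup=key,
            increment=float(grid[ci]),
            mse=best_mse,
            grid=grid,
            mse_profile=profile,
            residuals=residuals,
        )
        logger.info("calibrated %s: increment %.2f kcal/yr (MSE %.3e)", key, grid[ci], best_mse)
    return results
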