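"""Model parameters: loading, validation, and lookup structures.

The model is stratified into four race-sex subgroups (white/black ×
male/female).  Each subgroup carries an initial BMI-band distribution,
the mean fraction of daily calories obtained from meats (with a 95% CI
used as a heterogeneity scale), EQ-5D utility values by BMI band,
relative risks of death by BMI band (J-shaped, reference band
22.5-24.9 kg/m²), and a calibrated secular increase in daily caloric
intake.  Own-price elasticities of demand for red meat, white meat and
seafood are shared across subgroups.

File formats are deliberately plain (one YAML document for parameters,
CSV for life tables and demographic marginals) so that users can drop
in real CDC / Census exports with the same schemas.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Stratification constants
# ---------------------------------------------------------------------------

SEXES = ("male", "female")
RACES = ("white", "black")
#: Subgroup order used throughout (matches index = 2*sex_code + race_code
#: with male=0/female=1, white=0/black=1).
SUBGROUPS = ("white_male", "black_male", "white_female", "black_female")

#: 4-band BMI partition used for prevalence reporting:
#: underweight, normal, overweight, obese.  Closed-open except the last
#: band which is closed at 60.
BAND4_EDGES = np.array([15.0, 18.5, 25.0, 30.0, 60.0])
#: 3-band partition for EQ-5D utilities.
BAND3_EDGES = np.array([15.0, 25.0, 30.0, 60.0])
#: 9-band partition for mortality relative risks.
BAND9_EDGES = np.array([15.0, 18.5, 20.0, 22.5, 25.0, 27.5, 30.0, 35.0, 40.0, 60.0])

#: Index of the RR reference band [22.5, 25.0) within BAND9_EDGES.
RR_REFERENCE_BAND = 3

#: Terminal age of the life table; annual death probability is 1 there,
#: which bounds the simulation without immortals.
TERMINAL_AGE = 110
MIN_ADULT_AGE = 18

#: Rounding slack accepted for a printed-percentage probability vector;
#: columns transcribed from rounded percent tables can sum to 99-101%.
BAND_PROB_SUM_TOL = 0.02


class ParameterError(ValueError):
    """A parameter file failed validation; the message names the field."""


def subgroup_key(race: str, sex: str) -> str:
    return f"{race}_{sex}"


def subgroup_index(race_code: int, sex_code: int) -> int:
    """Map (race, sex) integer codes to the subgroup index 0..3."""
    return 2 * sex_code + race_code


def sex_code(sex: str) -> int:
    return SEXES.index(sex)


def race_code(race: str) -> int:
    return RACES.index(race)


def band_index(bmi, edges: np.ndarray):
    """Band index for BMI value(s) against a band-edge vector.

    Values are clamped to the partition's support before lookup; bands are
    closed-open except the last, which is closed at the upper edge.
    """
    clamped = np.clip(bmi, edges[0], edges[-1] - 1e-12)
    return np.searchsorted(edges[1:-1], clamped, side="right")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubgroupParams:
    """Parameter block for one race-sex subgroup."""

    race: str
    sex: str
    #: Probabilities of the four reporting BMI bands at baseline, stored
    #: exactly as published (rounded percentages may sum to 0.99-1.01);
    #: renormalized when used as a sampling distribution.
    bmi_band_probs: tuple[float, float, float, float]
    #: Mean fraction of daily calories from meats (red + white + seafood).
    meat_share_mean: float
    #: 95% CI for the meat calorie share, reused as a between-individual
    #: heterogeneity scale.
    meat_share_ci: tuple[float, float]
    #: EQ-5D utility by 3-band BMI partition.
    utilities: tuple[float, float, float]
    #: Relative risk of death by 9-band BMI partition; band [22.5,25) is
    #: the reference with RR = 1.
    rr_by_band: tuple[float, ...]
    #: Calibrated secular increase in daily caloric intake, kcal/day added
    #: per elapsed calendar year.
    yearly_kcal_increase: float

    @property
    def key(self) -> str:
        return subgroup_key(self.race, self.sex)

    def band_probs_normalized(self) -> np.ndarray:
        p = np.asarray(self.bmi_band_probs, dtype=float)
        return p / p.sum()

    def validate(self) -> None:
        key = self.key
        p = np.asarray(self.bmi_band_probs, dtype=float)
        if len(p) != 4 or np.any(p < 0):
            raise ParameterError(f"{key}.bmi_band_probs: need 4 non-negative values, got {p}")
        if abs(p.sum() - 1.0) > BAND_PROB_SUM_TOL:
            raise ParameterError(
                f"{key}.bmi_band_probs: sum {p.sum():.4f} not within "
                f"{BAND_PROB_SUM_TOL} of 1"
            )
        if not (0.0 < self.meat_share_mean < 1.0):
            raise ParameterError(f"{key}.meat_share.mean: {self.meat_share_mean} not in (0,1)")
        lo, hi = self.meat_share_ci
        if not (lo <= self.meat_share_mean <= hi):
            raise ParameterError(
                f"{key}.meat_share ci ({lo}, {hi}) does not bracket mean {self.meat_share_mean}"
            )
        if len(self.utilities) != 3 or any(not (0.0 < u <= 1.0) for u in self.utilities):
            raise ParameterError(f"{key}.utilities: need 3 values in (0,1], got {self.utilities}")
        rr = np.asarray(self.rr_by_band, dtype=float)
        if len(rr) != 9 or np.any(rr < 0):
            raise ParameterError(f"{key}.rr_by_band: need 9 non-negative values, got {rr}")
        if rr[RR_REFERENCE_BAND] != 1.0:
            raise ParameterError(
                f"{key}.rr_by_band: reference band [22.5,25.0) RR is "
                f"{rr[RR_REFERENCE_BAND]}, must be exactly 1.0"
            )
        if self.yearly_kcal_increase < 0:
            raise ParameterError(
                f"{key}.yearly_kcal_increase: {self.yearly_kcal_increase} < 0"
            )


@dataclass(frozen=True)
class Elasticities:
    """Own-price elasticities of demand for the three meat subtypes.

    ``cross`` is a single aggregate cross-price elasticity of non-meat
    calories with respect to meat price; the base case assumes no
    complementarity (cross = 0 effectively, since the complementarity
    channel is off by default).
    """

    red: float = -0.52
    white: float = -0.46
    seafood: float = -0.53
    cross: float = 0.0

    def validate(self) -> None:
        for name in ("red", "white", "seafood"):
            v = getattr(self, name)
            if v > 0:
                raise ParameterError(f"elasticities.{name}: own-price elasticity {v} > 0")

    def own(self) -> np.ndarray:
        return np.array([self.red, self.white, self.seafood])


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set: four subgroup blocks plus elasticities."""

    subgroups: Mapping[str, SubgroupParams]
    elasticities: Elasticities
    #: Split of meat calories between red meat, white meat, seafood (not
    #: published; default equal thirds — only the split-weighted mean
    #: elasticity matters downstream).
    subtype_split: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: "linear" (ΔQ/Q = e·ΔP/P) or "loglog" ((1+ΔP/P)^e − 1).
    elasticity_form: str = "linear"
    #: "sampled" draws each individual's meat share from the CI-derived
    #: spread; "fixed" pins it at the subgroup mean.
    meat_share_mode: str = "sampled"

    def validate(self) -> None:
        missing = [k for k in SUBGROUPS if k not in self.subgroups]
        if missing:
            raise ParameterError(f"missing subgroup block(s): {', '.join(missing)}")
        for sp in self.subgroups.values():
            sp.validate()
        self.elasticities.validate()
        split = np.asarray(self.subtype_split, dtype=float)
        if len(split) != 3 or abs(split.sum() - 1.0) > 1e-9:
            raise ParameterError(f"subtype_split must be 3 fractions summing to 1, got {split}")
        if self.elasticity_form not in ("linear", "loglog"):
            raise ParameterError(f"elasticity_form: unknown form {self.elasticity_form!r}")
        if self.meat_share_mode not in ("sampled", "fixed"):
            raise ParameterError(f"meat_share_mode: unknown mode {self.meat_share_mode!r}")

    def subgroup(self, race: str, sex: str) -> SubgroupParams:
        return self.subgroups[subgroup_key(race, sex)]

    def ordered(self) -> list[SubgroupParams]:
        return [self.subgroups[k] for k in SUBGROUPS]

    # -- dense lookup arrays for the vectorized engine --

    def rr_matrix(self) -> np.ndarray:
        """(4 subgroups × 9 bands) relative-risk matrix."""
        return np.array([sp.rr_by_band for sp in self.ordered()])

    def utility_matrix(self) -> np.ndarray:
        """(4 subgroups × 3 bands) EQ-5D utility matrix."""
        return np.array([sp.utilities for sp in self.ordered()])

    def increments(self) -> np.ndarray:
        """Per-subgroup yearly kcal/day increments in subgroup order."""
        return np.array([sp.yearly_kcal_increase for sp in self.ordered()])


@dataclass(frozen=True)
class Scenario:
    """A price-change experiment with sensitivity toggles.

    ``price_change`` is a signed fraction applied uniformly to red meat,
    white meat and seafood (0.10 = +10%).  The base case runs a 15-year
    horizon over 100,000 individuals with all variant flags off.
    """

    price_change: float = 0.0
    horizon_years: int = 15
    n_individuals: int = 100_000
    seed: int = 0
    complementarity: bool = False
    flat_mortality_curve: bool = False
    swap_race_rr: bool = False
    swap_race_bmi: bool = False
    recalibrate_mortality: bool = False
    rate_based_rr: bool = False
    creep_multiplier: float = 1.0

    def validate(self) -> None:
        if self.price_change <= -1.0:
            raise ParameterError(f"price_change {self.price_change} must be > -1")
        if self.horizon_years < 1:
            raise ParameterError(f"horizon_years {self.horizon_years} must be >= 1")
        if self.n_individuals < 1:
            raise ParameterError(f"n_individuals {self.n_individuals} must be >= 1")


class LifeTable:
    """Annual death probabilities q(age, sex, race) for ages 18..110.

    Backed by a dense array; lookups are vectorized and ages beyond the
    terminal age return q = 1.
    """

    def __init__(self, q: np.ndarray):
        expected = (TERMINAL_AGE - MIN_ADULT_AGE + 1, len(SEXES), len(RACES))
        if q.shape != expected:
            raise ParameterError(f"life table array shape {q.shape}, expected {expected}")
        if np.any((q < 0) | (q > 1)) or np.any(np.isnan(q)):
            raise ParameterError("life table q values must lie in [0, 1]")
        if not np.all(q[-1] == 1.0):
            raise ParameterError(f"life table q at terminal age {TERMINAL_AGE} must be 1.0")
        self._q = q

    def lookup(self, age, sex_codes, race_codes):
        """Vectorized q(age, sex, race); age past the terminal age gives 1."""
        age = np.asarray(age)
        idx = np.clip(age - MIN_ADULT_AGE, 0, TERMINAL_AGE - MIN_ADULT_AGE)
        q = self._q[idx, sex_codes, race_codes]
        return np.where(age >= TERMINAL_AGE, 1.0, q)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        required = {"age", "sex", "race", "q"}
        if not required.issubset(df.columns):
            raise ParameterError(f"life table CSV needs columns {sorted(required)}")
        q = np.full((TERMINAL_AGE - MIN_ADULT_AGE + 1, len(SEXES), len(RACES)), np.nan)
        for row in df.itertuples():
            if row.sex not in SEXES or row.race not in RACES:
                raise ParameterError(f"life table row has unknown sex/race: {row.sex}, {row.race}")
            a = int(row.age)
            if MIN_ADULT_AGE <= a <= TERMINAL_AGE:
                q[a - MIN_ADULT_AGE, sex_code(row.sex), race_code(row.race)] = row.q
        missing = np.argwhere(np.isnan(q))
        if len(missing):
            a, s, r = missing[0]
            raise ParameterError(
                f"life table incomplete: missing (age={a + MIN_ADULT_AGE}, "
                f"sex={SEXES[s]}, race={RACES[r]}) and "
                f"{len(missing) - 1} more"
            )
        return cls(q)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in range(MIN_ADULT_AGE, TERMINAL_AGE + 1):
            for s, sex in enumerate(SEXES):
                for r, race in enumerate(RACES):
                    rows.append((a, sex, race, self._q[a - MIN_ADULT_AGE, s, r]))
        return pd.DataFrame(rows, columns=["age", "sex", "race", "q"])


class Demographics:
    """Joint (age, sex, race) marginals for cohort generation.

    Rows carry probability weights, normalized on load.  Every race-sex
    subgroup must be represented.
    """

    def __init__(self, df: pd.DataFrame, require_all_subgroups: bool = True):
        required = {"age", "sex", "race", "weight"}
        if not required.issubset(df.columns):
            raise ParameterError(f"demographics CSV needs columns {sorted(required)}")
        if (df["weight"] < 0).any():
            raise ParameterError("demographics weights must be non-negative")
        total = df["weight"].sum()
        if total <= 0:
            raise ParameterError("demographics weights sum to zero")
        df = df.copy()
        df["weight"] = df["weight"] / total
        if require_all_subgroups:
            for sex in SEXES:
                for race in RACES:
                    mask = (df["sex"] == sex) & (df["race"] == race)
                    if df.loc[mask, "weight"].sum() <= 0:
                        raise ParameterError(
                            f"demographics: subgroup {subgroup_key(race, sex)} has no mass"
                        )
        self.df = df
        self.ages = df["age"].to_numpy(dtype=int)
        self.sex_codes = df["sex"].map(SEXES.index).to_numpy(dtype=np.int8)
        self.race_codes = df["race"].map(RACES.index).to_numpy(dtype=np.int8)
        self.probs = df["weight"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "Demographics":
        return cls(pd.read_csv(path, comment="#"))

    def restrict(self, race: str, sex: str) -> "Demographics":
        """Marginals conditioned on one subgroup (for per-subgroup runs)."""
        mask = (self.df["sex"] == sex) & (self.df["race"] == race)
        return Demographics(
            self.df.loc[mask].reset_index(drop=True), require_all_subgroups=False
        )


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------


def _subgroup_from_dict(key: str, d: Mapping) -> SubgroupParams:
    try:
        race, sex = key.split("_")
        ms = d["meat_share"]
        return SubgroupParams(
            race=race,
            sex=sex,
            bmi_band_probs=tuple(float(x) for x in d["bmi_band_probs"]),
            meat_share_mean=float(ms["mean"]),
            meat_share_ci=(float(ms["ci_low"]), float(ms["ci_high"])),
            utilities=tuple(float(x) for x in d["utilities"]),
            rr_by_band=tuple(float(x) for x in d["rr_by_band"]),
            yearly_kcal_increase=float(d["yearly_kcal_increase"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"subgroup block {key!r} malformed: {exc}") from exc


def params_from_dict(doc: Mapping) -> ModelParams:
    if "subgroups" not in doc:
        raise ParameterError("parameter file has no 'subgroups' block")
    subgroups = {k: _subgroup_from_dict(k, v) for k, v in doc["subgroups"].items()}
    e = doc.get("elasticities", {})
    elasticities = Elasticities(
        red=float(e.get("red", -0.52)),
        white=float(e.get("white", -0.46)),
        seafood=float(e.get("seafood", -0.53)),
        cross=float(e.get("cross", 0.0)),
    )
    params = ModelParams(
        subgroups=subgroups,
        elasticities=elasticities,
        subtype_split=tuple(doc.get("subtype_split", (1 / 3, 1 / 3, 1 / 3))),
        elasticity_form=doc.get("elasticity_form", "linear"),
        meat_share_mode=doc.get("meat_share_mode", "sampled"),
    )
    params.validate()
    return params


def params_to_dict(params: ModelParams) -> dict:
    return {
        "elasticities": {
            "red": params.elasticities.red,
            "white": params.elasticities.white,
            "seafood": params.elasticities.seafood,
            "cross": params.elasticities.cross,
        },
        "subtype_split": list(params.subtype_split),
        "elasticity_form": params.elasticity_form,
        "meat_share_mode": params.meat_share_mode,
        "subgroups": {
            sp.key: {
                "bmi_band_probs": list(sp.bmi_band_probs),
                "meat_share": {
                    "mean": sp.meat_share_mean,
                    "ci_low": sp.meat_share_ci[0],
                    "ci_high": sp.meat_share_ci[1],
                },
                "utilities": list(sp.utilities),
                "rr_by_band": list(sp.rr_by_band),
                "yearly_kcal_increase": sp.yearly_kcal_increase,
            }
            for sp in params.ordered()
        },
    }


def load_params(path) -> ModelParams:
    """Load and validate the full parameter set from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ParameterError(f"parameter file {path} is not a mapping")
    return params_from_dict(doc)


def save_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    """Load a scenario config, filling base-case defaults.

    An empty file yields the status-quo scenario.  A missing seed defaults
    to 0 with a logged warning so batch runs are still reproducible.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise ParameterError(f"scenario file {path} is not a mapping")
    known = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"scenario file has unknown keys: {sorted(unknown)}")
    if "seed" not in doc:
        logger.warning("scenario %s has no seed; defaulting to 0", path)
    scenario = Scenario(**doc)
    scenario.validate()
    return scenario


def load_life_table(path) -> LifeTable:
    return LifeTable.from_csv(path)


def load_demographics(path) -> Demographics:
    return Demographics.from_csv(path)


# -- packaged defaults -------------------------------------------------------


def _data_path(name: str):
    return resources.files("meatshift").joinpath("data", name)


def default_params() -> ModelParams:
    """The packaged parameter file (published model parameters)."""
    with resources.as_file(_data_path("params.yaml")) as p:
        return load_params(p)


def default_life_table() -> LifeTable:
    """Packaged synthetic Gompertz-style life-table fixture."""
    with resources.as_file(_data_path("lifetable.csv")) as p:
        return load_life_table(p)


def default_demographics() -> Demographics:
    """Packaged synthetic demographic-marginals fixture."""
    with resources.as_file(_data_path("demographics.csv")) as p:
        return load_demographics(p)
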