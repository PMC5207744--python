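"""Named sensitivity analyses as parameter-set transformations.

Each variant is a pure transformation of the parameter set (the base set
is never mutated) plus, where relevant, a scenario toggle.  A battery
runs a (variant × price) grid, contrasting every run against its own
variant-matched status quo.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import contrast_vs_status_quo, run_scenario
from .params import (
    Demographics,
    LifeTable,
    ModelParams,
    RR_REFERENCE_BAND,
    Scenario,
    SUBGROUPS,
    SubgroupParams,
)
from .population import sample_population

logger = logging.getLogger(__name__)

VARIANT_NAMES = (
    "complementarity_on",
    "flat_mortality",
    "swap_race_rr",
    "swap_race_bmi",
    "zero_creep",
    "price_decrease",
    "meat_share_scaled",
    "elasticity_scaled",
)

SCALED_VARIANTS = ("meat_share_scaled", "elasticity_scaled")

#: Placeholder aggregate cross-price elasticity for the complementarity
#: sensitivity (the published analysis does not print its magnitudes).
DEFAULT_CROSS_ELASTICITY = -0.1


@dataclass(frozen=True)
class VariantSpec:
    """One named sensitivity variant, with a magnitude where scaled."""

    name: str
    magnitude: float | None = None

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; known: {VARIANT_NAMES}")
        if self.name in SCALED_VARIANTS and self.magnitude is None:
            raise ValueError(f"variant {self.name!r} requires a magnitude")


def _replace_subgroups(params: ModelParams, new: dict[str, SubgroupParams]) -> ModelParams:
    return dataclasses.replace(params, subgroups={**params.subgroups, **new})


def apply_variant(params: ModelParams, spec: VariantSpec) -> ModelParams:
    """Return a transformed copy of the parameter set; base untouched.

    swap variants copy white columns onto the sex-matched black subgroup;
    flat_mortality sets every RR to 1; zero_creep zeroes all yearly
    increments; scaled variants multiply the named parameter by the
    magnitude.  The transformed set is re-validated.  ``price_decrease``
    is a scenario-level variant (negative prices in the battery) and
    leaves parameters unchanged.
    """
    name = spec.name
    if name == "price_decrease":
        out = params
    elif name == "complementarity_on":
        cross = spec.magnitude if spec.magnitude is not None else DEFAULT_CROSS_ELASTICITY
        out = dataclasses.replace(
            params, elasticities=dataclasses.replace(params.elasticities, cross=cross)
        )
    elif name == "flat_mortality":
        out = _replace_subgroups(
            params,
            {
                k: dataclasses.replace(sp, rr_by_band=(1.0,) * 9)
                for k, sp in params.subgroups.items()
            },
        )
    elif name == "swap_race_rr":
        out = _replace_subgroups(
            params,
            {
                f"black_{sex}": dataclasses.replace(
                    params.subgroups[f"black_{sex}"],
                    rr_by_band=params.subgroups[f"white_{sex}"].rr_by_band,
                )
                for sex in ("male", "female")
            },
        )
    elif name == "swap_race_bmi":
        out = _replace_subgroups(
            params,
            {
                f"black_{sex}": dataclasses.replace(
                    params.subgroups[f"black_{sex}"],
                    bmi_band_probs=params.subgroups[f"white_{sex}"].bmi_band_probs,
                )
                for sex in ("male", "female")
            },
        )
    elif name == "zero_creep":
        out = _replace_subgroups(
            params,
            {
                k: dataclasses.replace(sp, yearly_kcal_increase=0.0)
                for k, sp in params.subgroups.items()
            },
        )
    elif name == "meat_share_scaled":
        m = spec.magnitude
        out = _replace_subgroups(
            params,
            {
                k: dataclasses.replace(
                    sp,
                    meat_share_mean=min(0.99, sp.meat_share_mean * m),
                    meat_share_ci=(
                        min(0.99, sp.meat_share_ci[0] * m),
                        min(0.99, sp.meat_share_ci[1] * m),
                    ),
                )
                for k, sp in params.subgroups.items()
            },
        )
    elif name == "elasticity_scaled":
        m = spec.magnitude
        e = params.elasticities
        out = dataclasses.replace(
            params,
            elasticities=dataclasses.replace(
                e, red=e.red * m, white=e.white * m, seafood=e.seafood * m
            ),
        )
    else:  # pragma: no cover — guarded by VariantSpec
        raise ValueError(f"unknown variant {name!r}")
    out.validate()
    return out


def apply_variants(params: ModelParams, specs) -> ModelParams:
    """Compose variants left-to-right."""
    for spec in specs:
        logger.info("applying variant %s", spec.name)
        params = apply_variant(params, spec)
    return params


def run_battery(
    variants: list[VariantSpec],
    price_changes: list[float],
    params: ModelParams,
    demographics: Demographics,
    life_table: LifeTable,
    seed: int = 0,
    n: int = 20_000,
    horizon: int = 15,
) -> pd.DataFrame:
    """Run a (variant × price) grid of scenario contrasts.

    Each variant gets its own cohort (generation-time variants such as
    swap_race_bmi change the cohort) and its own variant-matched status
    quo; an empty variant list runs the base-case battery only.  Returns
    one long contrast table with ``variant`` and ``price_change`` columns.
    """
    batteries = [("base", [])] + [(v.name, [v]) for v in variants]
    frames = []
    for name, specs in batteries:
        vp = apply_variants(params, specs)
        names = [s.name for s in specs]
        complementarity = "complementarity_on" in names
        creep = 0.0 if "zero_creep" in names else 1.0
        cohort = sample_population(n, demographics, vp, seed=seed)

        def scenario(price):
            return Scenario(
                price_change=price,
                horizon_years=horizon,
                n_individuals=n,
                seed=seed,
                complementarity=complementarity,
                creep_multiplier=creep,
            )

        sq = run_scenario(cohort, scenario(0.0), vp, life_table)
        for price in price_changes:
            if price == 0.0:
                continue
            res = run_scenario(cohort, scenario(price), vp, life_table)
            contrast = contrast_vs_status_quo(res, sq)
            contrast.insert(0, "variant", name)
            frames.append(contrast)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
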