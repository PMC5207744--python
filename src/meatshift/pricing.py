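"""Price response: meat price change → change in daily caloric intake.

A one-time, permanent price change applied uniformly to red meat, white
meat and seafood shifts each individual's meat calories through the
own-price elasticities of demand; an optional cross-price (complement)
channel shifts non-meat calories.  The price shock composes with the
secular yearly caloric increase ("caloric creep") into the net intake
change at each elapsed year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Elasticities

#: Total daily intake is floored here to avoid pathological starvation
#: under extreme configured shocks.
INTAKE_FLOOR_KCAL = 500.0


@dataclass(frozen=True)
class IntakeDelta:
    """Decomposed intake change: one-time price shock + yearly creep.

    ``one_time`` (kcal/day) applies from year 0 onward; ``yearly``
    (kcal/day per elapsed year) is the subgroup's calibrated increment
    scaled by the scenario's creep multiplier, first accruing at t=1.
    """

    one_time: float
    yearly: float


def quantity_change(elasticity, price_change, form: str = "linear"):
    """Fractional change in quantity consumed for a fractional price change.

    Linear convention: ΔQ/Q = e · ΔP/P (an elasticity of −0.5 under a +10%
    price change gives a 5% reduction).  The log-log alternative
    (1 + ΔP/P)^e − 1 agrees to first order and diverges only for large
    shocks.  The result is floored at −1 (quantity cannot go negative).
    """
    if np.any(np.asarray(price_change) <= -1.0):
        raise ValueError("price_change must be > -1")
    e = np.asarray(elasticity, dtype=float)
    dp = np.asarray(price_change, dtype=float)
    if form == "linear":
        out = e * dp
    elif form == "loglog":
        out = (1.0 + dp) ** e - 1.0
    else:
        raise ValueError(f"unknown elasticity form {form!r}")
    return np.maximum(out, -1.0)


def meat_calorie_delta(
    baseline_intake,
    meat_share,
    elasticities: Elasticities,
    price_change: float,
    subtype_split=(1 / 3, 1 / 3, 1 / 3),
    form: str = "linear",
):
    """Change in daily calories from meats under a uniform price change.

    baseline_intake · meat_share · Σ_k split_k · quantity_change(e_k, ΔP).
    Opposite in sign to the price change for meat eaters (own-price
    elasticities are negative).  Array arguments broadcast.
    """
    split = np.asarray(subtype_split, dtype=float)
    if len(split) != 3 or abs(split.sum() - 1.0) > 1e-9:
        raise ValueError(f"subtype_split must be 3 fractions summing to 1, got {split}")
    qc = float(np.dot(split, quantity_change(elasticities.own(), price_change, form)))
    return np.asarray(baseline_intake, dtype=float) * np.asarray(meat_share, dtype=float) * qc


def complementarity_delta(
    baseline_intake,
    meat_share,
    cross_elasticity: float,
    price_change: float,
    enabled: bool = True,
):
    """Change in non-meat daily calories through the complement channel.

    baseline_intake · (1 − meat_share) · cross · ΔP; zero when the channel
    is off (the base case assumes no complementarity).
    """
    if not enabled:
        return np.zeros_like(np.asarray(baseline_intake, dtype=float))
    return (
        np.asarray(baseline_intake, dtype=float)
        * (1.0 - np.asarray(meat_share, dtype=float))
        * cross_elasticity
        * price_change
    )


def net_intake_delta(delta: IntakeDelta, t) -> float:
    """Net kcal/day change relative to baseline at elapsed year t ≥ 0."""
    return delta.one_time + delta.yearly * np.asarray(t)


def floored_intake(baseline_intake, net_delta):
    """Total intake with the starvation floor applied."""
    return np.maximum(np.asarray(baseline_intake) + np.asarray(net_delta), INTAKE_FLOOR_KCAL)
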