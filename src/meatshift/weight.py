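"""Energy-balance body-weight dynamics.

A one-compartment model: weight changes at a rate proportional to the gap
between caloric intake and total energy expenditure, where expenditure is
the physical activity level (PAL) times a resting metabolic rate (RMR)
that itself depends on current weight:

    dW/dt = (intake − pal · RMR(W, height, age, sex)) / rho

with rho the energy content of tissue change (kcal per kg).  Because RMR
rises with weight, weight change is self-limiting: constant intake drives
weight toward a unique steady state, which the linear Mifflin-St Jeor RMR
makes available in closed form.

Integration uses explicit daily Euler steps.  Within a simulated year all
coefficients are constant, so the m-step Euler recursion is a geometric
contraction toward the steady state and is evaluated in closed form —
bit-equivalent to looping over the days but O(1) per individual-year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Energy content of tissue change, kcal per kg of body-weight change.
RHO_KCAL_PER_KG = 7700.0

#: Hard plausibility bounds on simulated BMI; values outside are clamped
#: (band lookups clamp further to [15, 60]).
BMI_HARD_MIN = 12.0
BMI_HARD_MAX = 70.0

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class EnergyModelConfig:
    """Numerical configuration of the energy-balance integrator."""

    rho: float = RHO_KCAL_PER_KG       # kcal per kg of tissue change
    dt: float = 1.0                    # integration step, days
    rmr_formula: str = "mifflin"

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not (0 < self.dt <= 30):
            raise ValueError(f"dt must be in (0, 30] days, got {self.dt}")
        if self.rmr_formula != "mifflin":
            raise ValueError(f"unknown rmr_formula {self.rmr_formula!r}")


def _sex_constant(sex):
    """Mifflin-St Jeor additive sex term: +5 male, −161 female.

    Accepts 'male'/'female' strings or integer codes (0 male, 1 female),
    scalar or array.
    """
    if isinstance(sex, str):
        if sex not in ("male", "female"):
            raise ValueError(f"unknown sex {sex!r}")
        return 5.0 if sex == "male" else -161.0
    return np.where(np.asarray(sex) == 0, 5.0, -161.0)


def rmr(weight, height, age, sex):
    """Resting metabolic rate (kcal/day), Mifflin-St Jeor.

    RMR = 10·W[kg] + 6.25·H[cm] − 5·age[y] + s, with s = +5 for males and
    −161 for females.  ``height`` is in meters.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    return 10.0 * weight + 6.25 * (height * 100.0) - 5.0 * np.asarray(age) + _sex_constant(sex)


def steady_state_weight(intake, pal, height, age, sex):
    """Weight W* at which intake = pal · RMR(W*); closed form.

    W* = (intake/pal − 6.25·H[cm] + 5·age − s) / 10.  May be non-positive
    for intakes too low for the covariates; callers should clamp (a
    warning is the caller's responsibility since vector contexts differ).
    """
    intake = np.asarray(intake, dtype=float)
    return (
        intake / np.asarray(pal, dtype=float)
        - 6.25 * (np.asarray(height, dtype=float) * 100.0)
        + 5.0 * np.asarray(age)
        - _sex_constant(sex)
    ) / 10.0


def update_weight(weight, intake, pal, height, age, sex, duration_years=1.0,
                  config: EnergyModelConfig = EnergyModelConfig()):
    """Advance weight by ``duration_years`` under constant daily intake.

    Evaluates the explicit-Euler daily integration of the energy-balance
    ODE in closed form: with b = 10·pal (kcal/day per kg of RMR feedback)
    and r = 1 − b·dt/rho, the m-step recursion gives

        W(m) = W* + (W0 − W*) · r^m.

    The result lies strictly between the starting weight and the steady
    state when they differ, and equals the starting weight at the fixed
    point.  All arguments broadcast.
    """
    w0 = np.asarray(weight, dtype=float)
    wstar = steady_state_weight(intake, pal, height, age, sex)
    b = 10.0 * np.asarray(pal, dtype=float)
    r = 1.0 - b * config.dt / config.rho
    m = int(round(duration_years * DAYS_PER_YEAR / config.dt))
    return wstar + (w0 - wstar) * r**m


def clamp_bmi(weight, height):
    """BMI from weight/height with hard clamping to [12, 70].

    Returns (bmi, n_clamped).  Clamping also rewrites weight implicitly
    for callers that recompute it; the engine keeps weight consistent by
    converting the clamped BMI back.
    """
    height = np.asarray(height, dtype=float)
    bmi = np.asarray(weight, dtype=float) / height**2
    clamped = np.clip(bmi, BMI_HARD_MIN, BMI_HARD_MAX)
    return clamped, int(np.count_nonzero(clamped != bmi))
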