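"""Health-state utilities and discounted QALY accrual.

Utility is NYHA-class specific at baseline, permanently stepped down by a
multiplicative factor (default 0.82) at each of the first three
hospitalizations, and capped from above by the general-population utility at
the patient's current age (a quadratic age-sex equation of the Ara-Brazier
form), which also supplies the aging decrement.  QALYs are the discounted
integral of the utility path over survival, computed piecewise-analytically
between events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Trajectory
    from .population import PatientProfile

__all__ = [
    "UtilityParams",
    "general_population_utility",
    "utility_at",
    "discounted_qalys",
    "life_years",
]

#: Published general-population EQ-5D regression coefficients
#: (intercept, male shift, age, age^2); quadratic in age, shifted by sex.
ARA_BRAZIER_COEFFICIENTS = (0.9508566, 0.0212126, -0.0002587, -0.0000332)


@dataclass
class UtilityParams:
    nyha_utilities: tuple = (0.87976, 0.71178, 0.61405, 0.49228)
    nyha_utility_ses: tuple = (0.00827, 0.00944, 0.01349, 0.03032)
    hosp_multiplier: float = 0.82
    max_hosp_decrements: int = 3
    outpatient_multiplier: float = 1.0
    general_population_coefficients: tuple = ARA_BRAZIER_COEFFICIENTS
    #: when False, hospitalizations carry no lasting utility step-down
    #: (scenario switch for a transient-decrement reading)
    permanent_decrement: bool = True

    def __post_init__(self):
        self.nyha_utilities = tuple(float(u) for u in self.nyha_utilities)
        if len(self.nyha_utilities) != 4:
            raise ValueError("nyha_utilities needs 4 entries")
        if any(not 0.0 <= u <= 1.0 for u in self.nyha_utilities):
            raise ValueError("NYHA utilities must lie in [0, 1]")
        if not 0.0 < self.hosp_multiplier <= 1.0:
            raise ValueError("hosp_multiplier must lie in (0, 1]")
        if self.max_hosp_decrements < 0:
            raise ValueError("max_hosp_decrements must be >= 0")


def general_population_utility(age: float, male: bool, params: UtilityParams) -> float:
    """Age-sex general-population utility, clamped to [0, 1]."""
    if age < 0:
        raise ValueError("age must be >= 0")
    b0, b_male, b1, b2 = params.general_population_coefficients
    u = b0 + (b_male if male else 0.0) + b1 * age + b2 * age * age
    return min(1.0, max(0.0, u))


def _state_utility(profile, n_hosp: int, params: UtilityParams) -> float:
    base = params.nyha_utilities[profile.nyha - 1]
    if not params.permanent_decrement:
        return base
    k = min(n_hosp, params.max_hosp_decrements)
    return base * params.hosp_multiplier**k


def utility_at(
    profile: "PatientProfile", t: float, n_hosp_so_far: int, params: UtilityParams
) -> float:
    """Utility at time ``t`` given hospitalizations experienced so far."""
    if t < 0:
        raise ValueError("t must be >= 0")
    cap = general_population_utility(profile.age_years + t, profile.male, params)
    return min(_state_utility(profile, n_hosp_so_far, params), cap)


# ---------------------------------------------------------------------------
# analytic discounted integration of min(constant, clamped quadratic)
# ---------------------------------------------------------------------------


def _poly_exp_integral(coeffs, k, t0, t1):
    """Integral of (c0 + c1 t + c2 t^2) * exp(-k t) over [t0, t1], closed form."""
    c0, c1, c2 = coeffs
    if k == 0.0:
        return (
            c0 * (t1 - t0)
            + c1 * (t1**2 - t0**2) / 2.0
            + c2 * (t1**3 - t0**3) / 3.0
        )

    def antiderivative(t):
        # -e^{-kt} * (P0*c0 + P1*c1 + P2*c2) with Pn the t^n e^{-kt} kernels
        e = math.exp(-k * t)
        p0 = 1.0 / k
        p1 = t / k + 1.0 / k**2
        p2 = t * t / k + 2.0 * t / k**2 + 2.0 / k**3
        return -e * (c0 * p0 + c1 * p1 + c2 * p2)

    return antiderivative(t1) - antiderivative(t0)


def _real_roots_in(a, b, c, lo, hi):
    """Real roots of a + b t + c t^2 = 0 strictly inside (lo, hi)."""
    roots = []
    if abs(c) > 0.0:
        disc = b * b - 4.0 * c * a
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2.0 * c), (-b + sq) / (2.0 * c)]
    elif abs(b) > 0.0:
        roots = [-a / b]
    return sorted(r for r in roots if lo < r < hi)


def _segment_qalys(profile, params, u_state, t0, t1, k):
    """Discounted QALYs over [t0, t1] with constant state utility ``u_state``.

    The realized utility is min(u_state, clip(q(t), 0, 1)) where q is the
    general-population quadratic evaluated at age0 + t.  The segment is split
    at the crossings of q with u_state, 0 and 1, and each branch integrated in
    closed form.
    """
    if t1 <= t0:
        return 0.0
    b0, b_male, b1, b2 = params.general_population_coefficients
    age0 = profile.age_years
    # q(t) = alpha + beta t + gamma t^2
    alpha = b0 + (b_male if profile.male else 0.0) + b1 * age0 + b2 * age0 * age0
    beta = b1 + 2.0 * b2 * age0
    gamma = b2

    cuts = {t0, t1}
    for level in (u_state, 0.0, 1.0):
        cuts.update(_real_roots_in(alpha - level, beta, gamma, t0, t1))
    grid = sorted(cuts)

    total = 0.0
    for s0, s1 in zip(grid, grid[1:]):
        tm = 0.5 * (s0 + s1)
        q = alpha + beta * tm + gamma * tm * tm
        if q <= 0.0:
            continue  # capped at zero utility
        if q >= u_state or q >= 1.0:
            total += _poly_exp_integral((min(u_state, 1.0), 0.0, 0.0), k, s0, s1)
        else:
            total += _poly_exp_integral((alpha, beta, gamma), k, s0, s1)
    return total


def discounted_qalys(
    trajectory: "Trajectory",
    profile: "PatientProfile",
    params: UtilityParams,
    effect_rate: float,
) -> float:
    """Discounted QALYs over [0, death] for one trajectory.

    Piecewise-analytic: utility is constant between realized hospitalizations
    (which step it down) apart from the smooth general-population cap; each
    piece integrates a constant or the cap quadratic against (1+r)^(-t).
    """
    if trajectory.death_time is None:
        raise ValueError("trajectory has no death event")
    if effect_rate < 0:
        raise ValueError("effect discount rate must be >= 0")
    k = math.log1p(effect_rate)

    hosp_times = [
        e.time_years
        for e in trajectory.events
        if e.kind in ("hospitalization", "death_in_hospital")
    ]
    breakpoints = [0.0] + hosp_times + [trajectory.death_time]
    total = 0.0
    n_hosp = profile.n_prior_hospitalizations
    for i, (t0, t1) in enumerate(zip(breakpoints, breakpoints[1:])):
        u_state = _state_utility(profile, n_hosp, params)
        total += _segment_qalys(profile, params, u_state, t0, t1, k)
        n_hosp += 1  # the hospitalization at t1 (if any) steps utility down
    return total


def life_years(death_time: float, effect_rate: float) -> float:
    """Discounted life years: integral of (1+r)^(-t) over [0, death]."""
    if effect_rate == 0.0:
        return death_time
    k = math.log1p(effect_rate)
    return (1.0 - math.exp(-k * death_time)) / k
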