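"""Societal-perspective cost accrual and discounting.

Unit costs default to the Dutch 2020 figures used in the base case; yearly
components (care-provider contacts, drugs, informal care, telemonitoring
device, future unrelated medical costs) accrue continuously over survival and
are discounted with the annual-compounding convention (1+r)^(-t) applied in
continuous time.  Costs and effects use separate discount rates (Dutch
guideline differential discounting: costs 4%/yr, effects 1.5%/yr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

if TYPE_CHECKING:  # pragma: no cover
    from .engine import EventRecord, Trajectory
    from .population import PatientProfile

__all__ = [
    "CostParams",
    "EconSettings",
    "AgeSexTable",
    "ProductivityParams",
    "UnrelatedCostTable",
    "CostBreakdown",
    "discount_factor",
    "continuous_cost",
    "event_costs",
    "productivity_loss",
    "unrelated_medical_costs",
    "total_costs",
]

HTM_ARMS = ("HTM", "HTM_DA")


@dataclass
class CostParams:
    """Unit costs in 2020 euros."""

    outpatient_visit_uc: float = 44.50
    outpatient_visit_htm: float = 43.30
    other_contacts_uc_per_year: float = 188.38
    other_contacts_htm_per_year: float = 623.61
    hospitalization: float = 4404.46
    htm_device_per_year: float = 1257.75
    alarm_management: float = 18.38
    drugs_per_year: float = 286.44
    travel_outpatient: float = 3.75
    travel_hospitalization: float = 4.68
    informal_care_per_year: float = 2098.28

    def __post_init__(self):
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"cost parameter {name} must be >= 0, got {value}")


@dataclass
class EconSettings:
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    perspective: Literal["societal", "healthcare"] = "societal"

    def __post_init__(self):
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValueError("discount rates must be >= 0")
        if self.perspective not in ("societal", "healthcare"):
            raise ValueError(f"unknown perspective {self.perspective!r}")


@dataclass
class AgeSexTable:
    """Piecewise-constant age-by-sex lookup (contiguous half-open age bands).

    ``bands`` is a sequence of (low, high) ages; ``male``/``female`` hold the
    per-band values.  Lookup uses low <= age < high.
    """

    bands: tuple
    male: tuple
    female: tuple

    def __post_init__(self):
        self.bands = tuple((float(a), float(b)) for a, b in self.bands)
        self.male = tuple(float(v) for v in self.male)
        self.female = tuple(float(v) for v in self.female)
        if not (len(self.bands) == len(self.male) == len(self.female)):
            raise ValueError("bands, male and female must have equal length")
        for (a, b) in self.bands:
            if not a < b:
                raise ValueError(f"empty age band ({a}, {b})")
        for (_, b), (a2, _) in zip(self.bands, self.bands[1:]):
            if not math.isclose(b, a2):
                raise ValueError("age bands must be contiguous")

    def value_at(self, age: float, male: bool) -> float:
        values = self.male if male else self.female
        for (a, b), v in zip(self.bands, values):
            if a <= age < b:
                return v
        raise ValueError(f"age {age} outside table coverage "
                         f"[{self.bands[0][0]}, {self.bands[-1][1]})")

    def edges_between(self, age0: float, age1: float):
        """Interior band edges strictly inside (age0, age1)."""
        edges = [a for (a, _) in self.bands[1:]]
        return [e for e in edges if age0 < e < age1]


def _default_participation():
    # net labor participation by age band and sex; illustrative figures in
    # the range of Dutch labor statistics
    return AgeSexTable(
        bands=((18, 25), (25, 55), (55, 65), (65, math.inf)),
        male=(0.65, 0.88, 0.70, 0.0),
        female=(0.68, 0.78, 0.55, 0.0),
    )


def _default_hours():
    return AgeSexTable(
        bands=((18, 55), (55, 65), (65, math.inf)),
        male=(38.0, 35.0, 0.0),
        female=(27.0, 25.0, 0.0),
    )


def _default_wage():
    return AgeSexTable(
        bands=((18, 55), (55, 65), (65, math.inf)),
        male=(37.0, 39.0, 0.0),
        female=(33.0, 34.0, 0.0),
    )


@dataclass
class ProductivityParams:
    """Friction-cost productivity model.

    A hospitalized working patient below retirement age loses one friction
    month of age-sex-specific wages.  Working status is a baseline draw:
    P(working) = working_prob_by_nyha[class] x labor participation(age, sex),
    and does not change during the simulation.  The NYHA working shares and
    the wage tables are illustrative (the underlying sources are not printed).
    """

    working_prob_by_nyha: tuple = (0.35, 0.25, 0.10, 0.02)
    labor_participation: AgeSexTable = field(default_factory=_default_participation)
    hours_per_week: AgeSexTable = field(default_factory=_default_hours)
    hourly_labor_cost: AgeSexTable = field(default_factory=_default_wage)
    friction_months_per_hospitalization: float = 1.0
    retirement_age: float = 65.0

    def __post_init__(self):
        self.working_prob_by_nyha = tuple(float(p) for p in self.working_prob_by_nyha)
        if len(self.working_prob_by_nyha) != 4:
            raise ValueError("working_prob_by_nyha needs one entry per NYHA class")
        for p in self.working_prob_by_nyha:
            if not 0.0 <= p <= 1.0:
                raise ValueError("working probabilities must lie in [0, 1]")

    def working_probability(self, age: float, male: bool, nyha: int) -> float:
        base = self.working_prob_by_nyha[nyha - 1]
        try:
            part = self.labor_participation.value_at(age, male)
        except ValueError:
            part = 0.0
        return base * part


def _default_unrelated():
    # per-capita yearly health expenditure by age/sex; illustrative values of
    # the order of Dutch per-capita spending
    return AgeSexTable(
        bands=((0, 50), (50, 60), (60, 70), (70, 80), (80, math.inf)),
        male=(2100.0, 3500.0, 5300.0, 8100.0, 13000.0),
        female=(2400.0, 3700.0, 5100.0, 7800.0, 13800.0),
    )


@dataclass
class UnrelatedCostTable:
    """Future unrelated medical costs (euros/year) by age band and sex."""

    table: AgeSexTable = field(default_factory=_default_unrelated)

    def __post_init__(self):
        if any(v < 0 for v in self.table.male + self.table.female):
            raise ValueError("unrelated medical costs must be >= 0")


# ---------------------------------------------------------------------------
# discounting primitives
# ---------------------------------------------------------------------------


def discount_factor(t: float, r: float) -> float:
    """(1+r)^(-t) with continuous-time exponent."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + r) ** (-t)


def continuous_cost(annual_rate: float, t0: float, t1: float, r: float) -> float:
    """Discounted value of a constant flow of ``annual_rate`` euros/year over [t0, t1].

    Closed form: c * [(1+r)^(-t0) - (1+r)^(-t1)] / ln(1+r); reduces to
    c * (t1 - t0) at r = 0.
    """
    if t0 < 0 or t1 < t0:
        raise ValueError("need 0 <= t0 <= t1")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    if r == 0.0:
        return annual_rate * (t1 - t0)
    k = math.log1p(r)
    return annual_rate * (discount_factor(t0, r) - discount_factor(t1, r)) / k


# ---------------------------------------------------------------------------
# per-event and per-trajectory costs
# ---------------------------------------------------------------------------


def event_costs(
    event: "EventRecord", arm: str, params: CostParams, settings: EconSettings
) -> float:
    """Discounted cost of one event record.

    Travel expenses ride on outpatient visits and hospitalizations (societal
    perspective only).  False alarms accrued over the gap preceding the event
    are charged at the gap midpoint (``fa_time`` in the payload) at the
    alarm-management unit cost.
    """
    r = settings.discount_rate_costs
    societal = settings.perspective == "societal"
    kind = event.kind
    df = discount_factor(event.time_years, r)
    if kind == "outpatient_visit":
        visit = params.outpatient_visit_uc if arm == "UC" else params.outpatient_visit_htm
        cost = (visit + (params.travel_outpatient if societal else 0.0)) * df
    elif kind == "hospitalization":
        cost = (
            params.hospitalization
            + (params.travel_hospitalization if societal else 0.0)
        ) * df
    elif kind == "averted_hospitalization":
        cost = params.alarm_management * df
    elif kind in ("death_in_hospital", "death_other"):
        cost = params.hospitalization * df if kind == "death_in_hospital" else 0.0
        if kind == "death_in_hospital" and societal:
            cost += params.travel_hospitalization * df
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    fa = float(event.payload.get("false_alarms", 0.0))
    if fa > 0.0:
        fa_t = float(event.payload.get("fa_time", event.time_years))
        cost += fa * params.alarm_management * discount_factor(fa_t, r)
    return cost


def productivity_loss(
    profile: "PatientProfile",
    t_hosp: float,
    params: ProductivityParams,
    settings: EconSettings,
) -> float:
    """Discounted friction-cost productivity loss of one hospitalization.

    Zero if the patient was not working at baseline or has reached retirement
    age by the admission; otherwise friction months of age-sex-specific wages
    (hours/week x euros/hour x 52/12 per month), discounted at the cost rate.
    """
    if t_hosp < 0:
        raise ValueError("t_hosp must be >= 0")
    if not profile.working:
        return 0.0
    age = profile.age_years + t_hosp
    if age >= params.retirement_age:
        return 0.0
    hours = params.hours_per_week.value_at(age, profile.male)
    wage = params.hourly_labor_cost.value_at(age, profile.male)
    monthly = hours * wage * 52.0 / 12.0
    loss = monthly * params.friction_months_per_hospitalization
    return loss * discount_factor(t_hosp, settings.discount_rate_costs)


def unrelated_medical_costs(
    profile: "PatientProfile",
    t0: float,
    t1: float,
    table: UnrelatedCostTable,
    settings: EconSettings,
) -> float:
    """Discounted unrelated medical costs over [t0, t1], aging through bands."""
    if t1 < t0:
        raise ValueError("need t1 >= t0")
    age0 = profile.age_years + t0
    age1 = profile.age_years + t1
    cuts = [t0] + [e - profile.age_years for e in table.table.edges_between(age0, age1)] + [t1]
    total = 0.0
    for s0, s1 in zip(cuts, cuts[1:]):
        if s1 <= s0:
            continue
        rate = table.table.value_at(profile.age_years + 0.5 * (s0 + s1), profile.male)
        total += continuous_cost(rate, s0, s1, settings.discount_rate_costs)
    return total


@dataclass
class CostBreakdown:
    """Per-component discounted costs for one trajectory."""

    components: dict

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))


def total_costs(
    trajectory: "Trajectory",
    profile: "PatientProfile",
    arm: str,
    costs: CostParams,
    settings: EconSettings,
    productivity: ProductivityParams,
    unrelated: UnrelatedCostTable,
) -> CostBreakdown:
    """All discounted costs of one trajectory, by component.

    Event costs (visits, hospitalizations, alarm management) plus continuous
    flows (other care contacts, drugs, informal care, telemonitoring device
    for HTM-based arms, unrelated medical costs) over [0, death], plus
    friction-cost productivity losses.  The healthcare perspective drops
    travel, informal care, productivity and unrelated medical costs.
    """
    if trajectory.death_time is None:
        raise ValueError("trajectory has no death event")
    r = settings.discount_rate_costs
    societal = settings.perspective == "societal"
    t_death = trajectory.death_time

    comp: dict = {
        "outpatient_visits": 0.0,
        "hospitalizations": 0.0,
        "alarm_management": 0.0,
        "false_alarms": 0.0,
        "other_contacts": 0.0,
        "drugs": 0.0,
        "htm_device": 0.0,
        "informal_care": 0.0,
        "productivity": 0.0,
        "unrelated_medical": 0.0,
    }

    fa_settings = settings
    for event in trajectory.events:
        fa = float(event.payload.get("false_alarms", 0.0))
        if fa > 0.0:
            fa_t = float(event.payload.get("fa_time", event.time_years))
            comp["false_alarms"] += fa * costs.alarm_management * discount_factor(fa_t, r)
        base = event_costs(event, arm, costs, fa_settings)
        fa_part = (
            fa * costs.alarm_management
            * discount_factor(float(event.payload.get("fa_time", event.time_years)), r)
            if fa > 0.0
            else 0.0
        )
        own = base - fa_part
        if event.kind == "outpatient_visit":
            comp["outpatient_visits"] += own
        elif event.kind in ("hospitalization", "death_in_hospital"):
            comp["hospitalizations"] += own
            if societal:
                comp["productivity"] += productivity_loss(
                    profile, event.time_years, productivity, settings
                )
        elif event.kind == "averted_hospitalization":
            comp["alarm_management"] += own

    other = (
        costs.other_contacts_uc_per_year
        if arm == "UC"
        else costs.other_contacts_htm_per_year
    )
    comp["other_contacts"] = continuous_cost(other, 0.0, t_death, r)
    comp["drugs"] = continuous_cost(costs.drugs_per_year, 0.0, t_death, r)
    if arm in HTM_ARMS:
        comp["htm_device"] = continuous_cost(costs.htm_device_per_year, 0.0, t_death, r)
    if societal:
        comp["informal_care"] = continuous_cost(
            costs.informal_care_per_year, 0.0, t_death, r
        )
        comp["unrelated_medical"] = unrelated_medical_costs(
            profile, 0.0, t_death, unrelated, settings
        )
    return CostBreakdown(components=comp)
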