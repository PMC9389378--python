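"""Patient-level discrete event simulation of the three intervention arms.

Each patient is simulated from baseline to death under usual care (UC), home
telemonitoring (HTM), and HTM plus the diagnostic alarm algorithm (HTM_DA).
Competing events are the scheduled outpatient visit (deterministic fixed
interval), the next hospitalization (log-normal in the base case, redrawn
conditionally after every admission or averted admission), and death (Weibull
in the base case, drawn once at baseline).  When the diagnostic algorithm is
enabled, an imminent hospitalization is averted with probability
sensitivity x avoidable-fraction, and false alarms accrue deterministically
as false-positive-rate x days over every inter-event gap.

Common random numbers: every patient owns one substream per stochastic
purpose (death time, hospitalization sequence, alarm interception,
in-hospital death), recreated identically for each arm, so that arm
contrasts are variance-reduced and a null algorithm (sensitivity 0, false
positive rate 0) reproduces the HTM trajectory exactly.  The in-hospital
death uniform is consumed even for averted admissions to keep the streams
aligned across arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import econ as _econ
from . import outcomes as _outcomes
from .cea import ArmResult
from .survival import (
    LogisticModel,
    ParametricSurvival,
    in_hospital_death_probability,
    sample_conditional,
)

__all__ = [
    "DASpec",
    "ArmConfig",
    "EventRecord",
    "Trajectory",
    "ModelSet",
    "ARMS",
    "avoidance_probability",
    "expected_false_alarms",
    "simulate_patient",
    "simulate_cohort",
    "CohortOutput",
]

ARMS = ("UC", "HTM", "HTM_DA")
DAYS_PER_YEAR = 365.25
MAX_EVENTS = 1_000_000

_STREAM_PURPOSE = {"death": 0, "hosp": 1, "da": 2, "ihd": 3}


@dataclass
class DASpec:
    """Diagnostic-algorithm operating characteristics.

    ``sensitivity`` is the probability of flagging a true imminent
    hospitalization; ``false_positive_rate`` is the daily probability of a
    false alarm; ``p_avoidable`` the clinically avoidable fraction of
    flagged admissions.
    """

    sensitivity: float = 0.52
    false_positive_rate: float = 0.03
    p_avoidable: float = 0.50
    enabled: bool = False

    def __post_init__(self):
        for name in ("sensitivity", "false_positive_rate", "p_avoidable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ArmConfig:
    arm: str
    outpatient_interval_months: float
    da: DASpec = field(default_factory=lambda: DASpec(enabled=False))

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not self.outpatient_interval_months > 0:
            raise ValueError("outpatient interval must be > 0")
        if self.arm != "HTM_DA" and self.da.enabled:
            raise ValueError(f"arm {self.arm} cannot enable the diagnostic algorithm")


@dataclass
class EventRecord:
    time_years: float
    kind: str  # outpatient_visit | hospitalization | averted_hospitalization |
    #            death_in_hospital | death_other
    payload: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Timed event log of one patient under one arm."""

    patient_id: int
    arm: str
    events: list[EventRecord]
    death_time: float | None
    total_false_alarms: float = 0.0

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    @property
    def n_hospitalizations(self) -> int:
        """Realized admissions, including the fatal one."""
        return self.count("hospitalization") + self.count("death_in_hospital")

    @property
    def n_averted(self) -> int:
        return self.count("averted_hospitalization")

    @property
    def n_outpatient_visits(self) -> int:
        return self.count("outpatient_visit")


@dataclass
class ModelSet:
    """The event-time and in-hospital mortality models of one configuration."""

    death: ParametricSurvival
    hospitalization: ParametricSurvival | None
    in_hospital_death: LogisticModel | None


def avoidance_probability(da: DASpec) -> float:
    """Overall probability an imminent admission is averted: sens x avoidable."""
    return da.sensitivity * da.p_avoidable


def expected_false_alarms(da: DASpec, gap_days: float) -> float:
    """Deterministic expected false alarms over a monitoring gap (fractional)."""
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    return da.false_positive_rate * gap_days


def _patient_streams(seed: int, patient_index: int) -> dict:
    return {
        name: np.random.default_rng(np.random.SeedSequence((seed, patient_index, code)))
        for name, code in _STREAM_PURPOSE.items()
    }


def simulate_patient(
    profile,
    arm_config: ArmConfig,
    models: ModelSet,
    seed: int,
    patient_index: int | None = None,
    max_events: int = MAX_EVENTS,
) -> Trajectory:
    """Simulate one patient under one arm to death.

    ``patient_index`` (defaulting to ``profile.id``) keys the per-patient
    random substreams; passing the same seed and index for different arms
    yields common random numbers across arms.
    """
    idx = profile.id if patient_index is None else patient_index
    streams = _patient_streams(seed, idx)
    arm = arm_config.arm
    da = arm_config.da
    tau = arm_config.outpatient_interval_months / 12.0
    p_avert = avoidance_probability(da) if da.enabled else 0.0

    # death drawn once at baseline; hospitalization redrawn conditionally
    t_death = sample_conditional(models.death, arm, profile, 0.0, streams["death"])
    t_hosp = (
        sample_conditional(models.hospitalization, arm, profile, 0.0, streams["hosp"])
        if models.hospitalization is not None
        else math.inf
    )
    next_visit = tau

    events: list[EventRecord] = []
    t = 0.0
    n_prior = profile.n_prior_hospitalizations
    total_fa = 0.0

    for _ in range(max_events):
        # competing risks; priority on exact ties: death, hospitalization, visit
        t_next, what = min(
            (t_death, 0, "death"), (t_hosp, 1, "hosp"), (next_visit, 2, "visit"),
            key=lambda c: (c[0], c[1]),
        )[0::2]
        payload = {}
        if da.enabled and da.false_positive_rate > 0.0:
            fa = expected_false_alarms(da, (t_next - t) * DAYS_PER_YEAR)
            if fa > 0.0:
                payload = {"false_alarms": fa, "fa_time": 0.5 * (t + t_next)}
                total_fa += fa

        if what == "death":
            events.append(EventRecord(t_next, "death_other", payload))
            return Trajectory(profile.id, arm, events, t_next, total_fa)

        if what == "visit":
            events.append(EventRecord(t_next, "outpatient_visit", payload))
            next_visit += tau
            t = t_next
            continue

        # hospitalization candidate
        u_intercept = streams["da"].uniform() if da.enabled else 1.0
        u_death = streams["ihd"].uniform()  # consumed regardless, for CRN alignment
        if da.enabled and u_intercept < p_avert:
            events.append(EventRecord(t_next, "averted_hospitalization", payload))
        else:
            if models.in_hospital_death is not None:
                p_die = in_hospital_death_probability(
                    models.in_hospital_death,
                    profile,
                    overrides={"n_prior_hospitalizations": n_prior},
                )
            else:
                p_die = 0.0
            if u_death < p_die:
                events.append(EventRecord(t_next, "death_in_hospital", payload))
                return Trajectory(profile.id, arm, events, t_next, total_fa)
            events.append(EventRecord(t_next, "hospitalization", payload))
            n_prior += 1
        t_hosp = sample_conditional(
            models.hospitalization, arm, profile, t_next, streams["hosp"]
        )
        t = t_next

    raise RuntimeError(f"simulation exceeded {max_events} events without death")


@dataclass
class CohortOutput:
    per_arm: dict  # arm -> ArmResult
    trajectories: dict  # arm -> list[Trajectory] (empty when not kept)
    per_patient: dict  # arm -> list of (cost, life_years, qalys) tuples


def simulate_cohort(
    cohort: Sequence,
    config,
    seed: int,
    arms: Sequence[str] = ARMS,
    keep_trajectories: bool = False,
) -> CohortOutput:
    """Simulate every patient under every arm with common random numbers.

    ``config`` is a :class:`hfsim.config.ModelConfig` (or an object exposing
    the same attributes).  Aggregates per arm follow the base-case reporting:
    discounted mean costs, life years and QALYs; yearly event rates as total
    events over undiscounted person-years; and death-type proportions.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one patient")
    models = config.model_set()
    econ_settings = config.econ
    per_arm: dict = {}
    all_traj: dict = {}
    per_patient: dict = {}

    for arm in arms:
        arm_cfg = config.arm_config(arm)
        costs_sum = 0.0
        ly_sum = qaly_sum = 0.0
        uly_sum = uqaly_sum = 0.0
        person_years = 0.0
        visits = hosps = averted = 0
        deaths_hospital = 0
        trajs: list[Trajectory] = []
        pp: list[tuple] = []
        for i, profile in enumerate(cohort):
            traj = simulate_patient(profile, arm_cfg, models, seed, patient_index=i)
            breakdown = _econ.total_costs(
                traj, profile, arm, config.costs, econ_settings,
                config.productivity, config.unrelated,
            )
            cost = breakdown.total
            ly = _outcomes.life_years(traj.death_time, econ_settings.discount_rate_effects)
            qaly = _outcomes.discounted_qalys(
                traj, profile, config.utilities, econ_settings.discount_rate_effects
            )
            uly = traj.death_time
            uqaly = _outcomes.discounted_qalys(traj, profile, config.utilities, 0.0)
            costs_sum += cost
            ly_sum += ly
            qaly_sum += qaly
            uly_sum += uly
            uqaly_sum += uqaly
            person_years += traj.death_time
            visits += traj.n_outpatient_visits
            hosps += traj.n_hospitalizations
            averted += traj.n_averted
            deaths_hospital += 1 if traj.events[-1].kind == "death_in_hospital" else 0
            pp.append((cost, ly, qaly))
            if keep_trajectories:
                trajs.append(traj)
        n = len(cohort)
        per_arm[arm] = ArmResult(
            arm=arm,
            n_patients=n,
            mean_cost=costs_sum / n,
            mean_life_years=ly_sum / n,
            mean_qalys=qaly_sum / n,
            mean_undiscounted_life_years=uly_sum / n,
            mean_undiscounted_qalys=uqaly_sum / n,
            visit_rate=visits / person_years,
            hospitalization_rate=hosps / person_years,
            averted_rate=averted / person_years,
            death_in_hospital_frac=deaths_hospital / n,
            death_other_frac=(n - deaths_hospital) / n,
        )
        all_traj[arm] = trajs
        per_patient[arm] = pp
    return CohortOutput(per_arm=per_arm, trajectories=all_traj, per_patient=per_patient)
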