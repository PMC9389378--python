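"""Experiment orchestration: diagnostic-algorithm operating-point sweep,
the 26 patient subgroups, and named scenario runs.

Every experiment is reproducible bit-for-bit given (config, cohort, seed):
the same common-random-number seed is used at every ROC point, subgroup and
scenario, so differences between runs are attributable to the varied inputs
rather than Monte Carlo noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import cea as _cea
from .config import ModelConfig, get_param, set_param
from .engine import ARMS, simulate_cohort
from .population import filter_subgroup, generate_population, subgroup_names
from .survival import ParametricSurvival

__all__ = [
    "ROCCurve",
    "ScenarioResult",
    "default_roc_curve",
    "sweep_da_operating_points",
    "run_subgroups",
    "run_scenarios",
    "builtin_scenarios",
    "matched_exponential",
]


@dataclass
class ROCCurve:
    """Operating points (false-positive rate, sensitivity) of the alarm."""

    points: tuple  # ((fpr, sensitivity), ...)

    def __post_init__(self):
        pts = tuple((float(f), float(s)) for f, s in self.points)
        if not pts:
            raise ValueError("ROC curve must contain at least one point")
        for f, s in pts:
            if not (0.0 <= f <= 1.0 and 0.0 <= s <= 1.0):
                raise ValueError(f"ROC point ({f}, {s}) outside the unit square")
        for (f0, s0), (f1, s1) in zip(pts, pts[1:]):
            if f1 < f0 or s1 < s0:
                raise ValueError(
                    "ROC points must be non-decreasing in both coordinates; "
                    f"({f1}, {s1}) follows ({f0}, {s0})"
                )
        self.points = pts

    def augmented(self) -> "ROCCurve":
        """Curve with the corner points (0,0) and (1,1) guaranteed present."""
        pts = list(self.points)
        if pts[0] != (0.0, 0.0):
            pts.insert(0, (0.0, 0.0))
        if pts[-1] != (1.0, 1.0):
            pts.append((1.0, 1.0))
        return ROCCurve(tuple(pts))

    @classmethod
    def from_csv(cls, path) -> "ROCCurve":
        df = pd.read_csv(path)
        for col in ("fpr", "sensitivity"):
            if col not in df.columns:
                raise ValueError(f"{path}: ROC CSV needs columns fpr,sensitivity")
        return cls(tuple(zip(df["fpr"], df["sensitivity"])))


def default_roc_curve() -> ROCCurve:
    """The operating points examined in the alarm-threshold analysis."""
    return ROCCurve(
        (
            (0.007, 0.200),
            (0.024, 0.400),
            (0.030, 0.520),  # base case
            (0.068, 0.600),
            (0.194, 0.800),
            (0.562, 0.950),
        )
    )


@dataclass
class ScenarioResult:
    scenario: str
    per_arm: dict  # arm -> ArmResult
    icer_vs_uc: float | None
    pct_change_vs_base: float | None
    overrides: dict = field(default_factory=dict)
    note: str = ""

    def row(self) -> dict:
        out = {"scenario": self.scenario, "icer_vs_uc": self.icer_vs_uc,
               "pct_change_vs_base": self.pct_change_vs_base, "note": self.note}
        for arm, res in self.per_arm.items():
            out[f"cost_{arm}"] = res.mean_cost
            out[f"qalys_{arm}"] = res.mean_qalys
        return out


def _run(config, cohort, seed, arms) -> dict:
    return simulate_cohort(cohort, config, seed, arms=arms).per_arm


def _icer_vs_uc(per_arm) -> float | None:
    uc, da = per_arm["UC"], per_arm["HTM_DA"]
    return _cea.icer(da.mean_cost - uc.mean_cost, da.mean_qalys - uc.mean_qalys)


def sweep_da_operating_points(
    roc: ROCCurve,
    config: ModelConfig,
    cohort,
    seed: int,
    arms: Sequence[str] = ("UC", "HTM_DA"),
):
    """Run the model at each alarm operating point; return results and argmin.

    Every point reuses the same seed (common random numbers), so averted
    hospitalizations rise monotonically with sensitivity.  Returns
    ``(results, best)`` where ``best`` is the point with the lowest ICER of
    HTM+DA versus usual care (undefined ICERs excluded).
    """
    base_per_arm = _run(config, cohort, seed, arms)
    base_icer = _icer_vs_uc(base_per_arm)
    results = []
    for fpr, sens in roc.points:
        cfg = config.copy()
        cfg.da = dataclasses.replace(cfg.da, sensitivity=sens, false_positive_rate=fpr)
        per_arm = _run(cfg, cohort, seed, arms)
        this_icer = _icer_vs_uc(per_arm)
        pct = (
            _cea.percent_change(this_icer, base_icer)
            if this_icer is not None and base_icer not in (None, 0)
            else None
        )
        results.append(
            ScenarioResult(
                scenario=f"sens={sens:.3f},fpr={fpr:.3f}",
                per_arm=per_arm,
                icer_vs_uc=this_icer,
                pct_change_vs_base=pct,
                overrides={"da.sensitivity": sens, "da.false_positive_rate": fpr},
            )
        )
    defined = [r for r in results if r.icer_vs_uc is not None]
    best = min(defined, key=lambda r: r.icer_vs_uc) if defined else None
    return results, best


def run_subgroups(
    config: ModelConfig,
    seed: int,
    criteria: Sequence[str] | None = None,
    n_pool: int = 10_000,
    n_run: int = 1_000,
    arms: Sequence[str] = ARMS,
) -> list[ScenarioResult]:
    """Three-arm runs for each named subgroup of a generated pool.

    A pool of ``n_pool`` patients is generated from the configured moments;
    each subgroup is formed by filtering and then resampling ``n_run``
    patients with replacement (mirroring the base-case run size).  Empty
    subgroups are recorded as not estimable.  The base-case row (whole
    population) is included first for reference.
    """
    criteria = list(criteria) if criteria is not None else subgroup_names()
    pool = generate_population(config.population, n_pool, seed, config.productivity)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))

    def resampled(source):
        idx = rng.integers(0, len(source), size=n_run)
        return [source[i] for i in idx]

    results = []
    base_per_arm = _run(config, resampled(pool), seed, arms)
    base_icer = _icer_vs_uc(base_per_arm)
    results.append(
        ScenarioResult("base_case", base_per_arm, base_icer, 0.0)
    )
    for name in criteria:
        sub = filter_subgroup(pool, name)
        if not sub:
            results.append(
                ScenarioResult(name, {}, None, None, note="not estimable: empty subgroup")
            )
            continue
        per_arm = _run(config, resampled(sub), seed, arms)
        this_icer = _icer_vs_uc(per_arm)
        pct = (
            _cea.percent_change(this_icer, base_icer)
            if this_icer is not None and base_icer not in (None, 0)
            else None
        )
        results.append(ScenarioResult(name, per_arm, this_icer, pct))
    return results


def matched_exponential(model: ParametricSurvival) -> ParametricSurvival:
    """Exponential alternative with the same baseline mean event time."""
    if model.family == "exponential":
        return model
    if model.family == "weibull":
        shape, scale = model.params
        mean = scale * special.gamma(1.0 + 1.0 / shape)
    elif model.family == "lognormal":
        mu, s = model.params
        mean = math.exp(mu + 0.5 * s * s)
    else:
        raise ValueError(f"no closed-form mean matching for family {model.family!r}")
    return ParametricSurvival(
        family="exponential",
        params=(1.0 / mean,),
        log_hr_treatment=dict(model.log_hr_treatment),
        covariate_log_hrs=dict(model.covariate_log_hrs),
    )


def builtin_scenarios(config: ModelConfig) -> dict:
    """Named structural scenarios: override dictionaries keyed by scenario id.

    Covers the healthcare perspective, all costs at their low/high bounds,
    outpatient intervals at their bounds, a transient utility decrement, and
    mean-matched exponential alternatives for the event-time families.
    """
    cost_bounds = {
        "costs.outpatient_visit_uc": (30.94, 60.08),
        "costs.outpatient_visit_htm": (30.11, 58.46),
        "costs.other_contacts_uc_per_year": (130.98, 254.33),
        "costs.other_contacts_htm_per_year": (433.59, 841.93),
        "costs.hospitalization": (3062.36, 5946.44),
        "costs.htm_device_per_year": (1059.87, 1469.69),
        "costs.alarm_management": (12.78, 24.81),
        "costs.drugs_per_year": (199.16, 386.72),
        "costs.travel_outpatient": (2.61, 5.06),
        "costs.travel_hospitalization": (3.25, 6.32),
        "costs.informal_care_per_year": (1458.90, 2832.88),
    }
    scenarios = {
        "base_case": {},
        "healthcare_perspective": {"econ.perspective": "healthcare"},
        "all_costs_low": {path: lo for path, (lo, _) in cost_bounds.items()},
        "all_costs_high": {path: hi for path, (_, hi) in cost_bounds.items()},
        "outpatient_intervals_low": {
            "outpatient_interval_uc_months": 2.46,
            "outpatient_interval_htm_months": 1.59,
        },
        "outpatient_intervals_high": {
            "outpatient_interval_uc_months": 3.13,
            "outpatient_interval_htm_months": 1.79,
        },
        "transient_hospital_disutility": {"utilities.permanent_decrement": False},
        "death_exponential": {"death_model": matched_exponential(config.death_model)},
    }
    if config.hospitalization_model is not None:
        scenarios["hospitalization_exponential"] = {
            "hospitalization_model": matched_exponential(config.hospitalization_model)
        }
    return scenarios


def run_scenarios(
    overrides_by_scenario: dict,
    config: ModelConfig,
    cohort,
    seed: int,
    arms: Sequence[str] = ARMS,
) -> list[ScenarioResult]:
    """One run per named scenario, overrides applied to a config copy.

    Every override path is validated against the configuration before any
    simulation runs; unknown keys raise immediately.  The base case is always
    included as reference even if absent from the input mapping.
    """
    for name, overrides in overrides_by_scenario.items():
        for path in overrides:
            get_param(config, path)  # raises KeyError on unknown paths

    items = dict(overrides_by_scenario)
    if "base_case" not in items:
        items = {"base_case": {}, **items}

    base_per_arm = _run(config, cohort, seed, arms)
    base_icer = _icer_vs_uc(base_per_arm)

    results = []
    for name, overrides in items.items():
        cfg = config.copy()
        for path, value in overrides.items():
            set_param(cfg, path, value)
        per_arm = base_per_arm if not overrides else _run(cfg, cohort, seed, arms)
        this_icer = _icer_vs_uc(per_arm)
        pct = (
            _cea.percent_change(this_icer, base_icer)
            if this_icer is not None and base_icer not in (None, 0)
            else None
        )
        results.append(ScenarioResult(name, per_arm, this_icer, pct, overrides=dict(overrides)))
    return results
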