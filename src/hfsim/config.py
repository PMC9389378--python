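"""Model configuration: defaults, (de)serialization, and parameter paths.

A :class:`ModelConfig` bundles every input of the simulation: population
moments, event-time models, the in-hospital mortality logistic, arm settings,
the diagnostic-algorithm operating point, unit costs, discounting,
productivity and unrelated-cost tables, utilities and the threshold bands.

Survival and logistic coefficients are illustrative defaults: the fitted
equations of the underlying trial model are not published, so the shipped
values are calibrated only to give usual-care life expectancy and
hospitalization rates of a realistic order for a severe heart-failure
population (about 2.3 undiscounted years and 1.7 admissions/year).  They are
clearly not fitted estimates and every analysis accepts replacements.

Scenario and sensitivity machinery addresses parameters by dotted paths,
e.g. ``"costs.hospitalization"`` or ``"utilities.nyha_utilities.0"``.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cea import DEFAULT_THRESHOLD_BANDS
from .econ import (
    AgeSexTable,
    CostParams,
    EconSettings,
    ProductivityParams,
    UnrelatedCostTable,
)
from .engine import ArmConfig, DASpec, ModelSet
from .outcomes import UtilityParams
from .population import PopulationMoments, default_moments
from .survival import LogisticModel, ParametricSurvival

__all__ = [
    "ModelConfig",
    "default_config",
    "load_config",
    "save_config",
    "get_param",
    "set_param",
]


def _default_death_model() -> ParametricSurvival:
    # Weibull baseline (usual care); HTM-based arms share one hazard ratio.
    # Illustrative, not fitted: with the default in-hospital mortality this
    # gives ~2.4 undiscounted usual-care life years.
    return ParametricSurvival(
        family="weibull",
        params=(1.2, 4.0),
        log_hr_treatment={"HTM": math.log(0.70), "HTM_DA": math.log(0.70)},
    )


def _default_hosp_model() -> ParametricSurvival:
    # log-normal inter-admission gaps; illustrative, ~1.65 admissions/y under
    # usual care once in-hospital mortality truncates the sequence
    return ParametricSurvival(
        family="lognormal",
        params=(-1.3, 0.9),
        log_hr_treatment={"HTM": math.log(0.92), "HTM_DA": math.log(0.92)},
    )


def _default_logistic() -> LogisticModel:
    # illustrative in-hospital mortality (~0.07 for a typical patient)
    return LogisticModel(
        intercept=-4.8,
        coefficients={
            "age_years": 0.025,
            "male": 0.30,
            "myocardial_infarction": 0.30,
            "chronic_af": 0.25,
            "diabetes": 0.25,
            "copd": 0.25,
            "n_prior_hospitalizations": 0.10,
        },
    )


@dataclass
class ModelConfig:
    population: PopulationMoments = field(default_factory=default_moments)
    death_model: ParametricSurvival = field(default_factory=_default_death_model)
    hospitalization_model: ParametricSurvival | None = field(
        default_factory=_default_hosp_model
    )
    in_hospital_death_model: LogisticModel | None = field(default_factory=_default_logistic)
    outpatient_interval_uc_months: float = 2.81
    outpatient_interval_htm_months: float = 1.69
    da: DASpec = field(default_factory=lambda: DASpec(enabled=True))
    costs: CostParams = field(default_factory=CostParams)
    econ: EconSettings = field(default_factory=EconSettings)
    productivity: ProductivityParams = field(default_factory=ProductivityParams)
    unrelated: UnrelatedCostTable = field(default_factory=UnrelatedCostTable)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    threshold_bands: tuple = DEFAULT_THRESHOLD_BANDS

    def model_set(self) -> ModelSet:
        return ModelSet(
            death=self.death_model,
            hospitalization=self.hospitalization_model,
            in_hospital_death=self.in_hospital_death_model,
        )

    def arm_config(self, arm: str) -> ArmConfig:
        if arm == "UC":
            return ArmConfig("UC", self.outpatient_interval_uc_months)
        if arm == "HTM":
            return ArmConfig("HTM", self.outpatient_interval_htm_months)
        if arm == "HTM_DA":
            da = dataclasses.replace(self.da, enabled=True)
            return ArmConfig("HTM_DA", self.outpatient_interval_htm_months, da)
        raise ValueError(f"unknown arm {arm!r}")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


def default_config() -> ModelConfig:
    return ModelConfig()


# ---------------------------------------------------------------------------
# dotted parameter paths (used by DSA, PSA and scenario overrides)
# ---------------------------------------------------------------------------


def _walk(config, path: str):
    obj = config
    parts = path.split(".")
    for part in parts[:-1]:
        obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
    return obj, parts[-1]


def get_param(config: ModelConfig, path: str):
    """Value at a dotted path, e.g. ``costs.hospitalization``."""
    try:
        obj, last = _walk(config, path)
        if last.isdigit():
            return obj[int(last)]
        return getattr(obj, last)
    except (AttributeError, IndexError, TypeError) as exc:
        raise KeyError(f"no config parameter at path {path!r}: {exc}") from None


def set_param(config: ModelConfig, path: str, value) -> None:
    """Set the value at a dotted path in place (tuples are rebuilt)."""
    get_param(config, path)  # validate path before mutating
    obj, last = _walk(config, path)
    if last.isdigit():
        i = int(last)
        if isinstance(obj, tuple):
            parent_path = path.rsplit(".", 1)[0]
            new = obj[:i] + (value,) + obj[i + 1 :]
            set_param(config, parent_path, new)
        else:
            obj[i] = value
    else:
        current = getattr(obj, last)
        if isinstance(current, tuple) and not isinstance(value, tuple):
            value = tuple(value)
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _table_to_dict(t: AgeSexTable) -> dict:
    return {"bands": [list(b) for b in t.bands], "male": list(t.male), "female": list(t.female)}


def _table_from_dict(d: dict) -> AgeSexTable:
    return AgeSexTable(
        bands=tuple(tuple(b) for b in d["bands"]),
        male=tuple(d["male"]),
        female=tuple(d["female"]),
    )


def config_to_dict(config: ModelConfig) -> dict:
    def survival_dict(m):
        if m is None:
            return None
        return {
            "family": m.family,
            "params": list(m.params),
            "log_hr_treatment": dict(m.log_hr_treatment),
            "covariate_log_hrs": dict(m.covariate_log_hrs),
        }

    p = config.population
    return {
        "population": {
            "n_reference": p.n_reference,
            "continuous": {k: list(v) for k, v in p.continuous.items()},
            "truncation": {k: list(v) for k, v in p.truncation.items()},
            "nyha_proportions": list(p.nyha_proportions),
            "binary": dict(p.binary),
        },
        "death_model": survival_dict(config.death_model),
        "hospitalization_model": survival_dict(config.hospitalization_model),
        "in_hospital_death_model": (
            None
            if config.in_hospital_death_model is None
            else {
                "intercept": config.in_hospital_death_model.intercept,
                "coefficients": dict(config.in_hospital_death_model.coefficients),
            }
        ),
        "outpatient_interval_uc_months": config.outpatient_interval_uc_months,
        "outpatient_interval_htm_months": config.outpatient_interval_htm_months,
        "da": dataclasses.asdict(config.da),
        "costs": dataclasses.asdict(config.costs),
        "econ": dataclasses.asdict(config.econ),
        "productivity": {
            "working_prob_by_nyha": list(config.productivity.working_prob_by_nyha),
            "labor_participation": _table_to_dict(config.productivity.labor_participation),
            "hours_per_week": _table_to_dict(config.productivity.hours_per_week),
            "hourly_labor_cost": _table_to_dict(config.productivity.hourly_labor_cost),
            "friction_months_per_hospitalization": config.productivity.friction_months_per_hospitalization,
            "retirement_age": config.productivity.retirement_age,
        },
        "unrelated": {"table": _table_to_dict(config.unrelated.table)},
        "utilities": {
            "nyha_utilities": list(config.utilities.nyha_utilities),
            "nyha_utility_ses": list(config.utilities.nyha_utility_ses),
            "hosp_multiplier": config.utilities.hosp_multiplier,
            "max_hosp_decrements": config.utilities.max_hosp_decrements,
            "outpatient_multiplier": config.utilities.outpatient_multiplier,
            "general_population_coefficients": list(
                config.utilities.general_population_coefficients
            ),
            "permanent_decrement": config.utilities.permanent_decrement,
        },
        "threshold_bands": [list(b) for b in config.threshold_bands],
    }


def config_from_dict(d: dict) -> ModelConfig:
    def survival(sd):
        if sd is None:
            return None
        return ParametricSurvival(
            family=sd["family"],
            params=tuple(sd["params"]),
            log_hr_treatment=dict(sd.get("log_hr_treatment", {})),
            covariate_log_hrs=dict(sd.get("covariate_log_hrs", {})),
        )

    p = d["population"]
    population = PopulationMoments(
        n_reference=int(p["n_reference"]),
        continuous={k: tuple(v) for k, v in p["continuous"].items()},
        truncation={k: tuple(v) for k, v in p["truncation"].items()},
        nyha_proportions=tuple(p["nyha_proportions"]),
        binary=dict(p["binary"]),
    )
    logistic = d.get("in_hospital_death_model")
    prod = d["productivity"]
    return ModelConfig(
        population=population,
        death_model=survival(d["death_model"]),
        hospitalization_model=survival(d["hospitalization_model"]),
        in_hospital_death_model=(
            None
            if logistic is None
            else LogisticModel(
                intercept=float(logistic["intercept"]),
                coefficients=dict(logistic["coefficients"]),
            )
        ),
        outpatient_interval_uc_months=float(d["outpatient_interval_uc_months"]),
        outpatient_interval_htm_months=float(d["outpatient_interval_htm_months"]),
        da=DASpec(**d["da"]),
        costs=CostParams(**d["costs"]),
        econ=EconSettings(**d["econ"]),
        productivity=ProductivityParams(
            working_prob_by_nyha=tuple(prod["working_prob_by_nyha"]),
            labor_participation=_table_from_dict(prod["labor_participation"]),
            hours_per_week=_table_from_dict(prod["hours_per_week"]),
            hourly_labor_cost=_table_from_dict(prod["hourly_labor_cost"]),
            friction_months_per_hospitalization=float(
                prod["friction_months_per_hospitalization"]
            ),
            retirement_age=float(prod["retirement_age"]),
        ),
        unrelated=UnrelatedCostTable(table=_table_from_dict(d["unrelated"]["table"])),
        utilities=UtilityParams(
            nyha_utilities=tuple(d["utilities"]["nyha_utilities"]),
            nyha_utility_ses=tuple(d["utilities"]["nyha_utility_ses"]),
            hosp_multiplier=float(d["utilities"]["hosp_multiplier"]),
            max_hosp_decrements=int(d["utilities"]["max_hosp_decrements"]),
            outpatient_multiplier=float(d["utilities"]["outpatient_multiplier"]),
            general_population_coefficients=tuple(
                d["utilities"]["general_population_coefficients"]
            ),
            permanent_decrement=bool(d["utilities"].get("permanent_decrement", True)),
        ),
        threshold_bands=tuple(tuple(b) for b in d["threshold_bands"]),
    )


def save_config(config: ModelConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path) -> ModelConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return config_from_dict(d)
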