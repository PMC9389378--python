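"""Parameter uncertainty: deterministic and probabilistic sensitivity
analysis, acceptability curves, and expected value of perfect information.

The probabilistic analysis is a double loop: the outer loop draws one
parameter set per iteration (normal draws direct; gamma and beta
moment-matched from mean and SE; probability-like normals truncated to their
valid range), the inner loop resamples patients with replacement from the
baseline cohort and simulates all arms with common random numbers.
Event-time model coefficients stay fixed in the probabilistic analysis —
their structural uncertainty is covered by scenario switches instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cea as _cea
from .config import ModelConfig, get_param, set_param
from .engine import ARMS, simulate_cohort

__all__ = [
    "ParamDistribution",
    "PSAConfig",
    "PSAIteration",
    "PSAResult",
    "EVPIConfig",
    "default_distributions",
    "draw_parameter_set",
    "run_dsa",
    "run_psa",
    "ceac",
    "evpi_per_patient",
    "discounted_population",
    "population_evpi",
]


@dataclass
class ParamDistribution:
    """Sampling/bound specification of one scalar parameter.

    ``path`` addresses the parameter in :class:`~hfsim.config.ModelConfig`
    dotted-path form.  ``family`` is one of normal/gamma/beta/fixed; ``se``
    is the absolute standard error; ``low``/``high`` are the deterministic
    sensitivity bounds (95% CI); ``trunc_low``/``trunc_high`` optionally clip
    draws (used for probability-like normal parameters).
    """

    path: str
    mean: float
    family: str = "fixed"
    se: float = 0.0
    low: float | None = None
    high: float | None = None
    trunc_low: float | None = None
    trunc_high: float | None = None

    def __post_init__(self):
        if self.family not in ("normal", "gamma", "beta", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.low is not None and self.high is not None:
            if not self.low <= self.mean <= self.high:
                raise ValueError(
                    f"{self.path}: bounds ({self.low}, {self.high}) must bracket the mean"
                )
        if self.family == "gamma" and self.mean <= 0 and self.se > 0:
            raise ValueError(f"{self.path}: gamma requires a positive mean")
        if self.family == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ValueError(f"{self.path}: beta requires mean in (0, 1)")
            if self.se > 0 and self.se**2 >= self.mean * (1.0 - self.mean):
                raise ValueError(
                    f"{self.path}: beta moments infeasible (SE^2 >= mean(1-mean))"
                )

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "fixed" or self.se == 0.0:
            return self.mean
        if self.family == "normal":
            x = rng.normal(self.mean, self.se)
        elif self.family == "gamma":
            shape = (self.mean / self.se) ** 2
            scale = self.se**2 / self.mean
            x = rng.gamma(shape, scale)
        else:  # beta, moment matched
            m, v = self.mean, self.se**2
            nu = m * (1.0 - m) / v - 1.0
            x = rng.beta(m * nu, (1.0 - m) * nu)
        if self.trunc_low is not None:
            x = max(x, self.trunc_low)
        if self.trunc_high is not None:
            x = min(x, self.trunc_high)
        return float(x)


def _rel(mean, frac):
    return mean * frac


def default_distributions() -> list[ParamDistribution]:
    """The base-case parameter uncertainty specification.

    Relative SEs (10% or 20% of the mean) and the deterministic 95% CI
    bounds follow the published input table; discount rates enter the
    deterministic analysis only.
    """
    P = ParamDistribution
    return [
        P("econ.discount_rate_costs", 0.04, "fixed", 0.0, 0.0, 0.08),
        P("econ.discount_rate_effects", 0.015, "fixed", 0.0, 0.0, 0.03),
        P("outpatient_interval_uc_months", 2.81, "normal", _rel(2.81, 0.10), 2.46, 3.13),
        P("outpatient_interval_htm_months", 1.69, "normal", _rel(1.69, 0.10), 1.59, 1.79),
        P("da.p_avoidable", 0.50, "normal", _rel(0.50, 0.20), 0.336, 0.664, 0.0, 1.0),
        P("costs.outpatient_visit_uc", 44.50, "gamma", _rel(44.50, 0.20), 30.94, 60.08),
        P("costs.outpatient_visit_htm", 43.30, "gamma", _rel(43.30, 0.20), 30.11, 58.46),
        P("costs.other_contacts_uc_per_year", 188.38, "gamma", _rel(188.38, 0.20), 130.98, 254.33),
        P("costs.other_contacts_htm_per_year", 623.61, "gamma", _rel(623.61, 0.20), 433.59, 841.93),
        P("costs.hospitalization", 4404.46, "gamma", _rel(4404.46, 0.20), 3062.36, 5946.44),
        P("costs.htm_device_per_year", 1257.75, "gamma", _rel(1257.75, 0.20), 1059.87, 1469.69),
        P("costs.alarm_management", 18.38, "gamma", _rel(18.38, 0.20), 12.78, 24.81),
        P("costs.drugs_per_year", 286.44, "gamma", _rel(286.44, 0.20), 199.16, 386.72),
        P("costs.travel_outpatient", 3.75, "gamma", _rel(3.75, 0.20), 2.61, 5.06),
        P("costs.travel_hospitalization", 4.68, "gamma", _rel(4.68, 0.20), 3.25, 6.32),
        P("costs.informal_care_per_year", 2098.28, "gamma", _rel(2098.28, 0.20), 1458.90, 2832.88),
        P("utilities.nyha_utilities.0", 0.87976, "beta", 0.00827, 0.86588, 0.89308),
        P("utilities.nyha_utilities.1", 0.71178, "beta", 0.00944, 0.69615, 0.72720),
        P("utilities.nyha_utilities.2", 0.61405, "beta", 0.01349, 0.59176, 0.63614),
        P("utilities.nyha_utilities.3", 0.49228, "beta", 0.03032, 0.44243, 0.54220),
        P("utilities.hosp_multiplier", 0.82, "normal", _rel(0.82, 0.10), 0.69, 0.95, 0.0, 1.0),
    ]


def draw_parameter_set(
    distributions: Sequence[ParamDistribution], rng: np.random.Generator
) -> dict:
    """One joint (independent) draw of all parameters: path -> value."""
    return {d.path: d.draw(rng) for d in distributions}


def _apply(config: ModelConfig, values: dict) -> ModelConfig:
    cfg = config.copy()
    for path, value in values.items():
        set_param(cfg, path, value)
    return cfg


def _icer_da_vs_uc(config, cohort, seed) -> float | None:
    out = simulate_cohort(cohort, config, seed, arms=("UC", "HTM_DA"))
    uc, da = out.per_arm["UC"], out.per_arm["HTM_DA"]
    return _cea.icer(da.mean_cost - uc.mean_cost, da.mean_qalys - uc.mean_qalys)


def run_dsa(
    config: ModelConfig,
    cohort,
    distributions: Sequence[ParamDistribution],
    seed: int,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Each parameter with bounds is set to its low and high bound in turn
    (all else at base, common random numbers), recording the ICER of
    HTM+DA versus usual care; rows sorted by ICER range, widest first.
    Parameters without bounds are skipped.
    """
    rows = []
    base_icer = _icer_da_vs_uc(config, cohort, seed)
    for dist in distributions:
        if dist.low is None or dist.high is None:
            continue
        icer_lo = _icer_da_vs_uc(_apply(config, {dist.path: dist.low}), cohort, seed)
        icer_hi = _icer_da_vs_uc(_apply(config, {dist.path: dist.high}), cohort, seed)
        rows.append(
            {
                "parameter": dist.path,
                "low": dist.low,
                "high": dist.high,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "icer_base": base_icer,
                "range": abs((icer_hi or np.nan) - (icer_lo or np.nan)),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("range", ascending=False, ignore_index=True)


@dataclass
class PSAConfig:
    inner_n_patients: int = 100
    outer_iterations: int = 500
    seed: int = 0
    lambda_grid: tuple = tuple(range(0, 160_001, 5_000))

    def __post_init__(self):
        if self.inner_n_patients < 1 or self.outer_iterations < 1:
            raise ValueError("inner and outer sizes must be >= 1")


@dataclass
class PSAIteration:
    index: int
    params: dict
    mean_cost: dict  # arm -> euros
    mean_qalys: dict  # arm -> QALYs
    sim_seed: int
    indices: np.ndarray


@dataclass
class PSAResult:
    iterations: list

    @property
    def arms(self):
        return list(self.iterations[0].mean_cost)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"iteration": it.index, "arm": arm,
             "mean_cost": it.mean_cost[arm], "mean_qalys": it.mean_qalys[arm]}
            for it in self.iterations
            for arm in it.mean_cost
        ]
        return pd.DataFrame(rows)

    def nmb_matrix(self, lam: float) -> np.ndarray:
        """iterations x arms net monetary benefit."""
        arms = self.arms
        return np.array(
            [
                [_cea.nmb(it.mean_cost[a], it.mean_qalys[a], lam) for a in arms]
                for it in self.iterations
            ]
        )


def iteration_sim_seed(base_seed: int, iteration: int) -> int:
    """Derived per-iteration simulation seed (stable, below 2**31)."""
    return int(np.random.SeedSequence((base_seed, iteration, 7)).generate_state(1)[0] % (2**31))


def run_psa(
    psa_config: PSAConfig,
    distributions: Sequence[ParamDistribution],
    config: ModelConfig,
    cohort,
    arms: Sequence[str] = ARMS,
) -> PSAResult:
    """Double-loop probabilistic sensitivity analysis."""
    iterations = []
    for i in range(psa_config.outer_iterations):
        rng = np.random.default_rng(np.random.SeedSequence((psa_config.seed, i)))
        values = draw_parameter_set(distributions, rng)
        cfg = _apply(config, values)
        indices = rng.integers(0, len(cohort), size=psa_config.inner_n_patients)
        resample = [cohort[j] for j in indices]
        sim_seed = iteration_sim_seed(psa_config.seed, i)
        out = simulate_cohort(resample, cfg, sim_seed, arms=arms)
        iterations.append(
            PSAIteration(
                index=i,
                params=values,
                mean_cost={a: out.per_arm[a].mean_cost for a in arms},
                mean_qalys={a: out.per_arm[a].mean_qalys for a in arms},
                sim_seed=sim_seed,
                indices=indices,
            )
        )
    return PSAResult(iterations=iterations)


def ceac(psa: PSAResult, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay the fraction of iterations in which each arm
    attains the maximal net monetary benefit; exact ties split equally, so
    probabilities sum to one at every grid point.
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    if not psa.iterations:
        raise ValueError("empty PSA result")
    arms = psa.arms
    rows = []
    for lam in lambda_grid:
        nmb = psa.nmb_matrix(lam)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-12
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for a, p in zip(arms, probs):
            rows.append({"lambda": float(lam), "arm": a, "probability": float(p)})
    return pd.DataFrame(rows)


def evpi_per_patient(psa: PSAResult, lam: float) -> float:
    """Mean over iterations of the best NMB minus the best mean NMB (>= 0)."""
    if not psa.iterations:
        raise ValueError("empty PSA result")
    nmb = psa.nmb_matrix(lam)
    return float(nmb.max(axis=1).mean() - nmb.mean(axis=0).max())


@dataclass
class EVPIConfig:
    """Eligible-population projection for the population EVPI."""

    yearly_eligible_patients: tuple = (53_140, 55_009, 56_943, 58_946, 61_019)
    discount_rate: float = 0.04
    horizon_years: int = 5

    def __post_init__(self):
        if any(c <= 0 for c in self.yearly_eligible_patients):
            raise ValueError("eligible patient counts must be > 0")


def discounted_population(config: EVPIConfig) -> int:
    """Discounted eligible population; the first yearly cohort is one year out."""
    counts = config.yearly_eligible_patients[: config.horizon_years]
    total = sum(
        c * (1.0 + config.discount_rate) ** (-(k + 1)) for k, c in enumerate(counts)
    )
    return round(total)


def population_evpi(evpi_pp: float, population: float) -> float:
    if evpi_pp < 0 or population < 0:
        raise ValueError("EVPI and population must be >= 0")
    return evpi_pp * population
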