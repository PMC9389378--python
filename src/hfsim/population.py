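"""Synthetic baseline cohorts for the heart-failure model population.

The generator emulates the baseline table of the source trial population
(n=426): truncated-normal continuous covariates (ejection fraction, age,
systolic blood pressure, BMI, creatinine), a four-category NYHA multinomial,
and independent Bernoulli binary characteristics.  Covariates are sampled
independently by default — only marginal moments are published — with an
optional Gaussian-copula hook for rank-correlating the continuous variables.

Baseline working status is drawn here from the friction-cost productivity
model (NYHA-specific working share scaled by age-sex labor participation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .econ import ProductivityParams

__all__ = [
    "PopulationMoments",
    "PatientProfile",
    "ConfigurationError",
    "CohortParseError",
    "default_moments",
    "generate_population",
    "summarize_population",
    "filter_subgroup",
    "subgroup_names",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "SUBGROUP_CRITERIA",
]

CONTINUOUS_FIELDS = ("ef_pct", "age_years", "sbp_mmHg", "bmi_kg_m2", "creatinine_umol_l")
BINARY_FIELDS = (
    "male",
    "smoker",
    "diabetes",
    "copd",
    "recent_diagnosis",
    "no_beta_blocker",
    "no_ace_inhibitor",
    "myocardial_infarction",
    "chronic_af",
)

COHORT_COLUMNS = (
    "id",
    "age_years",
    "male",
    "ef_pct",
    "sbp_mmHg",
    "bmi_kg_m2",
    "creatinine_umol_l",
    "nyha",
    "smoker",
    "diabetes",
    "copd",
    "recent_diagnosis",
    "no_beta_blocker",
    "no_ace_inhibitor",
    "myocardial_infarction",
    "chronic_af",
    "working",
)


class ConfigurationError(ValueError):
    """Invalid population moments or generator settings."""


class CohortParseError(ValueError):
    """Malformed cohort CSV."""


@dataclass
class PopulationMoments:
    """Marginal moments of the baseline population.

    ``continuous`` maps field -> (mean, sd); ``truncation`` maps field ->
    (low, high); ``binary`` maps field -> prevalence; ``nyha_proportions``
    is the class I-IV multinomial.
    """

    n_reference: int
    continuous: dict
    truncation: dict
    nyha_proportions: tuple
    binary: dict

    def validate(self):
        for name in CONTINUOUS_FIELDS:
            if name not in self.continuous:
                raise ConfigurationError(f"missing continuous moments for {name!r}")
            mean, sd = self.continuous[name]
            if not sd > 0:
                raise ConfigurationError(f"sd for {name!r} must be > 0, got {sd}")
            low, high = self.truncation.get(name, (-math.inf, math.inf))
            if not low < high:
                raise ConfigurationError(
                    f"truncation bounds for {name!r} must satisfy low < high"
                )
        for name in BINARY_FIELDS:
            if name not in self.binary:
                raise ConfigurationError(f"missing prevalence for {name!r}")
            p = self.binary[name]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"prevalence for {name!r} must lie in [0, 1], got {p}"
                )
        props = self.nyha_proportions
        if len(props) != 4 or any(p < 0 for p in props):
            raise ConfigurationError("nyha_proportions must be 4 non-negative values")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("nyha_proportions must sum to 1 within 1e-9")
        return self


def default_moments() -> PopulationMoments:
    """Moments of the published baseline table (trial population, n=426)."""
    return PopulationMoments(
        n_reference=426,
        continuous={
            "ef_pct": (25.06, 7.58),
            "age_years": (67.56, 11.64),
            "sbp_mmHg": (114.24, 19.25),
            "bmi_kg_m2": (26.17, 4.73),
            "creatinine_umol_l": (135.71, 51.98),
        },
        truncation={
            "ef_pct": (5.0, 60.0),
            "age_years": (18.0, 100.0),
            "sbp_mmHg": (60.0, 220.0),
            "bmi_kg_m2": (12.0, 60.0),
            "creatinine_umol_l": (30.0, 500.0),
        },
        nyha_proportions=(0.185, 0.434, 0.310, 0.071),
        binary={
            "male": 0.775,
            "smoker": 0.122,
            "diabetes": 0.35,
            "copd": 0.244,
            "recent_diagnosis": 0.439,
            "no_beta_blocker": 0.373,
            "no_ace_inhibitor": 0.185,
            "myocardial_infarction": 0.568,
            "chronic_af": 0.263,
        },
    )


@dataclass
class PatientProfile:
    """One simulated patient's baseline covariates and mutable event history."""

    id: int
    age_years: float
    male: bool
    ef_pct: float
    sbp_mmHg: float
    bmi_kg_m2: float
    creatinine_umol_l: float
    nyha: int
    smoker: bool
    diabetes: bool
    copd: bool
    recent_diagnosis: bool
    no_beta_blocker: bool
    no_ace_inhibitor: bool
    myocardial_infarction: bool
    chronic_af: bool
    working: bool
    n_prior_hospitalizations: int = 0

    def __post_init__(self):
        if self.age_years <= 0:
            raise ValueError("age_years must be > 0")
        if self.nyha not in (1, 2, 3, 4):
            raise ValueError(f"nyha must be in 1..4, got {self.nyha}")
        if self.n_prior_hospitalizations < 0:
            raise ValueError("n_prior_hospitalizations must be >= 0")


def _truncnorm_ppf(u, mean, sd, low, high):
    """Truncated-normal quantiles whose truncated mean equals ``mean``.

    Truncation pulls the mean of a clipped normal away from its location
    parameter (for creatinine by several umol/L), so the location is
    re-solved such that the distribution reproduces the configured mean
    exactly; the configured sd is kept as the scale.
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = mean
    if not (math.isinf(low) and math.isinf(high)):
        # bracket the root on a finite grid; extreme tails can return nan,
        # in which case the location stays at the plain mean
        grid = [mean + sd * z for z in np.linspace(-6.0, 6.0, 25)]
        vals = [(m, trunc_mean(m) - mean) for m in grid]
        vals = [(m, g) for m, g in vals if np.isfinite(g)]
        for (m0, g0), (m1, g1) in zip(vals, vals[1:]):
            if g0 == 0.0:
                loc = m0
                break
            if g0 * g1 < 0.0:
                loc = brentq(lambda m: trunc_mean(m) - mean, m0, m1, xtol=1e-10)
                break
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def generate_population(
    moments: PopulationMoments,
    n: int,
    seed: int,
    productivity: ProductivityParams | None = None,
    rank_corr: np.ndarray | None = None,
) -> list[PatientProfile]:
    """Draw ``n`` baseline patients; deterministic given ``seed``.

    ``rank_corr``, if given, is a correlation matrix over the five continuous
    covariates (in :data:`CONTINUOUS_FIELDS` order) applied through a Gaussian
    copula; the default is marginal independence.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    moments.validate()
    productivity = productivity or ProductivityParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if n == 0:
        return []

    k = len(CONTINUOUS_FIELDS)
    if rank_corr is not None:
        corr = np.asarray(rank_corr, dtype=float)
        if corr.shape != (k, k):
            raise ConfigurationError(f"rank_corr must be {k}x{k}")
        z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
        u_cont = stats.norm.cdf(z)
    else:
        u_cont = rng.uniform(size=(n, k))

    cont = {}
    for j, name in enumerate(CONTINUOUS_FIELDS):
        mean, sd = moments.continuous[name]
        low, high = moments.truncation.get(name, (-math.inf, math.inf))
        cont[name] = _truncnorm_ppf(u_cont[:, j], mean, sd, low, high)

    nyha = rng.choice(
        np.array([1, 2, 3, 4]), size=n, p=np.asarray(moments.nyha_proportions)
    )
    binaries = {
        name: rng.uniform(size=n) < moments.binary[name] for name in BINARY_FIELDS
    }
    u_work = rng.uniform(size=n)

    cohort = []
    for i in range(n):
        age = float(cont["age_years"][i])
        male = bool(binaries["male"][i])
        p_work = productivity.working_probability(age, male, int(nyha[i]))
        cohort.append(
            PatientProfile(
                id=i,
                age_years=age,
                male=male,
                ef_pct=float(cont["ef_pct"][i]),
                sbp_mmHg=float(cont["sbp_mmHg"][i]),
                bmi_kg_m2=float(cont["bmi_kg_m2"][i]),
                creatinine_umol_l=float(cont["creatinine_umol_l"][i]),
                nyha=int(nyha[i]),
                smoker=bool(binaries["smoker"][i]),
                diabetes=bool(binaries["diabetes"][i]),
                copd=bool(binaries["copd"][i]),
                recent_diagnosis=bool(binaries["recent_diagnosis"][i]),
                no_beta_blocker=bool(binaries["no_beta_blocker"][i]),
                no_ace_inhibitor=bool(binaries["no_ace_inhibitor"][i]),
                myocardial_infarction=bool(binaries["myocardial_infarction"][i]),
                chronic_af=bool(binaries["chronic_af"][i]),
                working=bool(u_work[i] < p_work),
            )
        )
    return cohort


def summarize_population(cohort: Sequence[PatientProfile]) -> PopulationMoments:
    """Empirical moments of a cohort (round-trip counterpart of the generator)."""
    if not cohort:
        raise ValueError("cannot summarize an empty cohort")
    df = cohort_to_frame(cohort)
    continuous = {
        name: (float(df[name].mean()), float(df[name].std(ddof=0)))
        for name in CONTINUOUS_FIELDS
    }
    truncation = {name: (-math.inf, math.inf) for name in CONTINUOUS_FIELDS}
    counts = df["nyha"].value_counts()
    props = tuple(float(counts.get(c, 0)) / len(df) for c in (1, 2, 3, 4))
    binary = {name: float(df[name].mean()) for name in BINARY_FIELDS}
    return PopulationMoments(
        n_reference=len(cohort),
        continuous=continuous,
        truncation=truncation,
        nyha_proportions=props,
        binary=binary,
    )


def _binary_criteria():
    crit = {}
    label = {
        "male": ("sex_male", "sex_female"),
        "smoker": ("smoker_yes", "smoker_no"),
        "diabetes": ("diabetes_yes", "diabetes_no"),
        "copd": ("copd_yes", "copd_no"),
        "recent_diagnosis": ("recent_diagnosis_yes", "recent_diagnosis_no"),
        "no_beta_blocker": ("no_beta_blocker_yes", "no_beta_blocker_no"),
        "no_ace_inhibitor": ("no_ace_inhibitor_yes", "no_ace_inhibitor_no"),
        "myocardial_infarction": ("myocardial_infarction_yes", "myocardial_infarction_no"),
        "chronic_af": ("chronic_af_yes", "chronic_af_no"),
    }
    for attr, (yes, no) in label.items():
        crit[yes] = (lambda p, a=attr: bool(getattr(p, a)))
        crit[no] = (lambda p, a=attr: not getattr(p, a))
    return crit


#: The 26 named subgroup predicates: age and ejection-fraction splits, the four
#: NYHA classes, and present/absent for each binary characteristic.  Boundary
#: patients (age 65, EF 25) fall in the upper group, keeping each pair an
#: exhaustive partition.
SUBGROUP_CRITERIA: dict[str, Callable[[PatientProfile], bool]] = {
    "age_lt_65": lambda p: p.age_years < 65.0,
    "age_ge_65": lambda p: p.age_years >= 65.0,
    "ef_lt_25": lambda p: p.ef_pct < 25.0,
    "ef_ge_25": lambda p: p.ef_pct >= 25.0,
    "nyha_1": lambda p: p.nyha == 1,
    "nyha_2": lambda p: p.nyha == 2,
    "nyha_3": lambda p: p.nyha == 3,
    "nyha_4": lambda p: p.nyha == 4,
    **_binary_criteria(),
}


def subgroup_names() -> list[str]:
    return list(SUBGROUP_CRITERIA)


def filter_subgroup(cohort: Sequence[PatientProfile], criterion: str) -> list[PatientProfile]:
    """Patients matching one of the 26 named subgroup predicates."""
    try:
        pred = SUBGROUP_CRITERIA[criterion]
    except KeyError:
        raise KeyError(
            f"unknown subgroup {criterion!r}; valid names: {', '.join(SUBGROUP_CRITERIA)}"
        ) from None
    return [p for p in cohort if pred(p)]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_BOOL_COLUMNS = tuple(c for c in COHORT_COLUMNS if c in BINARY_FIELDS) + ("working",)


def cohort_to_frame(cohort: Sequence[PatientProfile]) -> pd.DataFrame:
    rows = [
        {col: getattr(p, col) for col in COHORT_COLUMNS} for p in cohort
    ]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    return df


def write_cohort(cohort: Sequence[PatientProfile], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path) -> list[PatientProfile]:
    """Read a cohort CSV (header row, booleans as 0/1)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortParseError(f"{path}: empty file without header") from None
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")
    cohort = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        values = {col: getattr(row, col) for col in COHORT_COLUMNS}
        for col, v in values.items():
            try:
                if not np.isfinite(float(v)):
                    raise ValueError
            except (TypeError, ValueError):
                raise CohortParseError(
                    f"{path}: non-numeric value {v!r} in {col!r} at row {row_no}"
                ) from None
        if int(values["nyha"]) not in (1, 2, 3, 4):
            raise CohortParseError(
                f"{path}: NYHA class {values['nyha']} outside 1-4 at row {row_no}"
            )
        try:
            cohort.append(
                PatientProfile(
                    id=int(values["id"]),
                    age_years=float(values["age_years"]),
                    male=bool(int(values["male"])),
                    ef_pct=float(values["ef_pct"]),
                    sbp_mmHg=float(values["sbp_mmHg"]),
                    bmi_kg_m2=float(values["bmi_kg_m2"]),
                    creatinine_umol_l=float(values["creatinine_umol_l"]),
                    nyha=int(values["nyha"]),
                    smoker=bool(int(values["smoker"])),
                    diabetes=bool(int(values["diabetes"])),
                    copd=bool(int(values["copd"])),
                    recent_diagnosis=bool(int(values["recent_diagnosis"])),
                    no_beta_blocker=bool(int(values["no_beta_blocker"])),
                    no_ace_inhibitor=bool(int(values["no_ace_inhibitor"])),
                    myocardial_infarction=bool(int(values["myocardial_infarction"])),
                    chronic_af=bool(int(values["chronic_af"])),
                    working=bool(int(values["working"])),
                )
            )
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"{path}: row {row_no}: {exc}") from exc
    return cohort
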