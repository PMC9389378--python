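"""Parametric time-to-event models and the in-hospital mortality logistic.

Six survival families are supported, each with a pinned parameterization so
that configurations are portable:

========================  =========================================  =============
family                    survival function S(t)                     params
========================  =========================================  =============
``exponential``           exp(-lambda*t)                             (rate,)
``weibull``               exp(-(t/sigma)**k)                         (shape, scale)
``lognormal``             1 - Phi((ln t - mu)/s)                     (mu, s)
``loglogistic``           1 / (1 + (t/sigma)**k)                     (shape, scale)
``gompertz``              exp(-(lambda/gamma)(e**(gamma*t) - 1))     (rate, gamma)
``generalized_gamma``     Prentice (mu, sigma, q) log-time form      (mu, sigma, q)
========================  =========================================  =============

Treatment effects are proportional hazards: S_arm(t) = S_0(t)**HR, applied on
the hazard even for AFT-form families (log-normal, log-logistic, generalized
gamma), where it is a numeric convention rather than the family's natural one.
Time unit is years throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special, stats

__all__ = [
    "ParametricSurvival",
    "LogisticModel",
    "ModelValidationError",
    "survival_probability",
    "sample_event_time",
    "sample_conditional",
    "in_hospital_death_probability",
    "FAMILIES",
]


class ModelValidationError(ValueError):
    """Raised for invalid survival-family or logistic specifications."""


# ---------------------------------------------------------------------------
# family definitions: baseline survival S0(t) and its inverse t = S0^{-1}(p)
# ---------------------------------------------------------------------------


def _exp_s(t, p):
    (rate,) = p
    return np.exp(-rate * t)


def _exp_inv(u, p):
    (rate,) = p
    return -np.log(u) / rate


def _weib_s(t, p):
    shape, scale = p
    return np.exp(-np.power(t / scale, shape))


def _weib_inv(u, p):
    shape, scale = p
    return scale * np.power(-np.log(u), 1.0 / shape)


def _lnorm_s(t, p):
    mu, s = p
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        z = (np.log(t) - mu) / s
    return stats.norm.sf(z)


def _lnorm_inv(u, p):
    mu, s = p
    return np.exp(mu + s * stats.norm.isf(u))


def _llog_s(t, p):
    shape, scale = p
    return 1.0 / (1.0 + np.power(t / scale, shape))


def _llog_inv(u, p):
    shape, scale = p
    return scale * np.power((1.0 - u) / u, 1.0 / shape)


def _gomp_s(t, p):
    rate, gamma = p
    if gamma == 0.0:
        return np.exp(-rate * t)
    return np.exp(-(rate / gamma) * np.expm1(gamma * t))


def _gomp_inv(u, p):
    rate, gamma = p
    if gamma == 0.0:
        return -np.log(u) / rate
    return np.log1p(-(gamma / rate) * np.log(u)) / gamma


def _gg_s(t, p):
    # Prentice log-time parameterization; q=0 degenerates to lognormal.
    mu, sigma, q = p
    if q == 0.0:
        return _lnorm_s(t, (mu, sigma))
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) / sigma
    a = 1.0 / (q * q)
    x = a * np.exp(q * w)
    cdf_g = special.gammainc(a, x)
    return 1.0 - cdf_g if q > 0 else cdf_g


def _gg_inv(u, p):
    mu, sigma, q = p
    if q == 0.0:
        return _lnorm_inv(u, (mu, sigma))
    a = 1.0 / (q * q)
    target = (1.0 - u) if q > 0 else u
    x = special.gammaincinv(a, target)
    w = np.log(x / a) / q
    return np.exp(mu + sigma * w)


def _check_positive(name, value):
    if not value > 0:
        raise ModelValidationError(f"{name} must be > 0, got {value!r}")


def _validate(family, params):
    if family == "exponential":
        if len(params) != 1:
            raise ModelValidationError("exponential takes (rate,)")
        _check_positive("rate", params[0])
    elif family in ("weibull", "loglogistic"):
        if len(params) != 2:
            raise ModelValidationError(f"{family} takes (shape, scale)")
        _check_positive("shape", params[0])
        _check_positive("scale", params[1])
    elif family == "lognormal":
        if len(params) != 2:
            raise ModelValidationError("lognormal takes (mu, s)")
        _check_positive("s", params[1])
    elif family == "gompertz":
        if len(params) != 2:
            raise ModelValidationError("gompertz takes (rate, gamma)")
        _check_positive("rate", params[0])
        if params[1] < 0:
            # negative gamma leaves defective survival mass (S(inf) > 0),
            # which a lifetime-horizon simulation cannot terminate under
            raise ModelValidationError(
                "gompertz gamma < 0 gives a defective distribution and is rejected"
            )
    elif family == "generalized_gamma":
        if len(params) != 3:
            raise ModelValidationError("generalized_gamma takes (mu, sigma, q)")
        _check_positive("sigma", params[1])
    else:
        raise ModelValidationError(
            f"unknown family {family!r}; valid: {sorted(FAMILIES)}"
        )


FAMILIES = {
    "exponential": (_exp_s, _exp_inv),
    "weibull": (_weib_s, _weib_inv),
    "lognormal": (_lnorm_s, _lnorm_inv),
    "loglogistic": (_llog_s, _llog_inv),
    "gompertz": (_gomp_s, _gomp_inv),
    "generalized_gamma": (_gg_s, _gg_inv),
}


@dataclass
class ParametricSurvival:
    """A parametric event-time process with proportional-hazards modifiers.

    ``log_hr_treatment`` maps arm name -> log hazard ratio (missing arms get
    0, i.e. the reference hazard).  ``covariate_log_hrs`` maps a patient
    attribute name to a per-unit log hazard ratio; the default is empty (arm
    effect only).
    """

    family: str
    params: tuple
    log_hr_treatment: Mapping[str, float] = field(default_factory=dict)
    covariate_log_hrs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.params = tuple(float(x) for x in self.params)
        _validate(self.family, self.params)

    def hazard_ratio(self, arm: str | None, profile=None) -> float:
        log_hr = float(self.log_hr_treatment.get(arm, 0.0)) if arm else 0.0
        for name, beta in self.covariate_log_hrs.items():
            if profile is None:
                raise ModelValidationError(
                    f"covariate hazard ratio on {name!r} requires a patient profile"
                )
            log_hr += beta * float(getattr(profile, name))
        return math.exp(log_hr)


def survival_probability(model: ParametricSurvival, t, arm=None, profile=None):
    """S_arm(t) = S_0(t)**HR.  ``t`` may be scalar or array, in years."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    s_fn, _ = FAMILIES[model.family]
    hr = model.hazard_ratio(arm, profile)
    out = np.power(s_fn(t_arr, model.params), hr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _invert(model, p0):
    """t such that S_0(t) = p0 (baseline survival)."""
    _, inv_fn = FAMILIES[model.family]
    return inv_fn(p0, model.params)


def sample_event_time(model: ParametricSurvival, arm=None, profile=None, rng=None):
    """Inverse-CDF draw: t with S_arm(t) = U, U ~ Uniform(0,1)."""
    rng = np.random.default_rng() if rng is None else rng
    u = rng.uniform()
    hr = model.hazard_ratio(arm, profile)
    # S0(t)^HR = u  =>  S0(t) = u^(1/HR)
    return float(_invert(model, u ** (1.0 / hr)))


def sample_conditional(
    model: ParametricSurvival, arm=None, profile=None, t0: float = 0.0, rng=None
):
    """Draw an event time conditional on survival past ``t0``.

    Returns t > t0 with S_arm(t)/S_arm(t0) = U.  At t0 = 0 this reduces to
    :func:`sample_event_time`.
    """
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    u = rng.uniform()
    hr = model.hazard_ratio(arm, profile)
    s_fn, _ = FAMILIES[model.family]
    s0_t0 = float(s_fn(np.asarray(t0, dtype=float), model.params))
    if s0_t0 <= 0.0:
        raise ValueError(f"survival at t0={t0} is numerically zero")
    # S0(t)^HR = u * S0(t0)^HR  =>  S0(t) = u^(1/HR) * S0(t0)
    t = float(_invert(model, (u ** (1.0 / hr)) * s0_t0))
    # guard against rounding placing t at/below t0 for tiny gaps
    return max(t, np.nextafter(t0, math.inf))


# ---------------------------------------------------------------------------
# logistic in-hospital mortality
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """Logistic regression p = expit(intercept + sum(beta_i * x_i)).

    Covariate names are patient-profile attributes (``age_years``, ``male``,
    ``myocardial_infarction``, ``chronic_af``, ``diabetes``, ``copd``,
    ``n_prior_hospitalizations``); booleans enter as 0/1.
    """

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def linear_predictor(self, profile, overrides: Mapping[str, float] | None = None):
        lp = float(self.intercept)
        overrides = overrides or {}
        for name, beta in self.coefficients.items():
            if name in overrides:
                x = overrides[name]
            elif hasattr(profile, name):
                x = getattr(profile, name)
            else:
                raise ModelValidationError(f"profile is missing covariate {name!r}")
            lp += float(beta) * float(x)
        return lp


def in_hospital_death_probability(
    model: LogisticModel, profile, overrides: Mapping[str, float] | None = None
) -> float:
    """Probability of dying during a hospitalization, from the logistic model."""
    return float(special.expit(model.linear_predictor(profile, overrides)))
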