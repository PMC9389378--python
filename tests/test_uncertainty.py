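import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import hfsim
from hfsim.uncertainty import (
    EVPIConfig,
    ParamDistribution,
    PSAConfig,
    PSAIteration,
    PSAResult,
    ceac,
    default_distributions,
    discounted_population,
    draw_parameter_set,
    evpi_per_patient,
    iteration_sim_seed,
    population_evpi,
    run_dsa,
    run_psa,
)


def _psa_from_nmb(costs_by_iter):
    """Build a PSAResult directly from per-iteration arm costs (QALYs zero)."""
    iterations = []
    for i, costs in enumerate(costs_by_iter):
        iterations.append(
            PSAIteration(
                index=i,
                params={},
                mean_cost={a: c for a, c in costs.items()},
                mean_qalys={a: 0.0 for a in costs},
                sim_seed=0,
                indices=np.array([]),
            )
        )
    return PSAResult(iterations)


def test_draws_are_moment_matched():
    rng = np.random.default_rng(1)
    gamma = ParamDistribution("costs.hospitalization", 4404.46, "gamma", 0.2 * 4404.46)
    draws = np.array([gamma.draw(rng) for _ in range(100_000)])
    se = 0.2 * 4404.46 / math.sqrt(draws.size)
    assert draws.mean() == pytest.approx(4404.46, abs=3 * se)
    assert np.all(draws > 0)

    beta = ParamDistribution("utilities.nyha_utilities.0", 0.87976, "beta", 0.00827)
    bdraws = np.array([beta.draw(rng) for _ in range(10_000)])
    assert np.all((0 < bdraws) & (bdraws < 1))
    assert bdraws.mean() == pytest.approx(0.87976, abs=3 * 0.00827 / math.sqrt(10_000))

    fixed = ParamDistribution("econ.discount_rate_costs", 0.04, "fixed")
    assert fixed.draw(rng) == 0.04
    zero_se = ParamDistribution("x", 5.0, "normal", 0.0)
    assert zero_se.draw(rng) == 5.0


def test_infeasible_beta_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        ParamDistribution("u", 0.5, "beta", 0.6)
    with pytest.raises(ValueError, match="bracket"):
        ParamDistribution("u", 0.5, "normal", 0.1, low=0.6, high=0.7)


def test_truncation_of_probability_draws():
    rng = np.random.default_rng(2)
    dist = ParamDistribution("da.p_avoidable", 0.9, "normal", 0.3, trunc_low=0.0, trunc_high=1.0)
    draws = [dist.draw(rng) for _ in range(2_000)]
    assert all(0.0 <= d <= 1.0 for d in draws)


def test_parameter_set_is_seed_deterministic():
    dists = default_distributions()
    a = draw_parameter_set(dists, np.random.default_rng(3))
    b = draw_parameter_set(dists, np.random.default_rng(3))
    assert a == b
    assert set(a) == {d.path for d in dists}


@pytest.fixture(scope="module")
def psa_setup(config):
    cohort = hfsim.generate_population(config.population, 80, seed=31,
                                       productivity=config.productivity)
    return config, cohort


def test_degenerate_psa_reproduces_deterministic_run(psa_setup):
    """All-fixed distributions: one PSA iteration equals the plain run of the
    same resampled cohort with the same derived seed."""
    config, cohort = psa_setup
    dists = [
        ParamDistribution("costs.hospitalization", config.costs.hospitalization, "fixed")
    ]
    psa_cfg = PSAConfig(inner_n_patients=40, outer_iterations=1, seed=5)
    psa = run_psa(psa_cfg, dists, config, cohort)
    it = psa.iterations[0]
    resample = [cohort[j] for j in it.indices]
    out = hfsim.simulate_cohort(resample, config, iteration_sim_seed(5, 0))
    for arm in it.mean_cost:
        assert it.mean_cost[arm] == pytest.approx(out.per_arm[arm].mean_cost, abs=1e-9)
        assert it.mean_qalys[arm] == pytest.approx(out.per_arm[arm].mean_qalys, abs=1e-9)


def test_psa_output_shape_and_ce_quadrant(psa_setup):
    config, cohort = psa_setup
    psa_cfg = PSAConfig(inner_n_patients=30, outer_iterations=12, seed=6)
    psa = run_psa(psa_cfg, default_distributions(), config, cohort)
    frame = psa.to_frame()
    assert len(frame) == 12 * 3
    assert frame[["mean_cost", "mean_qalys"]].notna().all().all()
    dq = [it.mean_qalys["HTM_DA"] - it.mean_qalys["UC"] for it in psa.iterations]
    dc = [it.mean_cost["HTM_DA"] - it.mean_cost["UC"] for it in psa.iterations]
    northeast = np.mean([(a > 0) and (b > 0) for a, b in zip(dq, dc)])
    assert northeast > 0.5  # incremental cloud predominantly cost- and QALY-increasing


def test_ceac_normalization_and_limits():
    psa = _psa_from_nmb([
        {"A": 10.0, "B": 20.0},
        {"A": 5.0, "B": 30.0},
        {"A": 1.0, "B": 2.0},
    ])
    curves = ceac(psa, [0.0, 50_000.0])
    for lam, group in curves.groupby("lambda"):
        assert group["probability"].sum() == pytest.approx(1.0)
        assert ((0 <= group["probability"]) & (group["probability"] <= 1)).all()
    # at lambda=0 the cheaper arm wins every iteration
    at0 = curves[curves["lambda"] == 0.0].set_index("arm")["probability"]
    assert at0["A"] == 1.0
    with pytest.raises(ValueError):
        ceac(psa, [])


def test_evpi_hand_enumeration():
    psa = _psa_from_nmb([{"A": -10.0, "B": 0.0}, {"A": 0.0, "B": -10.0}])
    # NMB (lambda=0) is -cost: iterations {A:10,B:0} and {A:0,B:10}
    assert evpi_per_patient(psa, 0.0) == pytest.approx(5.0)
    dominant = _psa_from_nmb([{"A": 0.0, "B": 10.0}, {"A": 5.0, "B": 20.0}])
    assert evpi_per_patient(dominant, 0.0) == 0.0


def test_evpi_shift_invariance():
    base = [{"A": -10.0, "B": 0.0}, {"A": 0.0, "B": -10.0}]
    shifted = [{a: c - 100.0 for a, c in row.items()} for row in base]
    assert evpi_per_patient(_psa_from_nmb(base), 0.0) == pytest.approx(
        evpi_per_patient(_psa_from_nmb(shifted), 0.0)
    )


def test_discounted_population_printed_counts():
    cfg = EVPIConfig()
    assert abs(discounted_population(cfg) - 253_118) <= 5
    undiscounted = EVPIConfig(discount_rate=0.0)
    assert discounted_population(undiscounted) == 285_057
    single = EVPIConfig(yearly_eligible_patients=(1000,), horizon_years=1)
    assert discounted_population(single) == round(1000 / 1.04)


def test_population_evpi_product():
    assert population_evpi(0.0, 253_118) == 0.0
    assert population_evpi(1.0, 10) == 10.0
    assert population_evpi(341.28, 253_118) == pytest.approx(86.38e6, rel=0.001)


def test_dsa_tornado_structure(psa_setup):
    config, cohort = psa_setup
    dists = [
        ParamDistribution("costs.htm_device_per_year", 1257.75, "gamma",
                          0.2 * 1257.75, 1059.87, 1469.69),
        ParamDistribution("costs.hospitalization", 4404.46, "gamma",
                          0.2 * 4404.46, 3062.36, 5946.44),
        ParamDistribution("costs.alarm_management", 18.38, "gamma",
                          0.2 * 18.38, 18.38, 18.38),  # zero-width bar
        ParamDistribution("skipped.no.bounds", 1.0, "fixed"),
    ]
    tornado = run_dsa(config, cohort[:40], dists, seed=7)
    assert list(tornado.columns[:3]) == ["parameter", "low", "high"]
    assert len(tornado) == 3  # unbounded parameter skipped
    assert tornado["range"].is_monotonic_decreasing
    zero = tornado[tornado["parameter"] == "costs.alarm_management"]["range"].iloc[0]
    assert zero == pytest.approx(0.0, abs=1e-9)


def test_dsa_cost_parameters_leave_qalys_unchanged(psa_setup):
    """Under CRN, moving a pure-cost parameter cannot move QALYs."""
    config, cohort = psa_setup
    cfg_hi = config.copy()
    hfsim.set_param(cfg_hi, "costs.hospitalization", 5946.44)
    base = hfsim.simulate_cohort(cohort[:30], config, seed=8)
    high = hfsim.simulate_cohort(cohort[:30], cfg_hi, seed=8)
    for arm in base.per_arm:
        assert high.per_arm[arm].mean_qalys == base.per_arm[arm].mean_qalys
        assert high.per_arm[arm].mean_cost > base.per_arm[arm].mean_cost
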