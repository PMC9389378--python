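import dataclasses
import math

import numpy as np
import pytest

import hfsim
from hfsim.engine import (
    ARMS,
    ArmConfig,
    DASpec,
    ModelSet,
    avoidance_probability,
    expected_false_alarms,
    simulate_cohort,
    simulate_patient,
)
from hfsim.survival import LogisticModel, ParametricSurvival


def test_avoidance_probability_worked_example():
    assert avoidance_probability(DASpec(0.52, 0.03, 0.50)) == pytest.approx(0.26)
    assert avoidance_probability(DASpec(0.0, 0.03, 0.50)) == 0.0
    assert avoidance_probability(DASpec(1.0, 0.03, 1.0)) == 1.0


def test_expected_false_alarms_worked_example():
    da = DASpec(0.52, 0.03, 0.50)
    assert expected_false_alarms(da, 100.0) == pytest.approx(3.0)
    assert expected_false_alarms(DASpec(0.52, 0.0, 0.5), 500.0) == 0.0
    assert expected_false_alarms(DASpec(0.52, 0.5, 0.5), 10.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        expected_false_alarms(da, -1.0)


def test_da_probabilities_validated():
    with pytest.raises(ValueError, match="sensitivity"):
        DASpec(sensitivity=1.2)
    with pytest.raises(ValueError, match="cannot enable"):
        ArmConfig("UC", 2.81, DASpec(enabled=True))


def test_trajectory_structure(config, small_cohort):
    models = config.model_set()
    for profile in small_cohort[:10]:
        traj = simulate_patient(profile, config.arm_config("HTM_DA"), models, seed=3)
        times = [e.time_years for e in traj.events]
        assert all(t1 > t0 for t0, t1 in zip(times, times[1:]))
        assert traj.events[-1].kind in ("death_other", "death_in_hospital")
        assert traj.death_time == times[-1]
        assert sum(1 for e in traj.events if e.kind.startswith("death")) == 1


def test_null_da_reproduces_htm_arm(config, small_cohort):
    """sensitivity=0, fpr=0: the HTM+DA trajectory is identical to HTM under CRN."""
    cfg = config.copy()
    cfg.da = DASpec(sensitivity=0.0, false_positive_rate=0.0, p_avoidable=0.5)
    models = cfg.model_set()
    for i, profile in enumerate(small_cohort):
        t_htm = simulate_patient(profile, cfg.arm_config("HTM"), models, seed=5, patient_index=i)
        t_da = simulate_patient(profile, cfg.arm_config("HTM_DA"), models, seed=5, patient_index=i)
        assert [(e.time_years, e.kind) for e in t_htm.events] == [
            (e.time_years, e.kind) for e in t_da.events
        ]


def test_hospitalization_conservation_under_crn(config, small_cohort):
    """Realized + averted admissions under HTM+DA equal realized under HTM.

    Exact per patient when in-hospital mortality is disabled (an averted
    admission cannot change survival), which is how the streams are aligned.
    """
    cfg = config.copy()
    cfg.in_hospital_death_model = None
    models = cfg.model_set()
    for i, profile in enumerate(small_cohort):
        t_htm = simulate_patient(profile, cfg.arm_config("HTM"), models, seed=9, patient_index=i)
        t_da = simulate_patient(profile, cfg.arm_config("HTM_DA"), models, seed=9, patient_index=i)
        assert t_da.n_hospitalizations + t_da.n_averted == t_htm.n_hospitalizations
        assert t_da.death_time == pytest.approx(t_htm.death_time)


def test_da_sensitivity_monotone_in_averted(config, small_cohort):
    """With common random numbers, higher sensitivity never averts fewer admissions."""
    counts = []
    for sens in (0.0, 0.3, 0.6, 0.9):
        cfg = config.copy()
        cfg.da = DASpec(sensitivity=sens, false_positive_rate=0.03, p_avoidable=0.5)
        cfg.in_hospital_death_model = None
        models = cfg.model_set()
        total = sum(
            simulate_patient(p, cfg.arm_config("HTM_DA"), models, seed=13, patient_index=i).n_averted
            for i, p in enumerate(small_cohort)
        )
        counts.append(total)
    assert counts == sorted(counts)


def test_death_only_exponential_mean(config):
    """Death-only model: mean death time over 1e4 patients matches 1/rate."""
    rate = 0.5
    cfg = config.copy()
    cfg.death_model = ParametricSurvival("exponential", (rate,))
    cfg.hospitalization_model = None
    cfg.in_hospital_death_model = None
    profile = hfsim.generate_population(cfg.population, 1, seed=1)[0]
    models = cfg.model_set()
    arm_cfg = cfg.arm_config("UC")
    n = 10_000
    times = np.array(
        [
            simulate_patient(profile, arm_cfg, models, seed=21, patient_index=i).death_time
            for i in range(n)
        ]
    )
    se = 1.0 / rate / math.sqrt(n)  # exponential sd equals the mean
    assert times.mean() == pytest.approx(1.0 / rate, abs=3 * se)


def test_false_alarm_accrual_totals(config, small_cohort):
    """Total false alarms equal fpr x days alive (deterministic expectation)."""
    cfg = config.copy()
    cfg.da = DASpec(sensitivity=0.52, false_positive_rate=0.03, p_avoidable=0.5)
    models = cfg.model_set()
    profile = small_cohort[0]
    traj = simulate_patient(profile, cfg.arm_config("HTM_DA"), models, seed=2)
    assert traj.total_false_alarms == pytest.approx(0.03 * traj.death_time * 365.25)
    assert traj.total_false_alarms == pytest.approx(
        sum(e.payload.get("false_alarms", 0.0) for e in traj.events)
    )


def test_simulate_cohort_aggregates(config, small_cohort):
    out = simulate_cohort(small_cohort, config, seed=4, keep_trajectories=True)
    assert set(out.per_arm) == set(ARMS)
    for arm, res in out.per_arm.items():
        assert res.mean_qalys <= res.mean_life_years + 1e-12
        assert res.death_in_hospital_frac + res.death_other_frac == pytest.approx(1.0)
        assert res.visit_rate <= 12.0 / config.arm_config(arm).outpatient_interval_months
    assert out.per_arm["UC"].averted_rate == 0.0
    assert out.per_arm["HTM"].averted_rate == 0.0
    assert out.per_arm["HTM_DA"].averted_rate > 0.0
    # all three arms cover the same patients
    ids = {arm: [t.patient_id for t in out.trajectories[arm]] for arm in ARMS}
    assert ids["UC"] == ids["HTM"] == ids["HTM_DA"]
    with pytest.raises(ValueError):
        simulate_cohort([], config, seed=4)


def test_visit_rate_near_interval_reciprocal(config):
    """With survival much longer than the visit interval, rate -> 12/interval."""
    cfg = config.copy()
    cfg.death_model = ParametricSurvival("exponential", (0.02,))  # mean 50 y
    cfg.hospitalization_model = None
    cfg.in_hospital_death_model = None
    cohort = hfsim.generate_population(cfg.population, 50, seed=3)
    out = simulate_cohort(cohort, cfg, seed=6, arms=("UC",))
    assert out.per_arm["UC"].visit_rate == pytest.approx(12.0 / 2.81, rel=0.02)


def test_qalys_equal_life_years_without_discount_and_disutility(config, small_cohort):
    cfg = config.copy()
    cfg.econ = dataclasses.replace(cfg.econ, discount_rate_costs=0.0, discount_rate_effects=0.0)
    cfg.utilities = hfsim.UtilityParams(
        nyha_utilities=(1.0, 1.0, 1.0, 1.0),
        hosp_multiplier=1.0,
        general_population_coefficients=(1.0, 1.0, 0.0, 0.0),
    )
    out = simulate_cohort(small_cohort[:20], cfg, seed=8, arms=("UC",))
    res = out.per_arm["UC"]
    assert res.mean_qalys == pytest.approx(res.mean_life_years, abs=1e-9)
    assert res.mean_life_years == pytest.approx(res.mean_undiscounted_life_years, abs=1e-9)
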