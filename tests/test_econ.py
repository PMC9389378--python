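import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import hfsim
from hfsim.econ import (
    AgeSexTable,
    CostParams,
    EconSettings,
    ProductivityParams,
    UnrelatedCostTable,
    continuous_cost,
    discount_factor,
    event_costs,
    productivity_loss,
    total_costs,
    unrelated_medical_costs,
)
from hfsim.engine import EventRecord


def test_discount_factor_definition():
    assert discount_factor(0.0, 0.04) == 1.0
    assert discount_factor(1.0, 0.04) == pytest.approx(1 / 1.04)
    assert discount_factor(7.3, 0.0) == 1.0
    with pytest.raises(ValueError):
        discount_factor(1.0, -0.01)
    with pytest.raises(ValueError):
        discount_factor(-1.0, 0.04)


def test_continuous_cost_against_quadrature():
    """Closed form matches numerical integration of c*(1+r)^(-t) to 1e-6."""
    for c, t0, t1, r in [(100, 0, 1, 0.04), (2098.28, 0.7, 5.3, 0.04), (50, 2, 2.5, 0.015)]:
        numeric, _ = quad(lambda t: c * (1 + r) ** (-t), t0, t1)
        assert continuous_cost(c, t0, t1, r) == pytest.approx(numeric, abs=1e-6)
    assert continuous_cost(100, 0, 1, 0.0) == 100.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    t=st.tuples(
        st.floats(0, 10), st.floats(0, 10), st.floats(0, 10)
    ).map(sorted),
    r=st.floats(0, 0.1),
    c=st.floats(0, 5000),
)
def test_continuous_cost_additivity(t, r, c):
    t0, t1, t2 = t
    whole = continuous_cost(c, t0, t2, r)
    split = continuous_cost(c, t0, t1, r) + continuous_cost(c, t1, t2, r)
    assert split == pytest.approx(whole, abs=1e-9 * max(1.0, abs(whole)))


def test_event_costs_at_time_zero():
    params = CostParams()
    settings_ = EconSettings(discount_rate_costs=0.04)
    hosp = EventRecord(0.0, "hospitalization")
    assert event_costs(hosp, "UC", params, settings_) == pytest.approx(4409.14)
    visit = EventRecord(0.0, "outpatient_visit")
    assert event_costs(visit, "UC", params, settings_) == pytest.approx(48.25)
    averted = EventRecord(0.0, "averted_hospitalization")
    assert event_costs(averted, "HTM_DA", params, settings_) == pytest.approx(18.38)
    alarms = EventRecord(0.0, "outpatient_visit", {"false_alarms": 3.0, "fa_time": 0.0})
    assert event_costs(alarms, "HTM_DA", params, settings_) == pytest.approx(
        43.30 + 3.75 + 3 * 18.38
    )
    with pytest.raises(ValueError, match="unknown event kind"):
        event_costs(EventRecord(0.0, "tea_break"), "UC", params, settings_)


def test_event_costs_discounted_and_by_perspective():
    params = CostParams()
    societal = EconSettings()
    healthcare = EconSettings(perspective="healthcare")
    visit = EventRecord(1.0, "outpatient_visit")
    assert event_costs(visit, "UC", params, societal) == pytest.approx(48.25 / 1.04)
    assert event_costs(visit, "UC", params, healthcare) == pytest.approx(44.50 / 1.04)


def _worker(patient, age, working=True):
    return dataclasses.replace(patient, age_years=age, working=working)


def test_productivity_loss_rules(patient):
    params = ProductivityParams(
        hours_per_week=AgeSexTable(((18, 65), (65, 120)), (40.0, 0.0), (40.0, 0.0)),
        hourly_labor_cost=AgeSexTable(((18, 65), (65, 120)), (30.0, 0.0), (30.0, 0.0)),
    )
    settings_ = EconSettings(discount_rate_costs=0.0)
    assert productivity_loss(_worker(patient, 70.0), 0.0, params, settings_) == 0.0
    assert productivity_loss(_worker(patient, 50.0, working=False), 0.0, params, settings_) == 0.0
    assert productivity_loss(_worker(patient, 50.0), 0.0, params, settings_) == pytest.approx(5200.0)
    # aging past retirement during the simulation also stops the losses
    assert productivity_loss(_worker(patient, 60.0), 6.0, params, settings_) == 0.0


def test_unrelated_costs_piecewise(patient):
    flat = UnrelatedCostTable(AgeSexTable(((0, 130),), (1000.0,), (1000.0,)))
    r0 = EconSettings(discount_rate_costs=0.0)
    assert unrelated_medical_costs(patient, 0.0, 2.5, flat, r0) == pytest.approx(2500.0)
    zero = UnrelatedCostTable(AgeSexTable(((0, 130),), (0.0,), (0.0,)))
    assert unrelated_medical_costs(patient, 0.0, 10.0, zero, r0) == 0.0

    # band crossing equals direct quadrature of the stepped rate
    p = _worker(patient, 63.0)
    table = UnrelatedCostTable(
        AgeSexTable(((0, 65), (65, 130)), (1000.0, 4000.0), (1000.0, 4000.0))
    )
    settings_ = EconSettings(discount_rate_costs=0.04)
    rate = lambda t: (1000.0 if 63.0 + t < 65.0 else 4000.0) * 1.04 ** (-t)
    numeric, _ = quad(rate, 0.0, 5.0, points=[2.0])
    assert unrelated_medical_costs(p, 0.0, 5.0, table, settings_) == pytest.approx(
        numeric, abs=1e-6
    )
    with pytest.raises(ValueError, match="outside table coverage"):
        unrelated_medical_costs(
            _worker(patient, 64.0),
            0.0,
            5.0,
            UnrelatedCostTable(AgeSexTable(((0, 65),), (1000.0,), (1000.0,))),
            settings_,
        )


def _trajectory(events, death_time, pid=0, arm="UC"):
    from hfsim.engine import Trajectory

    return Trajectory(pid, arm, events, death_time)


def test_total_costs_components(config, patient):
    """Component arithmetic: device cost for HTM arms, breakdown sums to total."""
    p = dataclasses.replace(patient, working=False)
    events = [
        EventRecord(0.5, "outpatient_visit"),
        EventRecord(1.0, "hospitalization"),
        EventRecord(2.0, "death_other"),
    ]
    traj = _trajectory(events, 2.0)
    settings_ = EconSettings(discount_rate_costs=0.0)
    uc = total_costs(traj, p, "UC", config.costs, settings_, config.productivity, config.unrelated)
    htm = total_costs(traj, p, "HTM", config.costs, settings_, config.productivity, config.unrelated)
    device = htm.components["htm_device"]
    assert device == pytest.approx(config.costs.htm_device_per_year * 2.0)
    assert sum(uc.components.values()) == pytest.approx(uc.total, abs=1e-6)
    # HTM arm also swaps visit price and contact rate
    assert htm.components["outpatient_visits"] == pytest.approx(43.30 + 3.75)
    assert uc.components["outpatient_visits"] == pytest.approx(44.50 + 3.75)

    with pytest.raises(ValueError, match="death"):
        total_costs(
            _trajectory([EventRecord(0.5, "outpatient_visit")], None),
            p, "UC", config.costs, settings_, config.productivity, config.unrelated,
        )


def test_discounting_and_perspective_reduce_totals(config, patient):
    events = [EventRecord(1.0, "hospitalization"), EventRecord(3.0, "death_other")]
    traj = _trajectory(events, 3.0)
    args = (traj, patient, "UC", config.costs)
    tail = (config.productivity, config.unrelated)
    undisc = total_costs(*args, EconSettings(discount_rate_costs=0.0), *tail).total
    disc = total_costs(*args, EconSettings(discount_rate_costs=0.04), *tail).total
    hc = total_costs(*args, EconSettings(perspective="healthcare"), *tail).total
    soc = total_costs(*args, EconSettings(), *tail).total
    assert disc <= undisc
    assert hc <= soc
    assert all(v >= 0 for v in total_costs(*args, EconSettings(), *tail).components.values())
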