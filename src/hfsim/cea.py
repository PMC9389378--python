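"""Incremental cost-effectiveness analysis and threshold logic.

Implements the standard frontier construction: interventions are ranked by
effectiveness, strictly dominated options removed, and extendedly dominated
options (whose ICER versus the previous efficient option exceeds that of the
next, more effective option) iteratively excluded until frontier ICERs are
non-decreasing.  The willingness-to-pay threshold follows the Dutch
proportional-shortfall scheme: the burden-of-disease fraction selects a
threshold band (defaults 20,000 / 50,000 / 80,000 euros per QALY).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ArmResult",
    "CEComparison",
    "CETable",
    "DEFAULT_THRESHOLD_BANDS",
    "icer",
    "incremental_analysis",
    "proportional_shortfall",
    "threshold_from_shortfall",
    "nmb",
    "rate_reduction",
    "percent_change",
]


@dataclass
class ArmResult:
    """Per-arm mean outcomes of a simulated cohort."""

    arm: str
    n_patients: int
    mean_cost: float
    mean_life_years: float
    mean_qalys: float
    mean_undiscounted_life_years: float = float("nan")
    mean_undiscounted_qalys: float = float("nan")
    visit_rate: float = float("nan")
    hospitalization_rate: float = float("nan")
    averted_rate: float = float("nan")
    death_in_hospital_frac: float = float("nan")
    death_other_frac: float = float("nan")


def icer(delta_cost: float, delta_qaly: float) -> float | None:
    """Incremental cost-effectiveness ratio; ``None`` when the QALY difference is 0."""
    if delta_qaly == 0.0:
        return None
    return delta_cost / delta_qaly


@dataclass
class CEComparison:
    arm: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None


@dataclass
class CETable:
    """Dominance-annotated incremental analysis of >= 2 arms."""

    #: arms ordered by increasing QALYs (ties broken by lower cost)
    order: list
    #: arm -> status in {"efficient", "dominated", "extendedly_dominated"}
    status: dict
    #: successive comparisons along the efficient frontier
    frontier: list
    #: all ordered pairwise comparisons (next-best style reporting)
    pairwise: list

    def comparison(self, arm: str, comparator: str) -> CEComparison:
        for c in self.pairwise:
            if c.arm == arm and c.comparator == comparator:
                return c
        raise KeyError(f"no comparison {arm} vs {comparator}")


def incremental_analysis(results: Sequence[ArmResult]) -> CETable:
    """Rank arms, flag dominance, and compute frontier and pairwise ICERs."""
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least 2 arms")
    by_arm = {r.arm: r for r in results}
    order = sorted(results, key=lambda r: (r.mean_qalys, r.mean_cost))
    status = {r.arm: "efficient" for r in order}

    # strict dominance: strictly more cost and strictly fewer (or equal) QALYs
    for r in order:
        for other in order:
            if other.arm == r.arm:
                continue
            if other.mean_qalys >= r.mean_qalys and other.mean_cost < r.mean_cost:
                status[r.arm] = "dominated"
            elif other.mean_qalys > r.mean_qalys and other.mean_cost <= r.mean_cost:
                status[r.arm] = "dominated"

    # extended dominance: drop interior options until frontier ICERs increase
    changed = True
    while changed:
        changed = False
        eff = [r for r in order if status[r.arm] == "efficient"]
        for i in range(1, len(eff) - 1):
            icer_here = icer(
                eff[i].mean_cost - eff[i - 1].mean_cost,
                eff[i].mean_qalys - eff[i - 1].mean_qalys,
            )
            icer_next = icer(
                eff[i + 1].mean_cost - eff[i].mean_cost,
                eff[i + 1].mean_qalys - eff[i].mean_qalys,
            )
            if icer_here is not None and icer_next is not None and icer_here > icer_next:
                status[eff[i].arm] = "extendedly_dominated"
                changed = True
                break

    eff = [r for r in order if status[r.arm] == "efficient"]
    frontier = [
        CEComparison(
            b.arm,
            a.arm,
            b.mean_cost - a.mean_cost,
            b.mean_qalys - a.mean_qalys,
            icer(b.mean_cost - a.mean_cost, b.mean_qalys - a.mean_qalys),
        )
        for a, b in zip(eff, eff[1:])
    ]
    pairwise = [
        CEComparison(
            b.arm,
            a.arm,
            b.mean_cost - a.mean_cost,
            b.mean_qalys - a.mean_qalys,
            icer(b.mean_cost - a.mean_cost, b.mean_qalys - a.mean_qalys),
        )
        for a in order
        for b in order
        if a.arm != b.arm and b.mean_qalys >= a.mean_qalys
    ]
    return CETable(
        order=[r.arm for r in order], status=status, frontier=frontier, pairwise=pairwise
    )


def proportional_shortfall(q_remaining: float, q_disease: float) -> float:
    """Fraction of remaining quality-adjusted life expectancy lost to disease."""
    if not q_remaining > 0:
        raise ValueError("q_remaining must be > 0")
    if not 0.0 <= q_disease <= q_remaining:
        raise ValueError("q_disease must lie in [0, q_remaining]")
    return (q_remaining - q_disease) / q_remaining


#: Dutch reimbursement bands: shortfall interval (closed on the right) ->
#: willingness-to-pay threshold in euros/QALY.
DEFAULT_THRESHOLD_BANDS = ((0.10, 0.40, 20_000.0), (0.40, 0.70, 50_000.0), (0.70, 1.00, 80_000.0))


def threshold_from_shortfall(ps: float, band_table=DEFAULT_THRESHOLD_BANDS) -> float | None:
    """Threshold for a proportional shortfall; ``None`` below the lowest band."""
    if not 0.0 <= ps <= 1.0:
        raise ValueError("proportional shortfall must lie in [0, 1]")
    low0 = band_table[0][0]
    if ps < low0:
        return None  # no reimbursement-relevant disease burden
    for low, high, threshold in band_table:
        if (ps == low0 or ps > low) and ps <= high:
            return threshold
    raise ValueError(f"shortfall {ps} not covered by the band table")


def nmb(cost: float, qalys: float, lam: float) -> float:
    """Net monetary benefit lambda*QALYs - cost."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * qalys - cost


def rate_reduction(rate_ref: float, rate_new: float) -> float:
    """Percentage reduction of an event rate versus a reference rate."""
    if rate_ref <= 0:
        raise ValueError("reference rate must be > 0")
    return 100.0 * (rate_ref - rate_new) / rate_ref


def percent_change(value: float, base: float) -> float:
    """Signed percentage change of ``value`` versus ``base``."""
    if base == 0:
        raise ValueError("base must be non-zero")
    return 100.0 * (value - base) / base
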