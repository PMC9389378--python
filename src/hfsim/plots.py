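"""Matplotlib figures for the standard cost-effectiveness outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["ce_plane", "ceac_plot", "tornado_plot"]


def ce_plane(psa_result, arm: str, comparator: str = "UC", ax=None):
    """Incremental cost-effectiveness plane cloud of ``arm`` vs ``comparator``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    dq = [it.mean_qalys[arm] - it.mean_qalys[comparator] for it in psa_result.iterations]
    dc = [it.mean_cost[arm] - it.mean_cost[comparator] for it in psa_result.iterations]
    ax.scatter(dq, dc, s=8, alpha=0.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental costs (€)")
    ax.set_title(f"{arm} vs {comparator}")
    return ax


def ceac_plot(ceac_frame, ax=None):
    """Cost-effectiveness acceptability curves from a :func:`hfsim.ceac` frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for arm, group in ceac_frame.groupby("arm"):
        ax.plot(group["lambda"], group["probability"], label=arm)
    ax.set_xlabel("Willingness to pay (€/QALY)")
    ax.set_ylabel("P(most cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def tornado_plot(dsa_frame, top: int = 5, ax=None):
    """Horizontal tornado bars for the widest-ranging parameters."""
    df = dsa_frame.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.6 * len(df) + 1.5))
    base = df["icer_base"].iloc[0]
    lo = df[["icer_low", "icer_high"]].min(axis=1)
    hi = df[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(df["parameter"], hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.axvline(base, color="black", lw=1)
    ax.set_xlabel("ICER HTM+DA vs UC (€/QALY)")
    return ax
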