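"""Matplotlib figures: cost-effectiveness plane, acceptability curves and
the pre-index parallel-trend plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe
import matplotlib.pyplot as plt


def ce_plane_plot(clouds: dict, wtp: float = 20_000.0):
    """Scatter of bootstrap replicates (QALY gain vs incremental cost), one
    colour per labelled cloud, with the willingness-to-pay ray."""
    fig, ax = plt.subplots(figsize=(6, 5))
    lo, hi = 0.0, 0.0
    for label, cloud in clouds.items():
        ax.scatter(cloud.qaly_gain, cloud.incremental_cost, s=6, alpha=0.35,
                   label=label)
        lo = min(lo, cloud.qaly_gain.min())
        hi = max(hi, cloud.qaly_gain.max())
    xs = [lo * 1.1, hi * 1.1]
    ax.plot(xs, [wtp * x for x in xs], "k--", lw=1,
            label=f"WTP €{wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental effect (QALYs)")
    ax.set_ylabel("Incremental cost (€)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def ceac_plot(curves: dict):
    """Cost-effectiveness acceptability curves, one per labelled group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.lambda_grid, curve.probability, label=label)
    ax.set_xlabel("Willingness to pay λ (€/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def trend_plot(series, outcome_label: str = "Back-pain-specific cost (€)"):
    """Per-quarter pre-index arm means (optionally stratified)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    keys = ["impairment", "arm"] if "impairment" in series.columns else ["arm"]
    for name, grp in series.groupby(keys):
        label = " / ".join(name) if isinstance(name, tuple) else str(name)
        ax.plot(grp["quarter_offset"], grp["mean_cost"], marker="o", ms=3,
                label=label)
    ax.set_xlabel("Quarter relative to index date")
    ax.set_ylabel(outcome_label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
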