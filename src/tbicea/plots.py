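"""Minimal figures: acceptability curve and tornado diagram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_ceac(curve, threshold: float, path) -> None:
    """Probability cost-effective vs willingness-to-pay threshold."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["threshold"], curve["probability"])
    ax.axvline(threshold, linestyle=":", color="grey")
    ax.set_xlabel("willingness-to-pay threshold (per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries, base_icer: float, path) -> None:
    """Horizontal bars spanning each scenario pair's ICER range."""
    rows = [
        (e.scenario_name, e.icer_low, e.icer_high)
        for e in entries
        if e.icer_low is not None and e.icer_high is not None
    ]
    rows.sort(key=lambda r: abs(r[2] - r[1]))
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
    for i, (name, lo, hi) in enumerate(rows):
        left, width = min(lo, hi), abs(hi - lo)
        ax.barh(i, width, left=left, height=0.6, color="steelblue")
    ax.axvline(base_icer, color="black", linestyle="--", linewidth=1)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r[0] for r in rows])
    ax.set_xlabel("ICER (per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
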