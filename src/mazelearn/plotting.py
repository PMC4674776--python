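"""Single static learning-curve plot: group posterior means with 95% bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .inference import LearningCurveSummary


def plot_learning_curves(summaries: list[LearningCurveSummary], path=None):
    """Plot per-group posterior mean curves (trial-resolved, segmented by day)
    with shaded 95% credible bands; returns the figure."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for s in summaries:
        df = s.table
        label = f"{s.group[0]}:{s.group[1]}"
        line = None
        for day, seg in df.groupby("day"):
            tpd = len(seg)
            x = (day - 1) * tpd + seg["trial"]
            (ln,) = ax.plot(
                x, seg["mean"],
                color=None if line is None else line.get_color(),
                label=label if line is None else None,
            )
            line = line or ln
            ax.fill_between(x, seg["lo2.5"], seg["hi97.5"],
                            color=line.get_color(), alpha=0.2, linewidth=0)
    ax.set_xlabel("cumulative trial (segments of one training day)")
    ax.set_ylabel("escape latency (s)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
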