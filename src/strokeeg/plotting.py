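"""Bar plots of group comparisons (mean +/- SEM with significance stars)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .group_stats import GroupComparison


def plot_comparisons(comparisons: list[GroupComparison], out_dir) -> list[Path]:
    """One PNG per band: group means with SEM error bars and the omnibus stars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in comparisons:
        groups = list(c.group_summaries)
        means = [c.group_summaries[g]["mean"] for g in groups]
        sems = [c.group_summaries[g]["sem"] for g in groups]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(groups, means, yerr=sems, capsize=4, color="0.7", edgecolor="0.2")
        ax.set_ylabel(c.metric_name)
        label = f"{c.band}  (F={c.F:.2f}, p={c.p:.3g}, eta2={c.eta_squared:.3f}) {c.stars}"
        ax.set_title(label, fontsize=9)
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        p = out / f"{c.metric_name.lower()}_{c.band}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
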