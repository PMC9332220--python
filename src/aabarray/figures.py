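"""Best-effort plots: reactivity boxplots and a marker reactivity heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .arrays import CLASS_ORDER
from .features import CohortDesign
from .seropositivity import SeroCallMatrix


def plot_immunoreactivity(
    calls: SeroCallMatrix, cohort: pd.DataFrame, path: str | Path
) -> Path:
    """Boxplot of per-sample immunoreactive proportion by disease class."""
    df = pd.DataFrame(
        {
            "proportion": calls.prop_immunoreactive,
            "class": cohort["class"].reindex(calls.calls.index),
        }
    )
    order = [c for c in CLASS_ORDER if c in set(df["class"])]
    fig, ax = plt.subplots(figsize=(6, 4))
    sns.boxplot(data=df, x="class", y="proportion", order=order, whis=(0, 100), ax=ax)
    ax.set_ylabel("proportion of immunoreactive antigens")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_marker_heatmap(design: CohortDesign, markers: list[str], path: str | Path) -> Path:
    """Heatmap of per-class seropositive fractions for the selected markers."""
    order = [c for c in CLASS_ORDER if c in set(design.y)]
    frac = (
        design.X[markers]
        .groupby(design.y)
        .mean()
        .reindex(order)
        .T
    )
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(markers) + 2))
    sns.heatmap(frac, cmap="viridis", annot=False, ax=ax)
    ax.set_xlabel("disease class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
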