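"""Minimal plotting helper: per-trait phenotype boxplots by block."""

from __future__ import annotations

import pandas as pd


def plot_phenotype_boxplots(table: pd.DataFrame, path=None):
    """Boxplots of phenotypic values per trait, split by block.

    Returns the matplotlib figure; writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    traits = list(dict.fromkeys(table["trait"]))
    fig, axes = plt.subplots(1, len(traits), figsize=(4 * len(traits), 4))
    if len(traits) == 1:
        axes = [axes]
    for ax, trait in zip(axes, traits):
        sub = table[table["trait"] == trait]
        blocks = sorted(sub["block_id"].unique())
        ax.boxplot([sub.loc[sub["block_id"] == b, "value"] for b in blocks],
                   tick_labels=blocks)
        ax.set_title(trait)
        ax.set_xlabel("block")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
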