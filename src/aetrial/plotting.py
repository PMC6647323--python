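"""Optional boxplot reporting of simulation results (matplotlib required)."""

from __future__ import annotations

import pandas as pd


def boxplot_operating_characteristics(replicates: pd.DataFrame, out_path: str) -> None:
    """Boxplots of enrolled patient numbers and total trial periods.

    One panel per quantity, grouped by recruitment strategy (and by
    scenario when the table carries several).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    quantities = [
        ("n_enrolled_O", "patients enrolled (O)"),
        ("n_enrolled_P", "patients enrolled (P)"),
        ("total_period", "total trial period"),
    ]
    fig, axes = plt.subplots(1, len(quantities), figsize=(4 * len(quantities), 4))
    strategies = list(replicates["strategy"].unique())
    for ax, (col, label) in zip(axes, quantities):
        data = [replicates.loc[replicates["strategy"] == s, col] for s in strategies]
        box = ax.boxplot(data, labels=strategies, showmeans=True)
        ax.set_ylabel(label)
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
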