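"""Advisory figures: forest plots, occupancy heatmap, regression scatter.

All outputs are diagnostic; no analysis result depends on them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .disproportionality import median_ror_table
from .regression import _PREDICTOR_OF


def forest_subgroups(signals: pd.DataFrame, path) -> None:
    """One forest panel per symptom subgroup (drug-level ROR with 95% CI)."""
    sub = signals[(signals["level"] == "subgroup") & signals["ror"].notna()]
    groups = sorted(sub["event"].unique())
    if not groups:
        return
    fig, axes = plt.subplots(
        1, len(groups), figsize=(3.2 * len(groups), 4), sharey=False, squeeze=False
    )
    for ax, grp in zip(axes[0], groups):
        g = sub[sub["event"] == grp].sort_values("ror")
        y = np.arange(len(g))
        ax.errorbar(
            g["ror"],
            y,
            xerr=[g["ror"] - g["ror_lo"], g["ror_hi"] - g["ror"]],
            fmt="o",
            ms=4,
            lw=1,
            capsize=2,
        )
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xscale("log")
        ax.set_yticks(y, g["drug"])
        ax.set_title(grp, fontsize=9)
        ax.set_xlabel("ROR (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def occupancy_heatmap(occ: pd.DataFrame, path) -> None:
    """Drug x receptor occupancy percentage heatmap."""
    pivot = occ.pivot(index="drug", columns="receptor", values="occupancy_pct")
    fig, ax = plt.subplots(figsize=(1 + 0.6 * pivot.shape[1], 1 + 0.4 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label="occupancy (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_scatter(
    signals,
    occ,
    regression,
    figdir,
    exclude_drugs=("iloperidone",),
    median_over="included",
) -> None:
    """Per receptor x mode scatter of median ROR vs predictor with fit line."""
    drugs = sorted(set(signals["drug"]) - set(exclude_drugs))
    medians = median_ror_table(signals[signals["level"] == "pt"], drugs, over=median_over)
    for _, row in regression.iterrows():
        predictor = _PREDICTOR_OF[row["mode"]]
        pts = (
            occ[(occ["receptor"] == row["receptor"]) & ~occ["drug"].isin(exclude_drugs)]
            .dropna(subset=[predictor])
            .merge(medians.rename("median_ror"), left_on="drug", right_index=True)
            .dropna(subset=["median_ror"])
        )
        if pts.empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 3.2))
        neg = pts[predictor] < 0
        ax.scatter(pts.loc[~neg, predictor], pts.loc[~neg, "median_ror"], c="tab:blue")
        ax.scatter(pts.loc[neg, predictor], pts.loc[neg, "median_ror"], c="tab:red")
        for _, p in pts.iterrows():
            ax.annotate(p["drug"], (p[predictor], p["median_ror"]), fontsize=6)
        xs = np.linspace(pts[predictor].min(), pts[predictor].max(), 50)
        ax.plot(xs, row["intercept"] + row["beta"] * xs, "k-", lw=1)
        ax.set_xlabel(predictor)
        ax.set_ylabel("median ROR")
        ax.set_title(
            f"{row['receptor']} ({row['mode']}): beta={row['beta']:.2f}, "
            f"p={row['p_value']:.3f}, R2={row['r2']:.2f}",
            fontsize=8,
        )
        fig.tight_layout()
        fig.savefig(
            figdir / f"regression_{row['receptor']}_{row['mode']}.png", dpi=120
        )
        plt.close(fig)
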