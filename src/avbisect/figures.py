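"""Summary figures for pipeline outputs.

Each function takes the tidy DataFrames produced by the pipeline and
returns a matplotlib Figure: conflict PSEs with the dominance lines,
explained variance by age, the weight-vs-weight scatter, average weights
by age, and thresholds by age with significance stars.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; figures are written to files
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_pse_vs_conflict",
    "plot_r2_by_age",
    "plot_weight_scatter",
    "plot_weights_by_age",
    "plot_thresholds_by_age",
    "save_all",
]


def _domains(df: pd.DataFrame):
    return sorted(df["domain"].unique())


def plot_pse_vs_conflict(conflict_pses: pd.DataFrame) -> plt.Figure:
    """Symmetric conflict PSEs per age group; red = visual dominance (+Δ),
    green = auditory dominance (−Δ)."""
    doms = _domains(conflict_pses)
    groups = list(conflict_pses["age_group"].unique())
    fig, axes = plt.subplots(
        len(doms), len(groups), figsize=(3 * len(groups), 3 * len(doms)),
        squeeze=False, sharex="row", sharey="row",
    )
    for i, dom in enumerate(doms):
        sub_d = conflict_pses[conflict_pses["domain"] == dom]
        lim = 1.2 * sub_d["conflict"].abs().max()
        line = np.array([-lim, lim])
        for j, grp in enumerate(groups):
            ax = axes[i][j]
            sub = sub_d[sub_d["age_group"] == grp]
            ax.plot(line, line, color="crimson", lw=1, label="visual dominance")
            ax.plot(line, -line, color="seagreen", lw=1, label="auditory dominance")
            for _, obs in sub.groupby("observer_id"):
                ax.plot(obs["conflict"], obs["pse_symmetric"],
                        "o-", ms=3, lw=0.6, alpha=0.6, color="steelblue")
            ax.set_title(f"{dom} / {grp}", fontsize=9)
            if j == 0:
                unit = sub_d["unit"].iloc[0] if len(sub_d) else ""
                ax.set_ylabel(f"PSE ({unit})")
            ax.set_xlabel(f"conflict Δ")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_r2_by_age(group_summary: pd.DataFrame) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for dom, sub in group_summary.groupby("domain"):
        ax.plot(sub["age_group"], sub["r_squared"], "o-", label=dom)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axhline(1, color="gray", lw=0.5, ls="--")
    ax.set_ylabel("explained variance $R^2$")
    ax.set_xlabel("age group")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_weight_scatter(weights: pd.DataFrame) -> plt.Figure:
    """Auditory weight from thresholds vs from the conflict slope."""
    doms = _domains(weights)
    fig, axes = plt.subplots(1, len(doms), figsize=(4 * len(doms), 3.8),
                             squeeze=False)
    for j, dom in enumerate(doms):
        ax = axes[0][j]
        sub = weights[weights["domain"] == dom]
        for grp, g in sub.groupby("age_group"):
            ax.plot(g["w_a_slope"], g["w_a_thresholds"], "o", ms=4, label=grp)
        ax.plot([0, 1], [0, 1], color="k", lw=1)
        ax.set_xlim(-0.3, 1.3)
        ax.set_ylim(-0.05, 1.05)
        ax.set_xlabel("$w_A$ from PSE slope")
        ax.set_ylabel("$w_A$ from thresholds")
        ax.set_title(dom)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_weights_by_age(group_summary: pd.DataFrame) -> plt.Figure:
    doms = _domains(group_summary)
    fig, axes = plt.subplots(1, len(doms), figsize=(4 * len(doms), 3.5),
                             squeeze=False)
    for j, dom in enumerate(doms):
        ax = axes[0][j]
        sub = group_summary[group_summary["domain"] == dom]
        ax.errorbar(sub["age_group"], sub["w_a_thresholds_mean"],
                    yerr=sub["w_a_thresholds_sem"], fmt="o-", color="gray",
                    label="from thresholds")
        ax.errorbar(sub["age_group"], sub["w_a_slope_mean"],
                    yerr=sub["w_a_slope_sem"], fmt="s-", color="royalblue",
                    label="from PSEs")
        ax.set_ylabel("auditory weight $w_A$")
        ax.set_title(dom)
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_thresholds_by_age(
    group_summary: pd.DataFrame, comparisons: pd.DataFrame
) -> plt.Figure:
    doms = _domains(group_summary)
    fig, axes = plt.subplots(1, len(doms), figsize=(4.5 * len(doms), 3.8),
                             squeeze=False)
    series = [
        ("sigma_v", "visual", "crimson"),
        ("sigma_a", "auditory", "seagreen"),
        ("sigma_bimodal", "bimodal", "royalblue"),
        ("sigma_va_pred", "MLE prediction", "gray"),
    ]
    for j, dom in enumerate(doms):
        ax = axes[0][j]
        sub = group_summary[group_summary["domain"] == dom]
        for col, label, color in series:
            ax.errorbar(sub["age_group"], sub[f"{col}_mean"],
                        yerr=sub[f"{col}_sem"], fmt="o-", color=color,
                        label=label)
        comp = comparisons[comparisons["domain"] == dom] if len(comparisons) else None
        if comp is not None:
            top = np.nanmax(sub[[f"{c}_mean" for c, _, _ in series]].to_numpy())
            for _, row in comp.iterrows():
                stars = "**" if row["significant_01"] else (
                    "*" if row["significant_05"] else "")
                if stars:
                    ax.annotate(stars, (row["age_group"], top * 1.05),
                                ha="center", fontsize=12)
        ax.set_ylabel("threshold σ")
        ax.set_title(dom)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def save_all(result_dir, out_dir, fmt: str = "png") -> list:
    """Regenerate every figure from a pipeline output directory."""
    result_dir, out = Path(result_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pses = pd.read_csv(result_dir / "conflict_pses.csv")
    weights = pd.read_csv(result_dir / "weights.csv")
    summary = pd.read_csv(result_dir / "group_summary.csv")
    comparisons = pd.read_csv(result_dir / "comparisons.csv")
    made = []
    for name, fig in [
        ("pse_vs_conflict", plot_pse_vs_conflict(pses)),
        ("r2_by_age", plot_r2_by_age(summary)),
        ("weight_scatter", plot_weight_scatter(weights)),
        ("weights_by_age", plot_weights_by_age(summary)),
        ("thresholds_by_age", plot_thresholds_by_age(summary, comparisons)),
    ]:
        path = out / f"{name}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        made.append(path)
    return made
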