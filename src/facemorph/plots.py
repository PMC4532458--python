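"""Figure generation (vector graphics; every figure has a companion table)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .stats import mean_ci


def plot_response_curves(curve_frame: pd.DataFrame, path, title: str = "") -> None:
    """Group-mean percent-angry curves over the morph grid, one line per
    condition (the main-results style figure)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    grp = curve_frame.groupby(["condition", "morph"])["p_angry"].mean().reset_index()
    for cond, g in grp.groupby("condition"):
        ax.plot(g["morph"], 100 * g["p_angry"], marker="o", label=str(cond))
    ax.set_xlabel("morph fraction (0 = fear, 1 = anger)")
    ax.set_ylabel("% angry responses")
    ax.set_ylim(-2, 102)
    ax.legend(title="condition", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_violin_ci(fit_frame: pd.DataFrame, parameter: str, path,
                   title: str = "") -> None:
    """Violin plot of a fitted parameter per condition with 95% CIs of the
    mean overlaid as bars."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    order = sorted(fit_frame["condition"].unique())
    sns.violinplot(data=fit_frame, x="condition", y=parameter, order=order,
                   inner="quartile", ax=axes[0], cut=0)
    axes[0].set_title("distribution")
    for i, cond in enumerate(order):
        vals = fit_frame.loc[fit_frame["condition"] == cond, parameter].dropna()
        m, lo, hi = mean_ci(vals)
        axes[1].plot([i, i], [lo, hi], color="red", lw=3)
        axes[1].plot(i, m, "ko")
    axes[1].set_xticks(range(len(order)), order)
    axes[1].set_title("mean with 95% CI")
    for ax in axes:
        ax.tick_params(axis="x", rotation=20)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ss_heatmap(similarity: pd.DataFrame, path, title: str = "") -> None:
    """Mean condition x condition ss2 matrix over participants and directions."""
    mat = similarity[~similarity["missing"]].pivot_table(
        index="train_condition", columns="test_condition", values="ss2",
        aggfunc="mean")
    fig, ax = plt.subplots(figsize=(5, 4))
    sns.heatmap(mat, annot=True, fmt=".3f", cmap="viridis", ax=ax)
    ax.set_title(title or "split-half ss2")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_identity_correction(raw_curves: pd.DataFrame, corrected: pd.DataFrame,
                             path, title: str = "") -> None:
    """Identity-mean curves before vs after threshold normalization."""
    conds = sorted(corrected["condition"].unique())
    fig, axes = plt.subplots(1, len(conds), figsize=(3.2 * len(conds), 3.4),
                             sharey=True, squeeze=False)
    for ax, cond in zip(axes[0], conds):
        pre = raw_curves[raw_curves["condition"] == cond] \
            .groupby("morph")["p_angry"].mean()
        post = corrected[corrected["condition"] == cond]
        ax.plot(pre.index, 100 * pre.values, "o-", label="uncorrected")
        ax.plot(post["morph"], 100 * post["p"], "s-", label="threshold-aligned")
        ax.set_title(str(cond), fontsize=9)
        ax.set_xlabel("morph fraction")
    axes[0][0].set_ylabel("% angry responses")
    axes[0][0].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
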