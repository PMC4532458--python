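"""Split-half cross-validation of response curves.

One half of each participant's experiment predicts the other half, in both
directions, with similarity measured by the sum of squared errors (ss2)
between 11-point response curves.  Two analyses are provided:

* `condition_similarity`: the condition x condition ss2 matrix per
  participant and direction, plus a group-level test of diagonal dominance
  (each condition should be closest to its analogue from the other half).
* `model_vs_raw`: does an anchored-logistic fit to the training half
  predict the held-out half better than the raw training curve itself?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ResponseCurve, aggregate_to_curves
from .psychometric import evaluate, fit_anchored_logistic
from .stats import dual_paired_test


def ss2(a, b) -> float:
    """Sum of squared pointwise differences between two curves.

    Positions undefined (NaN) in either curve are excluded pairwise; an
    empty overlap is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share their x positions")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no overlapping defined positions")
    d = a[ok] - b[ok]
    return float(np.dot(d, d))


def assign_halves(trials: pd.DataFrame) -> pd.DataFrame:
    """Return trials with a ``half`` column (1 or 2).

    With two or more runs the halves are the runs (first vs second
    pass of the experiment).  With a single run — the blocked composite
    design — halves are defined by occurrence order within each
    (participant, block, condition, morph) cell: the earlier half of that
    cell's trials in schedule order forms half 1.
    """
    t = trials.copy()
    if t["run"].nunique() >= 2:
        first = sorted(t["run"].unique())[:1][0]
        t["half"] = np.where(t["run"] == first, 1, 2)
    else:
        keys = ["participant", "block", "condition", "morph"]
        order = t.groupby(keys).cumcount()
        size = t.groupby(keys)["response"].transform("size")
        t["half"] = np.where(order < size / 2, 1, 2)
    return t


def _half_curves(trials: pd.DataFrame):
    """{(participant, half, condition): ResponseCurve}"""
    t = assign_halves(trials)
    out = {}
    for half, g in t.groupby("half"):
        for c in aggregate_to_curves(g, grouping="participant"):
            out[(c.key["participant"], half, c.key["condition"])] = c
    return out


def condition_similarity(trials: pd.DataFrame) -> pd.DataFrame:
    """Long-format ss2 matrices: one row per (participant, direction,
    train condition, test condition).

    Direction ``1->2`` compares each half-1 (train) curve to every half-2
    (test) curve, and vice versa.
    """
    curves = _half_curves(trials)
    participants = sorted({k[0] for k in curves})
    conditions = sorted({k[2] for k in curves})
    rows = []
    for p in participants:
        for train_half, test_half, direction in ((1, 2, "1->2"), (2, 1, "2->1")):
            for ci in conditions:
                for cj in conditions:
                    a = curves.get((p, train_half, ci))
                    b = curves.get((p, test_half, cj))
                    if a is None or b is None:
                        rows.append({"participant": p, "direction": direction,
                                     "train_condition": ci, "test_condition": cj,
                                     "ss2": np.nan, "missing": True})
                        continue
                    rows.append({"participant": p, "direction": direction,
                                 "train_condition": ci, "test_condition": cj,
                                 "ss2": ss2(a.p, b.p), "missing": False})
    return pd.DataFrame(rows)


def diagonal_dominance_test(similarity: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Is each condition significantly closest to its own analogue?

    For every train condition, the diagonal ss2 (averaged over the two
    directions per participant) is compared against each off-diagonal entry
    in its row with the dual-criterion paired test.  A condition passes when
    every off-diagonal comparison is significant with the diagonal smaller.
    """
    sim = similarity[~similarity["missing"]]
    per = sim.groupby(["participant", "train_condition", "test_condition"])["ss2"] \
             .mean().reset_index()
    conditions = sorted(per["train_condition"].unique())
    rows = []
    for ci in conditions:
        diag = per[(per["train_condition"] == ci) & (per["test_condition"] == ci)] \
            .set_index("participant")["ss2"]
        all_sig = True
        for cj in conditions:
            if cj == ci:
                continue
            off = per[(per["train_condition"] == ci) & (per["test_condition"] == cj)] \
                .set_index("participant")["ss2"]
            common = diag.index.intersection(off.index)
            res = dual_paired_test(diag.loc[common], off.loc[common], alpha=alpha,
                                   label=f"{ci} self vs {cj}")
            smaller = diag.loc[common].mean() < off.loc[common].mean()
            sig = bool(res.significant and smaller)
            all_sig &= sig
            rows.append({"condition": ci, "versus": cj,
                         "mean_self_ss2": diag.loc[common].mean(),
                         "mean_other_ss2": off.loc[common].mean(),
                         "p_t": res.p_t, "p_w": res.p_w,
                         "significant": sig, "alpha": alpha})
        for r in rows:
            if r["condition"] == ci:
                r["condition_dominant"] = all_sig
    return pd.DataFrame(rows)


def model_vs_raw(trials: pd.DataFrame) -> pd.DataFrame:
    """Fitted-function vs raw-data prediction of the left-out half.

    For each participant, condition and direction, the anchored logistic is
    fitted to the training half's curve and evaluated at the stimulus grid;
    ``ss2_model`` compares that prediction with the test half, ``ss2_raw``
    compares the raw training curve with the test half.  Degenerate training
    fits fall back to the raw curve as their own prediction (flagged).
    """
    curves = _half_curves(trials)
    rows = []
    for (p, half, cond), train in sorted(curves.items(), key=lambda kv: str(kv[0])):
        test_half = 2 if half == 1 else 1
        test = curves.get((p, test_half, cond))
        if test is None:
            continue
        fit = fit_anchored_logistic(train)
        if fit.degenerate:
            pred = train.p
        else:
            pred = evaluate(fit, train.x)
            pred = np.where(train.defined(), pred, np.nan)
        rows.append({"participant": p, "condition": cond,
                     "direction": f"{half}->{test_half}",
                     "ss2_model": ss2(pred, test.p),
                     "ss2_raw": ss2(train.p, test.p),
                     "degenerate_fit": fit.degenerate})
    return pd.DataFrame(rows)


def model_vs_raw_test(comparison: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group-level dual-criterion test, per condition, of whether the fitted
    function predicts held-out data better than the raw curve."""
    per = comparison.groupby(["participant", "condition"])[["ss2_model", "ss2_raw"]] \
                    .mean().reset_index()
    rows = []
    for cond, g in per.groupby("condition"):
        res = dual_paired_test(g["ss2_model"], g["ss2_raw"], alpha=alpha,
                               label=f"{cond}: model vs raw")
        rows.append({"condition": cond,
                     "mean_ss2_model": g["ss2_model"].mean(),
                     "mean_ss2_raw": g["ss2_raw"].mean(),
                     "model_wins": g["ss2_model"].mean() < g["ss2_raw"].mean(),
                     "p_t": res.p_t, "p_w": res.p_w,
                     "significant": res.significant, "alpha": alpha})
    return pd.DataFrame(rows)
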