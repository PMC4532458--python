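"""Summary tables in the shape of the experiments' parameter tables:
per-condition mean (SD) of each curve parameter with compact letter
groupings from dual-criterion pairwise tests, plus repeated-measures ANOVA
columns (F, df, p, partial eta squared)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import dual_paired_test, letter_display, rm_anova

PARAMETERS = ("x_threshold", "y_threshold", "slope")


def _split_exp2_condition(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    parts = out["condition"].str.split("_", expand=True)
    out["judged_half"] = parts[0]
    out["distractor"] = parts[1]
    return out


def parameter_table(fit_frame: pd.DataFrame, experiment: int,
                    alpha: float = 0.05) -> pd.DataFrame:
    """One row per curve parameter; per-condition ``mean (SD)^letters``
    columns plus ANOVA statistics.

    Experiment 1 runs a one-way (masking condition) repeated-measures
    ANOVA; experiment 2 a 2x2 (judged half x distractor emotion) ANOVA
    whose three effect columns are reported side by side.
    """
    conditions = sorted(fit_frame["condition"].unique())
    rows = []
    for param in PARAMETERS:
        sub = fit_frame[["participant", "condition", param]].dropna()
        letters = letter_display(sub, group="condition", value=param,
                                 subject="participant", alpha=alpha)
        row = {"parameter": param}
        for c in conditions:
            vals = sub.loc[sub["condition"] == c, param]
            row[c] = f"{vals.mean():.2f}{letters[c]} ({vals.std(ddof=1):.2f})"
        if experiment == 1:
            an = rm_anova(sub, dv=param, within="condition", subject="participant")
            e = an.iloc[0]
            row.update({"F": round(e["F"], 2), "df1": round(e["df1_gg"], 1),
                        "df2": round(e["df2_gg"], 1),
                        "p": e["p_gg"] if e["corrected"] else e["p"],
                        "np2": round(e["np2"], 3)})
        else:
            sub2 = _split_exp2_condition(sub)
            an = rm_anova(sub2, dv=param, within=["judged_half", "distractor"],
                          subject="participant")
            for _, e in an.iterrows():
                tag = {"judged_half": "half", "distractor": "emotion",
                       "judged_half:distractor": "interaction"}[e["effect"]]
                row.update({f"F_{tag}": round(e["F"], 2),
                            f"p_{tag}": e["p"],
                            f"np2_{tag}": round(e["np2"], 3)})
        rows.append(row)
    return pd.DataFrame(rows)


def condition_means(fit_frame: pd.DataFrame) -> pd.DataFrame:
    """Plain numeric per-condition means and SDs of the curve parameters."""
    g = fit_frame.groupby("condition")[list(PARAMETERS)]
    means = g.mean().add_suffix("_mean")
    sds = g.std(ddof=1).add_suffix("_sd")
    return means.join(sds).reset_index()
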