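"""Canonical trial-log format, validation, screening and curve aggregation.

The canonical log is a delimited text table (comma or tab, auto-detected)
with one row per 2AFC trial.  Deposited raw-data archives with a different
internal layout are ingested through a configurable column mapping; rows
violating the record invariants are rejected with line-numbered diagnostics.
"""

from __future__ import annotations

import io as _io
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (DISTRACTOR_NONE, EXP1_CONDITIONS, EXP2_CONDITIONS,
                     MorphGrid)

MANDATORY_COLUMNS = ("participant", "experiment", "run", "condition",
                     "identity", "morph", "response")
OPTIONAL_COLUMNS = ("block", "distractor", "rt")


class FormatError(ValueError):
    """The file cannot be interpreted as a trial log."""


class ValidationError(ValueError):
    """Rows violate the trial-record invariants."""


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def _read_delimited(path) -> pd.DataFrame:
    if str(path).endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            members = [m for m in zf.namelist()
                       if m.lower().endswith((".csv", ".txt", ".tsv", ".dat"))]
            if not members:
                raise FormatError(f"no delimited table found inside {path}")
            with zf.open(members[0]) as fh:
                return pd.read_csv(_io.TextIOWrapper(fh, "utf-8"),
                                   sep=None, engine="python")
    return pd.read_csv(path, sep=None, engine="python")


def read_trials(path, column_map: dict | None = None,
                grid: MorphGrid | None = None,
                validate: bool = True) -> pd.DataFrame:
    """Read and validate a trial log.

    Parameters
    ----------
    column_map : dict, optional
        Mapping ``canonical name -> name in the file`` for logs whose header
        differs from the canonical one (e.g. the deposited raw-data archive).
    grid : MorphGrid, optional
        Stimulus grid the morph fractions must lie on (default 11 levels).
    """
    raw = _read_delimited(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing_src = [s for s in rename if s not in raw.columns]
        if missing_src:
            raise FormatError(f"mapped columns absent from file: {missing_src}")
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {missing}")
    keep = [c for c in (*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS) if c in raw.columns]
    trials = raw[keep].copy()
    if "block" not in trials:
        trials["block"] = ""
    trials["block"] = trials["block"].fillna("")
    if "distractor" not in trials:
        trials["distractor"] = DISTRACTOR_NONE
    if validate:
        validate_trials(trials, grid=grid)
    return trials


def validate_trials(trials: pd.DataFrame, grid: MorphGrid | None = None) -> None:
    """Raise ValidationError naming the 1-based file lines of offending rows
    (line 1 is the header, so data row *i* is line *i* + 2)."""
    grid = grid or MorphGrid()
    levels = grid.as_array()
    problems: list[str] = []

    morph = pd.to_numeric(trials["morph"], errors="coerce").to_numpy(dtype=float)
    on_grid = np.any(np.abs(morph[:, None] - levels[None, :]) < 1e-9, axis=1)
    for i in np.nonzero(~on_grid)[0]:
        problems.append(f"line {i + 2}: morph {trials['morph'].iat[i]!r} not on the stimulus grid")

    resp = pd.to_numeric(trials["response"], errors="coerce").to_numpy(dtype=float)
    bad_resp = ~np.isin(resp, (0.0, 1.0))
    for i in np.nonzero(bad_resp)[0]:
        problems.append(f"line {i + 2}: response {trials['response'].iat[i]!r} is not binary")

    exp = pd.to_numeric(trials["experiment"], errors="coerce").to_numpy(dtype=float)
    vocab = {1.0: set(EXP1_CONDITIONS), 2.0: set(EXP2_CONDITIONS)}
    for i, (e, c) in enumerate(zip(exp, trials["condition"])):
        allowed = vocab.get(e)
        if allowed is None:
            problems.append(f"line {i + 2}: experiment {trials['experiment'].iat[i]!r} unknown")
        elif c not in allowed:
            problems.append(f"line {i + 2}: condition {c!r} not valid for experiment {int(e)}")

    if problems:
        shown = "\n".join(problems[:20])
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        raise ValidationError(f"{len(problems)} invalid rows:\n{shown}{more}")


@dataclass
class ScreeningResult:
    kept: list
    excluded: list
    reasons: pd.DataFrame  # one row per participant with the evidence


def screen_participants(trials: pd.DataFrame, accuracy_floor: float = 0.60,
                        rt_floor: float = 300.0) -> ScreeningResult:
    """Flag non-compliant participants.

    A participant is excluded iff their accuracy on the two unambiguous
    endpoint morphs (0 and 1), pooled over conditions, falls below
    ``accuracy_floor`` AND their median reaction time is below ``rt_floor``
    ms.  The rule is a conjunction: fast but accurate, or inaccurate but
    slow, participants are kept.  Without an RT column nobody is excluded.
    """
    if trials.empty:
        raise ValueError("no trials to screen")
    ends = trials[trials["morph"].isin((0.0, 1.0))]
    correct = (ends["response"].astype(float) == ends["morph"].astype(float))
    acc = correct.groupby(ends["participant"]).mean()
    if "rt" in trials.columns:
        med_rt = trials.groupby("participant")["rt"].median()
    else:
        med_rt = pd.Series(np.nan, index=acc.index)
    tab = pd.DataFrame({"endpoint_accuracy": acc, "median_rt": med_rt})
    tab["excluded"] = (tab["endpoint_accuracy"] < accuracy_floor) & \
                      (tab["median_rt"] < rt_floor)
    tab["reason"] = np.where(
        tab["excluded"],
        "endpoint accuracy below floor with exceptionally fast responses", "")
    tab = tab.rename_axis("participant").reset_index()
    return ScreeningResult(
        kept=tab.loc[~tab["excluded"], "participant"].tolist(),
        excluded=tab.loc[tab["excluded"], "participant"].tolist(),
        reasons=tab,
    )


@dataclass
class ResponseCurve:
    """Proportion-angry over the morph grid for one grouping cell.

    ``p`` is NaN (and ``n`` 0) at grid positions with no trials; such
    positions are excluded from fitting, never imputed.
    """

    key: dict
    x: np.ndarray
    p: np.ndarray
    n: np.ndarray

    def defined(self) -> np.ndarray:
        return self.n > 0

    @property
    def condition(self):
        return self.key.get("condition")


def aggregate_to_curves(trials: pd.DataFrame, grouping: str = "participant",
                        by_run: bool = False, extra_keys: tuple = (),
                        grid: MorphGrid | None = None) -> list[ResponseCurve]:
    """Aggregate trials into per-cell response curves.

    ``grouping`` selects the main unit ("participant" or "identity"); curves
    are always split by condition, and additionally by run when ``by_run``.
    """
    if grouping not in ("participant", "identity"):
        raise ValueError("grouping must be 'participant' or 'identity'")
    grid = grid or MorphGrid()
    levels = grid.as_array()
    keys = [grouping, "condition"] + (["run"] if by_run else []) + list(extra_keys)
    curves = []
    for key_vals, g in trials.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        agg = g.groupby("morph")["response"].agg(["mean", "count"])
        p = np.full(len(levels), np.nan)
        n = np.zeros(len(levels), dtype=int)
        for m, row in agg.iterrows():
            idx = int(np.argmin(np.abs(levels - m)))
            p[idx] = row["mean"]
            n[idx] = int(row["count"])
        curves.append(ResponseCurve(key=dict(zip(keys, key_vals)),
                                    x=levels.copy(), p=p, n=n))
    return curves


def curves_to_frame(curves: list[ResponseCurve]) -> pd.DataFrame:
    """Tidy long table: one row per (curve, grid position)."""
    rows = []
    for c in curves:
        for x, p, n in zip(c.x, c.p, c.n):
            rows.append({**c.key, "morph": x, "p_angry": p, "n": n})
    return pd.DataFrame(rows)
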