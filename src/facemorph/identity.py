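"""Per-identity threshold normalization.

Different face identities cross the fear/anger category boundary at
different physical morph levels, which blurs the group-average sigmoid.
The correction fits each identity's response curve, rigidly shifts every
identity's data so its fitted x- and y-thresholds coincide with the
condition mean, re-bins the shifted points onto the stimulus grid and
averages — revealing the curve shape the group would show if all identities
shared a common boundary.  Shifts are rigid translations, so no identity's
fitted slope is changed by the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .design import MorphGrid
from .io import ResponseCurve, aggregate_to_curves
from .psychometric import PsychometricFit, fit_anchored_logistic, fits_to_frame


@dataclass
class ShiftRecord:
    """Rigid translation taking one identity's thresholds to the condition mean."""

    identity: int
    condition: str
    dx: float  # identity x-threshold minus condition mean x-threshold
    dy: float


def fit_identities(identity_curves: list[ResponseCurve]):
    """Fit each identity x condition curve and derive shift records.

    Returns ``(fits, shifts)``.  Degenerate identity fits are excluded from
    the condition means with a warning; their shifts are undefined (NaN).
    """
    fits = [fit_anchored_logistic(c) for c in identity_curves]
    frame = fits_to_frame(fits)
    shifts = []
    for cond, g in frame.groupby("condition"):
        usable = g[~g["degenerate"]]
        if len(usable) < len(g):
            warnings.warn(f"condition {cond!r}: {len(g) - len(usable)} degenerate "
                          "identity fits excluded from the mean threshold")
        mx = usable["x_threshold"].mean()
        my = usable["y_threshold"].mean()
        for _, row in g.iterrows():
            if row["degenerate"]:
                shifts.append(ShiftRecord(row["identity"], cond, np.nan, np.nan))
            else:
                shifts.append(ShiftRecord(row["identity"], cond,
                                          row["x_threshold"] - mx,
                                          row["y_threshold"] - my))
    return fits, shifts


def shifts_to_frame(shifts: list[ShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"identity": s.identity, "condition": s.condition,
                          "dx": s.dx, "dy": s.dy} for s in shifts])


def apply_shifts(identity_curves: list[ResponseCurve], shifts: list[ShiftRecord],
                 grid: MorphGrid | None = None, bin_halfwidth: float = 0.05):
    """Shift each identity's raw points by its (dx, dy) and re-bin.

    Each defined point (x, p) of identity j becomes (x - dx_j, p - dy_j);
    shifted points are assigned to the nearest grid level when within
    ``bin_halfwidth`` of it and dropped when they fall outside the grid's
    outermost bins.  Shifted p values are deliberately NOT clipped to
    [0, 1], keeping the transformation invertible.

    Returns a DataFrame with one row per (condition, grid level):
    ``p`` the mean shifted proportion, ``n`` the point count, plus a
    ``dropped`` count per condition.
    """
    grid = grid or MorphGrid()
    levels = grid.as_array()
    smap = {(s.identity, s.condition): s for s in shifts}
    rows = []
    for cond in sorted({c.condition for c in identity_curves}):
        binned: dict[int, list] = {i: [] for i in range(len(levels))}
        dropped = 0
        for c in identity_curves:
            if c.condition != cond:
                continue
            s = smap.get((c.key["identity"], cond))
            if s is None or not np.isfinite(s.dx):
                raise ValueError(f"no defined shift for identity "
                                 f"{c.key['identity']} in {cond!r}")
            for x, p, n in zip(c.x, c.p, c.n):
                if n == 0:
                    continue
                xs, ps = x - s.dx, p - s.dy
                j = int(np.argmin(np.abs(levels - xs)))
                if abs(levels[j] - xs) <= bin_halfwidth + 1e-12:
                    binned[j].append(ps)
                else:
                    dropped += 1
        for j, vals in binned.items():
            rows.append({"condition": cond, "morph": levels[j],
                         "p": np.mean(vals) if vals else np.nan,
                         "n": len(vals), "dropped": dropped})
    return pd.DataFrame(rows)


class IdentityThresholdNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style wrapper: ``fit`` learns per-identity shifts from
    identity-level curves, ``transform`` returns the re-binned group curves.
    """

    def __init__(self, bin_halfwidth: float = 0.05):
        self.bin_halfwidth = bin_halfwidth

    def fit(self, curves: list[ResponseCurve], y=None):
        self.fits_, self.shifts_ = fit_identities(curves)
        return self

    def transform(self, curves: list[ResponseCurve]) -> pd.DataFrame:
        return apply_shifts(curves, self.shifts_,
                            bin_halfwidth=self.bin_halfwidth)


def identity_normalize(trials: pd.DataFrame, grid: MorphGrid | None = None):
    """End-to-end correction from a trial table.

    Aggregates identity-level curves (averaged across participants), learns
    the shifts and re-bins.  Returns ``(fits_frame, shifts_frame,
    corrected_curves, raw_identity_curves)``.
    """
    curves = aggregate_to_curves(trials, grouping="identity", grid=grid)
    fits, shifts = fit_identities(curves)
    corrected = apply_shifts(curves, shifts, grid=grid)
    return fits_to_frame(fits), shifts_to_frame(shifts), corrected, curves
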