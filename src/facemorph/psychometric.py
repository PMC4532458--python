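"""Anchored-logistic psychometric fitting.

The psychometric model is a logistic whose lower and upper limits are
*anchored* at the minimum and maximum of the observed response proportions,

    f(x) = L + (U - L) / (1 + exp(-beta (x - alpha))),

so that a best-fitting s-shape is obtained even for observers whose
responses never cross 50%.  Only (alpha, beta) are free; they are estimated
by nonlinear least squares on the proportions.  The category-boundary
summary is the steepest point of the fitted curve: its x-position
(x-threshold, = alpha), its height (y-threshold, = (L + U) / 2) and the
maximal first derivative (slope, = (U - L) beta / 4).

`AnchoredLogistic` is a scikit-learn style estimator (``fit`` /
``predict`` on morph fractions vs proportions); the module-level functions
are thin wrappers over it operating on `ResponseCurve` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import logistic
from .io import ResponseCurve


@dataclass
class PsychometricFit:
    """Anchored-logistic parameters plus the derived boundary summary."""

    lower: float
    upper: float
    alpha: float
    beta: float
    x_threshold: float
    y_threshold: float
    slope: float
    sse: float
    converged: bool
    degenerate: bool
    n_points: int
    key: dict = field(default_factory=dict)


def _column(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of morph fractions")
        X = X[:, 0]
    return X


class AnchoredLogistic(RegressorMixin, BaseEstimator):
    """Least-squares anchored-logistic regressor for 2AFC response curves.

    Parameters
    ----------
    beta_max : float
        Upper bound on the steepness (lower bound is 0: the task direction
        fear -> anger fixes the curve orientation; decreasing observers
        surface as near-degenerate fits rather than being flipped).
    alpha_bounds : pair of float
        Wide box on the location: thresholds may sit outside the morph
        range [0, 1], but on a near-flat curve the location is unidentified
        and would otherwise diverge as beta approaches 0.
    max_nfev : int
        Function-evaluation budget per optimizer start.
    tol : float
        Cost-improvement tolerance for convergence.
    n_starts : bool
        Use a small multi-start grid in addition to the data-driven
        initialization, guarding against local minima on noisy curves.

    Attributes (after ``fit``)
    --------------------------
    lower_, upper_ : anchors = min / max of the fitted proportions
    alpha_, beta_ : location and steepness of the logistic core
    x_threshold_, y_threshold_, slope_ : steepest-point summary
    sse_ : residual sum of squares
    converged_, degenerate_ : diagnostics (degenerate means L == U)
    """

    def __init__(self, beta_max: float = 200.0, max_nfev: int = 500,
                 tol: float = 1e-12, multi_start: bool = True,
                 alpha_bounds: tuple = (-2.0, 3.0)):
        self.beta_max = beta_max
        self.max_nfev = max_nfev
        self.tol = tol
        self.multi_start = multi_start
        self.alpha_bounds = alpha_bounds

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 4:
            raise ValueError("need at least 4 defined points to fit")
        L, U = float(np.min(y)), float(np.max(y))
        self.lower_, self.upper_ = L, U
        self.n_points_ = int(x.size)
        if U - L == 0.0:
            self.alpha_ = np.nan
            self.beta_ = 0.0
            self.degenerate_ = True
            self.converged_ = True
            self.sse_ = float(np.sum((y - L) ** 2))
            self.x_threshold_ = np.nan
            self.y_threshold_ = L
            self.slope_ = 0.0
            return self
        self.degenerate_ = False

        span = U - L

        def resid(theta):
            a, b = theta
            return y - (L + span * logistic(x, a, b))

        starts = [(self._alpha_init(x, y, L, U), 1.0)]
        if self.multi_start:
            starts += [(a0, b0) for a0 in (starts[0][0], 0.25, 0.5, 0.75)
                       for b0 in (4.0, 16.0, 64.0)]
        best = None
        converged = False
        a_lo, a_hi = self.alpha_bounds
        for a0, b0 in starts:
            res = least_squares(resid,
                                x0=[np.clip(a0, a_lo, a_hi),
                                    min(b0, self.beta_max)],
                                bounds=([a_lo, 0.0], [a_hi, self.beta_max]),
                                ftol=self.tol, xtol=1e-14, gtol=1e-14,
                                max_nfev=self.max_nfev)
            if best is None or res.cost < best.cost:
                best = res
            converged = converged or res.status > 0
        self.alpha_ = float(best.x[0])
        self.beta_ = float(best.x[1])
        self.converged_ = bool(converged)
        self.sse_ = float(2.0 * best.cost)
        self.x_threshold_ = self.alpha_
        self.y_threshold_ = 0.5 * (L + U)
        self.slope_ = span * self.beta_ / 4.0
        return self

    @staticmethod
    def _alpha_init(x, y, L, U):
        """Linear-interpolated x where the curve crosses (L + U) / 2."""
        mid = 0.5 * (L + U)
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        s = ys - mid
        for i in range(len(xs) - 1):
            if s[i] == 0.0:
                return float(xs[i])
            if s[i] < 0.0 <= s[i + 1]:
                t = s[i] / (s[i] - s[i + 1])
                return float(xs[i] + t * (xs[i + 1] - xs[i]))
        return 0.5

    def predict(self, X):
        check_is_fitted(self, "lower_")
        x = _column(X)
        if self.degenerate_:
            return np.full(x.shape, self.lower_)
        return self.lower_ + (self.upper_ - self.lower_) * logistic(x, self.alpha_, self.beta_)

    def derivative(self, X):
        """First derivative of the fitted curve."""
        check_is_fitted(self, "lower_")
        x = _column(X)
        if self.degenerate_:
            return np.zeros_like(x)
        f = logistic(x, self.alpha_, self.beta_)
        return (self.upper_ - self.lower_) * self.beta_ * f * (1.0 - f)

    def to_record(self, key: dict | None = None) -> PsychometricFit:
        check_is_fitted(self, "lower_")
        return PsychometricFit(
            lower=self.lower_, upper=self.upper_, alpha=self.alpha_,
            beta=self.beta_, x_threshold=self.x_threshold_,
            y_threshold=self.y_threshold_, slope=self.slope_, sse=self.sse_,
            converged=self.converged_, degenerate=self.degenerate_,
            n_points=self.n_points_, key=dict(key or {}))


def fit_anchored_logistic(curve: ResponseCurve, **estimator_kwargs) -> PsychometricFit:
    """Fit one response curve; degenerate (flat) curves return a flagged
    zero-slope fit rather than raising."""
    ok = curve.defined()
    est = AnchoredLogistic(**estimator_kwargs).fit(curve.x[ok], curve.p[ok])
    return est.to_record(key=curve.key)


def steepest_point(fit: PsychometricFit):
    """(x-threshold, y-threshold, slope) of the curve's steepest point."""
    if fit.degenerate:
        return (np.nan, fit.lower, 0.0)
    return (fit.alpha, 0.5 * (fit.lower + fit.upper),
            (fit.upper - fit.lower) * fit.beta / 4.0)


def evaluate(fit: PsychometricFit, x) -> np.ndarray:
    """Predicted proportions of the fitted curve at ``x``."""
    x = np.asarray(x, dtype=float)
    if fit.degenerate:
        return np.full(x.shape, fit.lower)
    return fit.lower + (fit.upper - fit.lower) * logistic(x, fit.alpha, fit.beta)


def fit_curves(curves: list[ResponseCurve], **estimator_kwargs) -> list[PsychometricFit]:
    return [fit_anchored_logistic(c, **estimator_kwargs) for c in curves]


def fits_to_frame(fits: list[PsychometricFit]) -> pd.DataFrame:
    """Tidy table: one row per fitted curve."""
    rows = []
    for f in fits:
        rows.append({**f.key, "lower": f.lower, "upper": f.upper,
                     "alpha": f.alpha, "beta": f.beta,
                     "x_threshold": f.x_threshold, "y_threshold": f.y_threshold,
                     "slope": f.slope, "sse": f.sse, "converged": f.converged,
                     "degenerate": f.degenerate})
    return pd.DataFrame(rows)


def grid_search_sse(x, p, alpha_grid=None, beta_grid=None,
                    beta_chunk: int = 64):
    """Brute-force (alpha, beta) search for the anchored model.

    An independent oracle for the least-squares fit: exhaustively evaluates
    the anchored-logistic SSE over a dense parameter grid and returns
    ``(best_sse, best_alpha, best_beta)``.  Uses the factorization
    exp(-b(x - a)) = exp(b a) exp(-b x) so each beta row costs one small
    exp per grid axis instead of one per (alpha, x) pair.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(x) & np.isfinite(p)
    x, p = x[ok], p[ok]
    L, U = p.min(), p.max()
    span = U - L
    if alpha_grid is None:
        alpha_grid = np.arange(-0.5, 1.5 + 1e-12, 0.001)
    if beta_grid is None:
        beta_grid = np.arange(0.0, 50.0 + 1e-12, 0.01)
    alpha_grid = np.asarray(alpha_grid, float)
    beta_grid = np.asarray(beta_grid, float)
    r = p - L
    best_sse, best_a, best_b = np.inf, np.nan, np.nan
    for start in range(0, beta_grid.size, beta_chunk):
        b = beta_grid[start:start + beta_chunk][:, None, None]     # (B,1,1)
        with np.errstate(over="ignore"):
            ebx = np.exp(-b * x[None, None, :])                    # (B,1,X)
            eba = np.exp(b * alpha_grid[None, :, None])            # (B,A,1)
            F = 1.0 / (1.0 + eba * ebx)                            # (B,A,X)
        sse = np.sum((r[None, None, :] - span * F) ** 2, axis=-1)  # (B,A)
        i = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[i] < best_sse:
            best_sse = float(sse[i])
            best_b = float(beta_grid[start + i[0]])
            best_a = float(alpha_grid[i[1]])
    return best_sse, best_a, best_b
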