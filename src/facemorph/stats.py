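"""Inferential toolkit: dual-criterion paired tests, fully-within
repeated-measures ANOVA with Greenhouse-Geisser correction and partial eta
squared, t-based confidence intervals, and compact letter displays.

The dual-criterion convention: a pairwise comparison counts as significant
only when BOTH the paired t-test and the Wilcoxon signed-rank test fall
below alpha, combining parametric sensitivity with a distribution-free
safeguard.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DualTestResult:
    label: str
    p_t: float
    p_w: float
    significant: bool
    n: int
    alpha: float


def dual_paired_test(a, b, alpha: float = 0.05, label: str = "") -> DualTestResult:
    """Paired t-test AND Wilcoxon signed-rank; significant only if both
    two-sided p-values fall below ``alpha``.

    The Wilcoxon null distribution is exact for n <= 25 pairs and a normal
    approximation with continuity correction above.  All-zero differences
    leave the signed-rank test undefined and the decision non-significant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 5:
        raise ValueError(f"need at least 5 pairs, got {n}")
    d = a - b
    if np.all(d == 0.0):
        return DualTestResult(label, np.nan, np.nan, False, n, alpha)
    p_t = float(sps.ttest_rel(a, b).pvalue)
    method = "exact" if n <= 25 else "approx"
    try:
        if method == "exact":
            p_w = float(sps.wilcoxon(d, method="exact").pvalue)
        else:
            p_w = float(sps.wilcoxon(d, method="approx", correction=True).pvalue)
    except ValueError:
        p_w = float(sps.wilcoxon(d, method="approx", correction=True).pvalue)
    sig = bool(np.isfinite(p_t) and np.isfinite(p_w) and p_t < alpha and p_w < alpha)
    return DualTestResult(label, p_t, p_w, sig, n, alpha)


def mean_ci(sample, level: float = 0.95):
    """Mean with a symmetric t-distribution confidence interval.

    Returns ``(mean, lower, upper)``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size))
    half = float(sps.t.ppf(0.5 + level / 2.0, x.size - 1) * se)
    return m, m - half, m + half


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the space orthogonal to the constant."""
    A = np.eye(k) - 1.0 / k
    u, s, vt = np.linalg.svd(A)
    return vt[: k - 1]


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Fully-within-subjects ANOVA for one or more crossed within factors.

    Each effect (main effect or interaction) is tested against its own
    effect-by-subject error term.  For effects with more than one numerator
    degree of freedom the Greenhouse-Geisser epsilon is estimated from the
    contrast covariance and corrected degrees of freedom / p-values are
    reported alongside the uncorrected ones.  Partial eta squared is
    ``SS_effect / (SS_effect + SS_error)``.

    Requires a complete, balanced design: every subject must contribute the
    same number of observations to every factor-level cell (multiple
    observations per cell are averaged first).
    """
    if isinstance(within, str):
        within = [within]
    within = list(within)
    counts = data.groupby([subject] + within, observed=True)[dv].count()
    levels = [np.sort(data[w].unique()) for w in within]
    n_cells = int(np.prod([len(l) for l in levels]))
    n_subj = data[subject].nunique()
    if len(counts) != n_cells * n_subj or counts.nunique() != 1:
        raise ValueError("design must be complete and balanced "
                         "(equal observations in every subject x cell)")
    cells = data.groupby([subject] + within, observed=True)[dv].mean()
    # subject x cell matrix with cells ordered by itertools.product(levels)
    wide = cells.unstack(within)
    order = list(itertools.product(*levels))
    if len(within) == 1:
        order = [o[0] for o in order]
    M = wide[order].to_numpy(dtype=float)

    Q = {w: _orthonormal_contrasts(len(l)) for w, l in zip(within, levels)}
    u = {w: np.full((1, len(l)), 1.0 / np.sqrt(len(l)))
         for w, l in zip(within, levels)}

    rows = []
    effects = [combo for r in range(1, len(within) + 1)
               for combo in itertools.combinations(within, r)]
    for combo in effects:
        C = np.ones((1, 1))
        for w in within:
            C = np.kron(C, Q[w] if w in combo else u[w])
        D = M @ C.T                              # subjects x df_effect
        df1 = D.shape[1]
        dbar = D.mean(axis=0)
        ss_eff = n_subj * float(np.sum(dbar ** 2))
        resid = D - dbar
        ss_err = float(np.sum(resid ** 2))
        df2 = df1 * (n_subj - 1)
        # numerically-zero sums of squares (constant data) are true zeros
        tol = 1e-12 * max(1.0, float(np.sum((M - M.mean()) ** 2)))
        if ss_eff < tol:
            ss_eff = 0.0
        if ss_err < tol:
            ss_err = 0.0
        if ss_err == 0.0:
            F = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
        np2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        if df1 > 1:
            S = np.cov(D, rowvar=False)
            tr = np.trace(S)
            denom = df1 * float(np.sum(S * S))
            eps = float(tr ** 2 / denom) if denom > 0 else 1.0
            eps = min(1.0, max(eps, 1.0 / df1))
            corrected = True
        else:
            eps, corrected = 1.0, False
        df1_c, df2_c = eps * df1, eps * df2
        p_c = float(sps.f.sf(F, df1_c, df2_c)) if np.isfinite(F) else p
        rows.append({"effect": ":".join(combo), "F": F,
                     "df1": df1, "df2": df2, "p": p,
                     "np2": np2, "gg_eps": eps,
                     "df1_gg": df1_c, "df2_gg": df2_c, "p_gg": p_c,
                     "corrected": corrected})
    return pd.DataFrame(rows)


def letter_display(values: pd.DataFrame, group: str, value: str,
                   subject: str, alpha: float = 0.05) -> dict:
    """Compact letter display from all-pairs dual-criterion tests.

    Groups sharing a letter do not differ significantly.  Letters are the
    maximal cliques of the non-significance graph, labelled in order of
    decreasing group mean.
    """
    wide = values.pivot(index=subject, columns=group, values=value)
    groups = sorted(wide.columns, key=lambda g: -wide[g].mean())
    differs = {}
    for g1, g2 in itertools.combinations(groups, 2):
        pair = wide[[g1, g2]].dropna()
        res = dual_paired_test(pair[g1], pair[g2], alpha=alpha)
        differs[frozenset((g1, g2))] = res.significant
    # maximal cliques of the "not significantly different" graph (tiny n)
    cliques = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            if any(set(combo) <= c for c in cliques):
                continue
            if all(not differs[frozenset(pr)]
                   for pr in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, c in enumerate(cliques):
        for g in c:
            letters[g] += chr(ord("a") + i)
    return {g: "".join(sorted(l)) for g, l in letters.items()}
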