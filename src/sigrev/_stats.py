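"""Shared statistical machinery: moderated linear models and p-value adjustment.

The moderated fit implements the empirical-Bayes variance squeeze used by
gene-wise linear modeling: per-row OLS residual variances s2_g with d_g
degrees of freedom are shrunk toward a common prior value s0^2 with d0 prior
degrees of freedom, where (d0, s0^2) are estimated by the method of moments
on log variances (a scaled-F fit).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "ModeratedFit",
    "adjust_pvalues",
    "build_design",
    "fit_moderated_lm",
    "squeeze_variances",
    "trigamma_inverse",
]


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment; ``method`` is 'bh' or 'bonferroni'."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method != "bh":
        raise ValueError(f"unknown adjustment method: {method!r}")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def trigamma_inverse(y: float, max_iter: int = 75) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-row variances toward a moment-matched prior.

    Fits s2 ~ s0^2 * F(df, d0) by matching the mean and variance of log(s2),
    then returns posterior variances (d0*s0^2 + df*s2)/(d0 + df) together with
    the estimated (d0, s0^2).  d0 = inf means complete shrinkage to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # Degenerate input: nothing to pool, return untouched.
        return s2.copy(), 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    emean = z.mean()
    evar = z.var(ddof=1)
    resid_var = evar - special.polygamma(1, df / 2.0)
    if resid_var > 0:
        d0 = 2.0 * trigamma_inverse(resid_var)
        log_s0 = (
            emean
            - special.polygamma(0, df / 2.0)
            + np.log(df / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        log_s0 = emean - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    s0_sq = float(np.exp(log_s0))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, float(d0), s0_sq


def build_design(
    condition: np.ndarray, database: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Intercept + condition indicator + database dummies (first level reference).

    Raises ``ValueError`` listing confounded columns if the design is
    rank-deficient (e.g., database perfectly aligned with condition).
    """
    condition = np.asarray(condition)
    database = np.asarray(database)
    n = condition.size
    cols = [np.ones(n), condition.astype(float)]
    names = ["intercept", "condition"]
    levels = [lv for lv in pd_unique(database)][1:]
    for lv in levels:
        cols.append((database == lv).astype(float))
        names.append(f"database[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _confounded_columns(X, names)
        raise ValueError(f"rank-deficient design; confounded columns: {bad}")
    return X, names


def pd_unique(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


def _confounded_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad


@dataclass
class ModeratedFit:
    """Row-wise moderated linear-model fit for one coefficient of interest."""

    coef: np.ndarray          # effect estimate per row
    se: np.ndarray            # moderated standard error per row
    t: np.ndarray             # moderated t statistic
    p: np.ndarray             # two-sided p-value, d0 + d_g df
    df_residual: float
    df_prior: float
    s2_prior: float
    s2_post: np.ndarray


def fit_moderated_lm(
    Y: np.ndarray,
    X: np.ndarray,
    coef_index: int = 1,
    moderate: bool = True,
) -> ModeratedFit:
    """Fit Y[g, :] ~ X row-wise by OLS with empirical-Bayes variance moderation.

    ``moderate=False`` gives the ordinary t-test (d0 = 0 identity).
    """
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError("Y columns must match design rows")
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T                       # rows x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df
    if moderate:
        s2_post, d0, s0 = squeeze_variances(s2, df)
    else:
        s2_post, d0, s0 = s2.copy(), 0.0, float("nan")
    unscaled = np.sqrt(XtX_inv[coef_index, coef_index])
    coef = beta[:, coef_index]
    se = np.sqrt(s2_post) * unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    df_total = df + d0
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    # Rows with zero residual variance and zero effect are exact nulls.
    pvals = np.where((se == 0) & (coef == 0), 1.0, pvals)
    return ModeratedFit(
        coef=coef, se=se, t=t, p=pvals,
        df_residual=float(df), df_prior=float(d0), s2_prior=s0, s2_post=s2_post,
    )
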