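"""Differential-expression signature construction.

Two routes build a disease-associated gene signature from a tumor/control
count matrix with a source-database covariate:

* ``moderated_lm_de`` — gene-wise linear models on log2(TPM + 1) with
  empirical-Bayes variance moderation and Bonferroni adjustment.
* ``nb_glm_de`` — per-gene negative-binomial GLMs on raw counts (log link,
  median-of-ratios size factors as offsets), method-of-moments dispersions
  shrunk halfway in log space toward a mean-dispersion trend, Wald tests with
  BH adjustment, and a ridge (zero-centered normal prior) shrunken log2 fold
  change for ranking.

``build_de_signature`` then walks the |log2FC| ranking of significant genes,
keeping only genes present in the perturbation-assay universe, until the
target signature size (90-120 genes by default) is reached.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import adjust_pvalues, build_design, fit_moderated_lm

__all__ = [
    "ExpressionStudy",
    "DifferentialResult",
    "GeneSignature",
    "tpm_log",
    "moderated_lm_de",
    "nb_glm_de",
    "build_de_signature",
]

LN2 = float(np.log(2.0))


@dataclass
class ExpressionStudy:
    """Gene x sample counts with per-sample condition/database labels.

    ``condition`` is binary (1 = tumor, 0 = control); ``database`` is the
    source-compendium label included as a batch covariate; ``gene_lengths``
    are in kilobases.
    """

    counts: pd.DataFrame               # genes x samples, non-negative integers
    gene_lengths: pd.Series            # kb, indexed like counts
    condition: pd.Series               # per sample, values {0, 1}
    database: pd.Series                # per sample, categorical

    def __post_init__(self) -> None:
        n = self.counts.shape[1]
        if not (len(self.condition) == len(self.database) == n):
            raise ValueError("sample metadata length must match count columns")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class DifferentialResult:
    """Per-gene differential-expression statistics for one route."""

    table: pd.DataFrame    # columns: log2fc, se, stat, p, p_adj (index = gene)
    method: str            # 'moderated_lm' | 'nb_glm'
    adjust: str            # 'bonferroni' | 'bh'

    def __post_init__(self) -> None:
        needed = {"log2fc", "se", "stat", "p", "p_adj"}
        if not needed <= set(self.table.columns):
            raise ValueError(f"result table must have columns {sorted(needed)}")


@dataclass
class GeneSignature:
    """Disjoint ordered up/down gene lists plus the eligibility universe."""

    up: list[str]
    down: list[str]
    method: str
    universe: set = field(default_factory=set)
    warning: str | None = None

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)


def tpm_log(study: ExpressionStudy) -> pd.DataFrame:
    """log2(TPM + 1) matrix; each TPM column sums to 1e6 before the log."""
    counts = study.counts.to_numpy(dtype=float)
    lengths = study.gene_lengths.reindex(study.counts.index).to_numpy(dtype=float)
    rate = counts / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        bad = list(study.counts.columns[zero])
        raise ValueError(f"all-zero sample column(s): {bad}")
    tpm = rate / colsum[None, :] * 1e6
    return pd.DataFrame(
        np.log2(tpm + 1.0), index=study.counts.index, columns=study.counts.columns
    )


def moderated_lm_de(
    logexpr: pd.DataFrame,
    condition: pd.Series,
    database: pd.Series,
) -> DifferentialResult:
    """Moderated linear-model DE on log expression, Bonferroni-adjusted."""
    cond = np.asarray(condition)
    if min((cond == 1).sum(), (cond == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per condition")
    X, _ = build_design(cond, np.asarray(database))
    fit = fit_moderated_lm(logexpr.to_numpy(dtype=float), X, coef_index=1)
    table = pd.DataFrame(
        {
            "log2fc": fit.coef,
            "se": fit.se,
            "stat": fit.t,
            "p": fit.p,
            "p_adj": adjust_pvalues(fit.p, "bonferroni"),
        },
        index=logexpr.index,
    )
    return DifferentialResult(table=table, method="moderated_lm", adjust="bonferroni")


# ---------------------------------------------------------------------------
# negative-binomial GLM route
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Genes whose geometric mean is zero (any zero count) are excluded from the
    median, as in the standard median-of-ratios estimator.
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    log_geo = logc.mean(axis=1)
    ok = np.isfinite(log_geo)
    if not ok.any():
        raise ValueError("no gene with all-positive counts; cannot form reference")
    ratios = logc[ok] - log_geo[ok, None]
    return np.exp(np.median(ratios, axis=0))


def _moment_dispersions(
    counts: np.ndarray, sf: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Method-of-moments dispersion per gene from within-cell variability."""
    y = counts / sf[None, :]
    g, n = y.shape
    mean_all = y.mean(axis=1)
    ss = np.zeros(g)
    dof = 0
    for lab in np.unique(groups):
        sel = groups == lab
        k = sel.sum()
        if k < 2:
            continue
        sub = y[:, sel]
        ss += sub.var(axis=1, ddof=1) * (k - 1)
        dof += k - 1
    if dof == 0:
        raise ValueError("no replication within design cells")
    var_within = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - mean_all) / mean_all**2
    alpha = np.where(np.isfinite(alpha), alpha, 1e-8)
    return np.clip(alpha, 1e-8, 10.0)


def _dispersion_trend(alpha: np.ndarray, mean_norm: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mean by least squares (two trimming rounds)."""
    use = (mean_norm > 0) & (alpha > 1e-7)
    if use.sum() < 10:
        return np.full_like(alpha, max(float(np.median(alpha)), 1e-8))
    x = 1.0 / mean_norm[use]
    y = alpha[use]
    for _ in range(2):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = A @ coef
        keep = np.abs(y - pred) <= 3.0 * np.std(y - pred) + 1e-12
        if keep.all():
            break
        x, y = x[keep], y[keep]
    a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean_norm, 1e-8)
    return np.clip(trend, 1e-8, 10.0)


def _nb_irls(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    ridge_idx: int | None = None,
    ridge_prec: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for per-gene NB GLMs sharing one design.

    Returns (beta [genes x p], cov diag of the condition coefficient is taken
    by the caller from the full inverse, converged flags).  ``ridge_idx`` adds
    a Gaussian-prior precision on one coefficient (shrunken-LFC refit).
    """
    G, n = counts.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # init: intercept from mean of offset-adjusted counts
    mu0 = np.maximum(counts.mean(axis=1), 0.1)
    beta[:, 0] = np.log(mu0) - offset.mean()
    penalty = np.zeros(p)
    if ridge_idx is not None:
        penalty[ridge_idx] = ridge_prec
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    XT = X.T
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = beta[idx] @ XT + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[idx, None] * mu)
        z = eta - offset[None, :] + (counts[idx] - mu) / mu
        # normal equations per gene: (X^T W X + diag(penalty)) delta = X^T W z
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWX += np.diag(penalty)[None, :, :]
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(new - beta[idx]).max(axis=1)
        beta[idx] = new
        done = step < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # covariance at the final fit
    eta = np.clip(beta @ XT + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X) + np.diag(penalty)[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def _fit_prior_scale(beta: np.ndarray, se: np.ndarray) -> float:
    """Marginal-ML scale of a zero-centered normal prior on the coefficient."""
    ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    b, s = beta[ok], se[ok]

    def nll(log_tau2: float) -> float:
        v = np.exp(log_tau2) + s**2
        return float(0.5 * (np.log(v) + b**2 / v).sum())

    res = optimize.minimize_scalar(nll, bounds=(-12.0, 8.0), method="bounded")
    return float(np.exp(res.x))


def nb_glm_de(study: ExpressionStudy) -> DifferentialResult:
    """Negative-binomial GLM DE with shrunken log2 fold changes (BH-adjusted)."""
    counts_df = study.counts
    counts = counts_df.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        flo = counts_df.to_numpy(dtype=float)
        if not np.allclose(flo, np.round(flo)):
            raise ValueError("nb_glm_de requires integer counts")
        counts = np.round(flo).astype(np.int64)
    cond = np.asarray(study.condition)
    if min((cond == 1).sum(), (cond == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per condition")
    db = np.asarray(study.database)
    X, _ = build_design(cond, db)
    sf = size_factors(counts)
    offset = np.log(sf)
    counts_f = counts.astype(float)
    cells = np.array([f"{c}|{d}" for c, d in zip(cond, db)])
    alpha_mom = _moment_dispersions(counts_f, sf, cells)
    mean_norm = (counts_f / sf[None, :]).mean(axis=1)
    trend = _dispersion_trend(alpha_mom, mean_norm)
    # halfway shrink in log space toward the trend
    alpha = np.exp(0.5 * np.log(alpha_mom) + 0.5 * np.log(trend))

    beta, cov, converged = _nb_irls(counts_f, X, offset, alpha)
    b_cond = beta[:, 1]
    se_cond = np.sqrt(cov[:, 1, 1])
    wald = b_cond / se_cond
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(converged, p, np.nan)
    if (~converged).any():
        warnings.warn(
            f"{(~converged).sum()} gene(s) failed IRLS convergence; p set to NA",
            RuntimeWarning,
        )

    # ridge-shrunken LFC: refit the condition coefficient under a zero-centered
    # normal prior whose scale is fit by marginal maximum likelihood
    tau2 = _fit_prior_scale(b_cond[converged], se_cond[converged])
    beta_s, _, _ = _nb_irls(
        counts_f, X, offset, alpha, ridge_idx=1, ridge_prec=1.0 / tau2
    )
    log2fc = beta_s[:, 1] / LN2

    p_adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    p_adj[ok] = adjust_pvalues(p[ok], "bh")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se_cond / LN2,
            "stat": wald,
            "p": p,
            "p_adj": p_adj,
        },
        index=counts_df.index,
    )
    return DifferentialResult(table=table, method="nb_glm", adjust="bh")


def build_de_signature(
    de: DifferentialResult,
    universe: set,
    n_min: int = 90,
    n_max: int = 120,
    n_target: int = 100,
    alpha: float = 0.05,
) -> GeneSignature:
    """Top-|log2FC| signature from significant genes restricted to a universe.

    Significant genes (p_adj < alpha) are ranked by |log2fc| descending (ties
    broken by gene id); the ranking is walked skipping genes outside the
    universe until n_target in [n_min, n_max] genes are collected.  If fewer
    eligible genes exist than n_min the signature carries a warning flag.
    """
    if len(de.table) == 0 or not universe:
        raise ValueError("empty differential result or universe")
    if not (n_min <= n_target <= n_max):
        raise ValueError("n_target must lie in [n_min, n_max]")
    tab = de.table.dropna(subset=["p_adj"])
    sig = tab[tab["p_adj"] < alpha]
    ranked = sig.reindex(
        sorted(sig.index, key=lambda g: (-abs(sig.at[g, "log2fc"]), g))
    )
    up: list[str] = []
    down: list[str] = []
    for gene, row in ranked.iterrows():
        if gene not in universe:
            continue
        if row["log2fc"] > 0:
            up.append(gene)
        elif row["log2fc"] < 0:
            down.append(gene)
        else:
            continue
        if len(up) + len(down) >= n_target:
            break
    warning = None
    if len(up) + len(down) < n_min:
        warning = (
            f"only {len(up) + len(down)} significant in-universe genes "
            f"(requested >= {n_min})"
        )
    return GeneSignature(
        up=up, down=down, method=de.method, universe=set(universe), warning=warning
    )
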