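"""Transfer-learning signature route.

Latent loadings learned on a large expression compendium are transferred to a
new tumor/control study by projecting row-standardized log expression onto
them.  Latent variables (LVs) are then tested for condition association with
the same moderated linear model used for gene-level DE; the most extreme LVs
are kept with a 3-standard-deviation absolute-effect rule on top of a
Bonferroni threshold, and the signature is assembled from the top-weighted
genes of the significant LVs (signed by the NB-GLM fold changes).

``label_switch_validation`` re-runs the projection after shuffling a growing
fraction of gene labels; a negative regression slope of significant-LV count
on switch fraction demonstrates that the gene labels carry the transferred
information.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import adjust_pvalues, build_design, fit_moderated_lm
from .diffexp import DifferentialResult, ExpressionStudy, GeneSignature, tpm_log

__all__ = [
    "LatentActivity",
    "LatentDifferential",
    "project_latent",
    "differential_lv",
    "three_sd_cutoff",
    "top_weighted_genes",
    "build_tl_signature",
    "label_switch_validation",
]

logger = logging.getLogger(__name__)


@dataclass
class LatentActivity:
    """LV x sample activity with the sample metadata used for testing."""

    B: pd.DataFrame              # lv x sample
    condition: pd.Series
    database: pd.Series
    n_genes_used: int = 0
    n_genes_dropped: int = 0


@dataclass
class LatentDifferential:
    """Per-LV condition effect with Bonferroni p and the 3-SD significance rule."""

    table: pd.DataFrame          # columns: effect, p, p_adj, significant
    cutoff: float                # applied absolute-effect threshold

    @property
    def significant_lvs(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def standardize_rows(Y: np.ndarray) -> np.ndarray:
    """Z-score each row across samples; constant rows become all-zero."""
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (Y - mu) / sd


def project_latent(
    logexpr: pd.DataFrame,
    Z: pd.DataFrame,
    condition: pd.Series,
    database: pd.Series,
    ridge: float = 1e-6,
) -> LatentActivity:
    """Project row-standardized expression onto loadings.

    B = (Z'Z + ridge I)^-1 Z' Y_std, genes aligned by id; genes of the study
    absent from the loading matrix (and vice versa) are dropped with a logged
    count.  ``ridge`` is numerical regularization only; 0 recovers the plain
    pseudo-inverse projection.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    shared = logexpr.index.intersection(Z.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between expression and loadings")
    dropped = (len(logexpr.index) - len(shared)) + (len(Z.index) - len(shared))
    if dropped:
        logger.info("project_latent: dropped %d unshared gene rows", dropped)
    Y = standardize_rows(logexpr.loc[shared].to_numpy(dtype=float))
    Zm = Z.loc[shared].to_numpy(dtype=float)
    G = Zm.T @ Zm + ridge * np.eye(Zm.shape[1])
    B = np.linalg.solve(G, Zm.T @ Y)
    return LatentActivity(
        B=pd.DataFrame(B, index=Z.columns, columns=logexpr.columns),
        condition=condition,
        database=database,
        n_genes_used=len(shared),
        n_genes_dropped=dropped,
    )


def three_sd_cutoff(effects: np.ndarray) -> float:
    """Absolute effect threshold: mean +/- 3 SD bounds averaged in magnitude.

    upper = mean + 3 sd, lower = mean - 3 sd; the applied cutoff is
    (|upper| + |lower|) / 2 rounded to 2 decimals (e.g. bounds 0.27 / -0.23
    give 0.25).
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size < 2:
        raise ValueError("need >= 2 effects for the 3-SD rule")
    m = effects.mean()
    s = effects.std(ddof=1)
    upper = m + 3.0 * s
    lower = m - 3.0 * s
    return float(round((abs(upper) + abs(lower)) / 2.0, 2))


def differential_lv(
    act: LatentActivity,
    alpha: float = 0.05,
    effect_cutoff: float | None = None,
) -> LatentDifferential:
    """Moderated LV-wise regression of activity on condition + database.

    Bonferroni-adjusted p-values; an LV is significant when p_adj < alpha AND
    |effect| >= cutoff, where the cutoff defaults to the 3-SD rule over all LV
    effects (pass ``effect_cutoff`` to pin it, as the label-switch validation
    does with 0.05).
    """
    cond = np.asarray(act.condition)
    if min((cond == 1).sum(), (cond == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per condition")
    X, _ = build_design(cond, np.asarray(act.database))
    fit = fit_moderated_lm(act.B.to_numpy(dtype=float), X, coef_index=1)
    p_adj = adjust_pvalues(fit.p, "bonferroni")
    cutoff = (
        three_sd_cutoff(fit.coef) if effect_cutoff is None else float(effect_cutoff)
    )
    significant = (p_adj < alpha) & (np.abs(fit.coef) >= cutoff)
    table = pd.DataFrame(
        {
            "effect": fit.coef,
            "se": fit.se,
            "p": fit.p,
            "p_adj": p_adj,
            "significant": significant,
        },
        index=act.B.index,
    )
    return LatentDifferential(table=table, cutoff=cutoff)


def top_weighted_genes(Z: pd.DataFrame, lv: str, k: int = 10) -> list[str]:
    """The k highest-weight genes of one LV column, ties by gene id."""
    if lv not in Z.columns:
        raise KeyError(f"unknown latent variable: {lv}")
    col = Z[lv]
    nz = col[col > 0]
    if k > len(nz):
        logger.warning(
            "top_weighted_genes: requested %d but only %d nonzero weights in %s",
            k, len(nz), lv,
        )
        k = len(nz)
    ranked = sorted(nz.index, key=lambda g: (-nz[g], g))
    return ranked[:k]


def build_tl_signature(
    ld: LatentDifferential,
    Z: pd.DataFrame,
    de: DifferentialResult,
    universe: set,
    n_target: int = 100,
) -> GeneSignature:
    """Round-robin top-weighted-gene signature over significant LVs.

    Significant LVs are ordered by |effect| descending; each in turn
    contributes its next-highest-weight gene that is in the universe, has a
    nonzero fold change in ``de`` (which supplies the up/down sign), and was
    not already taken, until ``n_target`` genes are collected.
    """
    sig_lvs = sorted(
        ld.significant_lvs,
        key=lambda lv: (-abs(ld.table.at[lv, "effect"]), lv),
    )
    if not sig_lvs:
        return GeneSignature(
            up=[], down=[], method="transfer_learning", universe=set(universe),
            warning="no significant latent variable",
        )
    queues = {
        lv: iter(top_weighted_genes(Z, lv, k=int((Z[lv] > 0).sum())))
        for lv in sig_lvs
    }
    lfc = de.table["log2fc"]
    chosen: dict[str, float] = {}
    exhausted: set = set()
    while len(chosen) < n_target and len(exhausted) < len(sig_lvs):
        for lv in sig_lvs:
            if lv in exhausted or len(chosen) >= n_target:
                continue
            for gene in queues[lv]:
                if gene in chosen or gene not in universe:
                    continue
                fc = lfc.get(gene, np.nan)
                if not np.isfinite(fc) or fc == 0:
                    continue
                chosen[gene] = float(fc)
                break
            else:
                exhausted.add(lv)
    up = [g for g, fc in chosen.items() if fc > 0]
    down = [g for g, fc in chosen.items() if fc < 0]
    warning = None
    if len(chosen) < n_target:
        warning = f"only {len(chosen)} eligible genes (requested {n_target})"
    return GeneSignature(
        up=up, down=down, method="transfer_learning",
        universe=set(universe), warning=warning,
    )


def label_switch_validation(
    study: ExpressionStudy,
    Z: pd.DataFrame,
    fractions: np.ndarray | None = None,
    reps: int = 50,
    seed: int = 0,
    ridge: float = 1e-6,
    alpha: float = 0.05,
    effect_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Gene-label-switch validation of the transfer-learning projection.

    For each fraction f, ``reps`` times: a random ceil(f * G) subset of gene
    labels is shuffled among itself, the study is re-projected and re-tested
    (adj p < alpha and |effect| >= effect_cutoff), and the significant-LV
    count recorded.  Returns the per-fraction curve (fraction 0 is the
    unpermuted baseline) with the OLS slope/R^2/p of mean count on fraction
    stored in ``DataFrame.attrs['regression']``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if fractions is None:
        fractions = np.arange(0.1, 1.01, 0.1)
    rng = np.random.default_rng(seed)
    logexpr = tpm_log(study)
    shared = logexpr.index.intersection(Z.index)
    Y = standardize_rows(logexpr.loc[shared].to_numpy(dtype=float))
    Zm = Z.loc[shared].to_numpy(dtype=float)
    G = Zm.T @ Zm + ridge * np.eye(Zm.shape[1])
    proj = np.linalg.solve(G, Zm.T)          # precomputed projector

    cond = np.asarray(study.condition)
    X, _ = build_design(cond, np.asarray(study.database))

    def count_significant(Yperm: np.ndarray) -> int:
        B = proj @ Yperm
        fit = fit_moderated_lm(B, X, coef_index=1)
        p_adj = adjust_pvalues(fit.p, "bonferroni")
        return int(((p_adj < alpha) & (np.abs(fit.coef) >= effect_cutoff)).sum())

    n_genes = Y.shape[0]
    baseline = count_significant(Y)
    rows = [{"fraction": 0.0, "mean_significant": float(baseline), "sd": 0.0}]
    for f in fractions:
        k = int(np.ceil(f * n_genes))
        counts = []
        for _ in range(reps):
            sub = rng.choice(n_genes, size=k, replace=False)
            perm = rng.permutation(k)
            Yp = Y.copy()
            Yp[sub] = Y[sub[perm]]
            counts.append(count_significant(Yp))
        rows.append(
            {
                "fraction": float(f),
                "mean_significant": float(np.mean(counts)),
                "sd": float(np.std(counts, ddof=1)),
            }
        )
    curve = pd.DataFrame(rows)
    reg = stats.linregress(curve["fraction"], curve["mean_significant"])
    curve.attrs["regression"] = {
        "slope": float(reg.slope),
        "r_squared": float(reg.rvalue**2),
        "p": float(reg.pvalue),
    }
    return curve
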