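"""Orthogonal validation of candidate drug sets.

Candidates produced by signature reversion are checked against evidence the
reversion never saw: clinical-trial membership (permutation enrichment over
same-size random draws of FDA-approved drugs), pooled viability-screen
sensitivity (median log2 fold change < 0.3 means a cell line is sensitive),
hypergeometric drug-set enrichment of shared targets, and CRISPR gene-effect
summaries for target genes (negative means fitness cost on knockout).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import adjust_pvalues

__all__ = [
    "DrugAnnotations",
    "ViabilityTable",
    "EnrichmentVerdict",
    "sensitivity_call",
    "trial_enrichment",
    "prism_enrichment",
    "target_dsea",
    "gene_effect_summary",
]


@dataclass
class DrugAnnotations:
    """Per-drug FDA status, trial membership, targets, MOA, fingerprint."""

    drug_ids: list[str]
    fda_approved: dict = field(default_factory=dict)     # drug -> bool
    in_trial: dict = field(default_factory=dict)         # drug -> {disease: bool}
    targets: dict = field(default_factory=dict)          # drug -> set of genes
    moa: dict = field(default_factory=dict)              # drug -> label
    fingerprints: dict = field(default_factory=dict)     # drug -> bool array

    def __post_init__(self) -> None:
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("drug ids must be unique")
        lens = {len(v) for v in self.fingerprints.values()}
        if len(lens) > 1:
            raise ValueError("fingerprints must share one length")

    @property
    def fda_universe(self) -> list[str]:
        return [d for d in self.drug_ids if self.fda_approved.get(d, False)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.drug_ids:
            trial = self.in_trial.get(d, {})
            rows.append(
                {
                    "drug_id": d,
                    "fda_approved": self.fda_approved.get(d, False),
                    "in_trial": ";".join(k for k, v in sorted(trial.items()) if v),
                    "targets": ";".join(sorted(self.targets.get(d, ()))),
                    "moa": self.moa.get(d, ""),
                }
            )
        return pd.DataFrame(rows).set_index("drug_id")


@dataclass
class ViabilityTable:
    """Drug x cell-line median log2 viability fold change (NaN = not assayed)."""

    values: pd.DataFrame
    disease_of_line: dict = field(default_factory=dict)  # cell line -> disease

    def lines_for(self, disease: str) -> list[str]:
        return [
            ln for ln in self.values.columns
            if self.disease_of_line.get(ln) == disease
        ]


@dataclass
class EnrichmentVerdict:
    """Observed enrichment fraction against a permutation null."""

    observed: float
    null_fractions: np.ndarray
    p_empirical: float
    p_wilcoxon: float
    n_perm: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.observed <= 1.0:
            raise ValueError("observed fraction must lie in [0, 1]")


def sensitivity_call(
    v: ViabilityTable, threshold: float = 0.3
) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean sensitivity matrix (value < threshold, strict) and per-drug
    sensitive fraction over evaluated (non-missing) lines."""
    if v.values.size == 0:
        raise ValueError("empty viability table")
    vals = v.values
    sens = (vals < threshold).astype("boolean")   # NaN compares False...
    sens = sens.where(vals.notna())               # ...then becomes NA (excluded)
    frac = sens.astype("Float64").mean(axis=1, skipna=True).astype(float)
    return sens, frac.rename("sensitive_fraction")


def _permutation_verdict(
    indicator: pd.Series,
    candidates: list[str],
    universe: list[str],
    n_perm: int,
    seed: int,
) -> EnrichmentVerdict:
    """Shared permutation machinery for trial/PRISM enrichment.

    ``indicator`` is the per-drug 0/1 outcome over the universe; null sets are
    same-size draws without replacement from the universe.  The rank-sum
    variant compares the candidate indicators against the pooled indicators of
    all random draws (one-tailed, candidates greater).
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    missing = set(candidates) - set(universe)
    if missing:
        raise ValueError(f"candidates outside the annotated universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    ind = indicator.loc[universe].to_numpy(dtype=float)
    pos = {d: i for i, d in enumerate(universe)}
    cand_idx = np.array([pos[d] for d in candidates])
    observed = float(ind[cand_idx].mean())
    k = len(candidates)
    nulls = np.empty(n_perm)
    pooled = np.empty(n_perm * k)
    for j in range(n_perm):
        draw = rng.choice(len(universe), size=k, replace=False)
        vals = ind[draw]
        nulls[j] = vals.mean()
        pooled[j * k: (j + 1) * k] = vals
    p_emp = (1.0 + (nulls >= observed).sum()) / (n_perm + 1.0)
    cand_vals = ind[cand_idx]
    if np.ptp(np.r_[cand_vals, pooled]) == 0:
        p_wil = 1.0
    else:
        p_wil = float(
            stats.mannwhitneyu(cand_vals, pooled, alternative="greater").pvalue
        )
    return EnrichmentVerdict(
        observed=observed,
        null_fractions=nulls,
        p_empirical=float(p_emp),
        p_wilcoxon=p_wil,
        n_perm=n_perm,
    )


def trial_enrichment(
    candidates: list[str],
    annotations: DrugAnnotations,
    disease: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentVerdict:
    """Are candidates enriched for drugs already in trials for the disease?

    Null: n_perm same-size random draws (without replacement) from the
    FDA-approved universe.
    """
    universe = annotations.fda_universe
    indicator = pd.Series(
        {
            d: float(annotations.in_trial.get(d, {}).get(disease, False))
            for d in universe
        }
    )
    return _permutation_verdict(indicator, list(candidates), universe, n_perm, seed)


def prism_enrichment(
    candidates: list[str],
    v: ViabilityTable,
    disease: str,
    n_perm: int = 10000,
    seed: int = 0,
    threshold: float = 0.3,
) -> EnrichmentVerdict:
    """Are candidates enriched for drugs the disease's cell lines are
    sensitive to?  A drug counts as sensitive when a strict majority of its
    evaluated disease lines are sensitive (< threshold)."""
    lines = v.lines_for(disease)
    if not lines:
        raise ValueError(f"no cell lines annotated for disease {disease!r}")
    sens, _ = sensitivity_call(v, threshold=threshold)
    sub = sens[lines].astype("Float64")
    evaluated = sub.notna().sum(axis=1)
    n_sens = sub.sum(axis=1, skipna=True).astype(float)
    drug_sensitive = (evaluated > 0) & (n_sens > evaluated / 2.0)
    universe = [d for d in v.values.index if evaluated[d] > 0]
    indicator = drug_sensitive.loc[universe].astype(float)
    return _permutation_verdict(indicator, list(candidates), universe, n_perm, seed)


def target_dsea(
    candidates: list[str], annotations: DrugAnnotations
) -> pd.DataFrame:
    """Hypergeometric drug-set enrichment of each target gene's drug set.

    For target t annotated to K drugs of the N-drug FDA universe, with k of
    the n candidates hitting t: p = upper-tail hypergeometric, BH-adjusted
    across targets.
    """
    universe = annotations.fda_universe
    if not universe:
        raise ValueError("empty FDA-approved universe")
    cand = [d for d in candidates if d in set(universe)]
    n_univ, n_cand = len(universe), len(cand)
    by_target: dict[str, set] = {}
    for d in universe:
        for t in annotations.targets.get(d, ()):
            by_target.setdefault(t, set()).add(d)
    rows = []
    cand_set = set(cand)
    for t, drugs in sorted(by_target.items()):
        k = len(drugs & cand_set)
        K = len(drugs)
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_cand)) if k > 0 else 1.0
        rows.append(
            {"target": t, "n_candidates": k, "n_universe": K, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows).set_index("target")
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    return out


def gene_effect_summary(
    effect_matrix: pd.DataFrame,
    lines: list[str],
    genes: list[str],
) -> pd.Series:
    """Mean CRISPR gene-effect score per gene over the requested cell lines.

    ``effect_matrix`` is cell-line x gene; missing entries are ignored;
    requested lines/genes absent from the matrix are dropped with a warning.
    """
    have_lines = [ln for ln in lines if ln in effect_matrix.index]
    have_genes = [g for g in genes if g in effect_matrix.columns]
    dropped = (len(lines) - len(have_lines)) + (len(genes) - len(have_genes))
    if dropped:
        warnings.warn(
            f"gene_effect_summary: {dropped} requested line(s)/gene(s) absent",
            RuntimeWarning,
        )
    if not have_lines or not have_genes:
        raise ValueError("no overlap between request and effect matrix")
    return effect_matrix.loc[have_lines, have_genes].mean(
        axis=0, skipna=True
    ).rename("mean_gene_effect")
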