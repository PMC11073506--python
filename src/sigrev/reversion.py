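"""LINCS-style signature reversion.

A disease signature (paired up/down gene sets) is scored against each drug's
perturbation profile with a bi-directional weighted Kolmogorov-Smirnov
statistic:

* ``weighted_es`` — GSEA-style running sum on the z-ranked profile, hits
  weighted by |z| (exponent 1), misses by 1/(G - |set|); ES is the running-sum
  extremum of largest magnitude.
* ``wtcs`` — (ES_up - ES_down)/2 when the two scores disagree in sign, else 0.
* ``normalize_ncs`` — WTCS divided by the signed mean of same-sign scores in
  the same cell-line group.
* ``compute_tau`` — signed percentile of |NCS| against a bank of matched-size
  random query signatures; -100 means more inverse than every reference query.
* ``permutation_fdr`` — one-sided (reversal-tail) permutation p with BH FDR.
* ``filter_candidates`` — the NCS < 0, FDR < 0.05, Tau < -80 candidate filter.

``run_reversion`` orchestrates all of the above for one query signature.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import adjust_pvalues
from .diffexp import GeneSignature

__all__ = [
    "PerturbationReference",
    "ConnectivityTable",
    "ReferenceBank",
    "weighted_es",
    "wtcs",
    "normalize_ncs",
    "compute_tau",
    "permutation_fdr",
    "filter_candidates",
    "run_reversion",
]


@dataclass
class PerturbationReference:
    """Drug x gene modified z-score matrix for one cell line."""

    zmat: pd.DataFrame
    cell_line: str = "unknown"

    def __post_init__(self) -> None:
        if not np.isfinite(self.zmat.to_numpy(dtype=float)).all():
            raise ValueError("perturbation z-scores must be finite")
        if self.zmat.index.has_duplicates or self.zmat.columns.has_duplicates:
            raise ValueError("drug and gene ids must be unique")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.zmat.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.zmat.columns)


@dataclass
class ConnectivityTable:
    """Per-drug reversion scores: ES pair, WTCS, NCS, Tau, permutation p/FDR."""

    table: pd.DataFrame   # columns: es_up, es_down, wtcs, ncs, tau, p, fdr
    cell_line: str = "unknown"

    def candidates(self, **kwargs) -> pd.DataFrame:
        return filter_candidates(self, **kwargs)


@dataclass
class ReferenceBank:
    """Null NCS values from matched-size random query signatures."""

    null_ncs: pd.DataFrame   # drugs x n_null
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.null_ncs.shape[1] < 100:
            raise ValueError("reference bank needs >= 100 null queries")


# ---------------------------------------------------------------------------
# enrichment-score core
# ---------------------------------------------------------------------------

def _rank_orders(zmat: np.ndarray, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-drug descending-z gene ordering with gene-id tie-break.

    Returns (rank_of [drugs x genes]: universe index -> rank position,
    ranked_weights [drugs x genes]: |z| in rank order).
    """
    name_rank = np.argsort(np.argsort(np.array(genes)))
    order = np.lexsort((np.broadcast_to(name_rank, zmat.shape), -zmat), axis=1)
    d_idx = np.arange(zmat.shape[0])[:, None]
    rank_of = np.empty_like(order)
    rank_of[d_idx, order] = np.arange(zmat.shape[1])[None, :]
    ranked_w = np.abs(zmat)[d_idx, order]
    return rank_of, ranked_w


def _es_many(pos: np.ndarray, ranked_w: np.ndarray, n_genes: int) -> np.ndarray:
    """Vectorized ES for many hit-position sets on one ranked profile.

    ``pos`` is (m, k) with each row sorted ascending.  The running-sum
    extremum can only occur immediately after a hit (max candidates) or
    immediately before one (min candidates); the walk starts and ends at 0.
    """
    m, k = pos.shape
    w = ranked_w[pos]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] <= 0
    if zero.any():                      # all-zero weights: equal-weight fallback
        w[zero] = 1.0
        total[zero] = k
    miss = 1.0 / (n_genes - k)
    cumw = np.cumsum(w, axis=1) / total
    misses_before = pos - np.arange(k)[None, :]
    after = cumw - misses_before * miss
    before = after - w / total
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    # |max| vs |min| ties (exact when G - k divides the hit count) resolve
    # toward the positive extremum, with float tolerance
    return np.where(hi >= -lo - 1e-12, hi, lo)


def weighted_es(profile: pd.Series, gene_set) -> float:
    """Weighted KS enrichment score of ``gene_set`` on a z-score profile.

    Genes are ranked by z descending (ties by gene id); a hit at rank i adds
    |z_i| / sum of |z| over the set, a miss subtracts 1/(G - |set|); the ES is
    the signed running-sum value of largest magnitude (ties resolved toward
    the positive extremum).
    """
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    if len(gene_set) >= len(profile):
        raise ValueError("gene set must be a proper subset of the profile genes")
    missing = [g for g in gene_set if g not in profile.index]
    if missing:
        raise KeyError(f"gene set members absent from profile: {missing[:5]}")
    genes = list(profile.index)
    rank_of, ranked_w = _rank_orders(profile.to_numpy(dtype=float)[None, :], genes)
    loc = {g: i for i, g in enumerate(genes)}
    pos = np.sort(rank_of[0, [loc[g] for g in gene_set]])[None, :]
    return float(_es_many(pos, ranked_w[0], len(genes))[0])


def wtcs(es_up: float, es_down: float) -> float:
    """Bi-directional connectivity score: (ES_up - ES_down)/2, 0 on same sign."""
    for v in (es_up, es_down):
        if not -1.0 <= v <= 1.0:
            raise ValueError("enrichment scores must lie in [-1, 1]")
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def normalize_ncs(
    wtcs_values: pd.Series, flag_unit: bool = False
) -> pd.Series | tuple[pd.Series, list[str]]:
    """NCS within one cell-line group: divide by the signed same-sign mean.

    Positive scores are divided by the mean of positive scores, negative by
    the magnitude of the mean of negative scores; zeros stay zero.  A score
    with no same-sign peers is its own group mean (NCS magnitude 1); such
    drugs are reported when ``flag_unit`` is set.
    """
    v = wtcs_values.to_numpy(dtype=float)
    out = np.zeros_like(v)
    flagged: list[str] = []
    pos, neg = v > 0, v < 0
    if pos.any():
        out[pos] = v[pos] / v[pos].mean()
        if pos.sum() == 1:
            flagged.extend(wtcs_values.index[pos])
    if neg.any():
        out[neg] = v[neg] / abs(v[neg].mean())
        if neg.sum() == 1:
            flagged.extend(wtcs_values.index[neg])
    res = pd.Series(out, index=wtcs_values.index, name="ncs")
    return (res, flagged) if flag_unit else res


def compute_tau(ncs_q: pd.Series, bank: ReferenceBank) -> pd.Series:
    """Signed percentile of |NCS| against the per-drug null NCS bank.

    tau(d) = sign(ncs_q(d)) * 100/N * #{r : |NCS_null(d, r)| < |ncs_q(d)|}.
    """
    missing = set(ncs_q.index) - set(bank.null_ncs.index)
    if missing:
        raise ValueError(f"bank lacks null NCS for drugs: {sorted(missing)[:5]}")
    null_abs = np.abs(bank.null_ncs.loc[ncs_q.index].to_numpy(dtype=float))
    n = null_abs.shape[1]
    q = np.abs(ncs_q.to_numpy(dtype=float))[:, None]
    frac = (null_abs < q).sum(axis=1) * (100.0 / n)
    return pd.Series(
        np.sign(ncs_q.to_numpy(dtype=float)) * frac, index=ncs_q.index, name="tau"
    )


class _Scorer:
    """Pre-ranked reference enabling vectorized batch WTCS computation."""

    def __init__(self, ref: PerturbationReference):
        self.genes = ref.gene_ids
        self.drugs = ref.drug_ids
        self.loc = {g: i for i, g in enumerate(self.genes)}
        self.rank_of, self.ranked_w = _rank_orders(
            ref.zmat.to_numpy(dtype=float), self.genes
        )
        self.n_genes = len(self.genes)

    def to_idx(self, gene_set) -> np.ndarray:
        return np.array([self.loc[g] for g in gene_set], dtype=int)

    def es_sets(self, idx_sets: np.ndarray) -> np.ndarray:
        """ES of each index set (m x k) against each drug -> (drugs x m)."""
        out = np.empty((len(self.drugs), idx_sets.shape[0]))
        for i in range(len(self.drugs)):
            pos = np.sort(self.rank_of[i, idx_sets], axis=1)
            out[i] = _es_many(pos, self.ranked_w[i], self.n_genes)
        return out

    def wtcs_sets(self, up_sets: np.ndarray, down_sets: np.ndarray) -> np.ndarray:
        eu = self.es_sets(up_sets)
        ed = self.es_sets(down_sets)
        w = (eu - ed) / 2.0
        return np.where(eu * ed > 0, 0.0, w)


def _null_index_sets(
    rng: np.random.Generator, n_genes: int, n_up: int, n_down: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    picks = np.empty((n, n_up + n_down), dtype=int)
    for j in range(n):
        picks[j] = rng.choice(n_genes, size=n_up + n_down, replace=False)
    return picks[:, :n_up], picks[:, n_up:]


def permutation_fdr(
    sig: GeneSignature,
    ref: PerturbationReference,
    n_perm: int = 1000,
    seed: int = 0,
    observed_wtcs: pd.Series | None = None,
) -> pd.DataFrame:
    """One-sided (reversal-tail) permutation p per drug, BH-adjusted.

    The null draws random up/down gene sets of the query's in-reference sizes
    from the reference gene universe; p(d) = (1 + #{null WTCS <= WTCS(d)}) /
    (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scorer = _Scorer(ref)
    up = [g for g in sig.up if g in scorer.loc]
    down = [g for g in sig.down if g in scorer.loc]
    if not up or not down:
        raise ValueError("query must retain both up and down genes in-reference")
    if observed_wtcs is None:
        w = scorer.wtcs_sets(
            scorer.to_idx(up)[None, :], scorer.to_idx(down)[None, :]
        )[:, 0]
        observed_wtcs = pd.Series(w, index=scorer.drugs)
    rng = np.random.default_rng(seed)
    null_up, null_down = _null_index_sets(
        rng, scorer.n_genes, len(up), len(down), n_perm
    )
    null_w = scorer.wtcs_sets(null_up, null_down)
    obs = observed_wtcs.loc[scorer.drugs].to_numpy(dtype=float)
    p = (1.0 + (null_w <= obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return pd.DataFrame(
        {"p": p, "fdr": adjust_pvalues(p, "bh")},
        index=pd.Index(scorer.drugs, name="drug"),
    )


def filter_candidates(
    ct: ConnectivityTable,
    annotations=None,
    tau_cut: float = -80.0,
    fdr_cut: float = 0.05,
    fda_only: bool = True,
) -> pd.DataFrame:
    """Candidate filter: NCS < 0, FDR < fdr_cut, Tau < tau_cut (all strict),
    optionally restricted to FDA-approved drugs; ordered by NCS ascending."""
    t = ct.table
    keep = (t["ncs"] < 0) & (t["fdr"] < fdr_cut) & (t["tau"] < tau_cut)
    if fda_only and annotations is not None:
        approved = t.index.map(lambda d: annotations.fda_approved.get(d, False))
        keep &= np.asarray(approved, dtype=bool)
    return t[keep].sort_values("ncs")


def run_reversion(
    sig: GeneSignature,
    ref: PerturbationReference,
    n_perm: int = 1000,
    n_bank: int = 1000,
    seed: int = 0,
) -> ConnectivityTable:
    """Full reversion scoring of one query signature against a reference.

    Deterministic given ``seed``; two independent null-signature draws feed
    the permutation p/FDR (``n_perm``) and the Tau bank (``n_bank``).
    """
    scorer = _Scorer(ref)
    up = [g for g in sig.up if g in scorer.loc]
    down = [g for g in sig.down if g in scorer.loc]
    n_query = len(sig.up) + len(sig.down)
    if n_query == 0:
        raise ValueError("empty query signature")
    if len(up) + len(down) == 0:
        raise ValueError("no query gene is present in the reference")
    if (len(up) + len(down)) < 0.5 * n_query:
        warnings.warn(
            f"only {len(up) + len(down)}/{n_query} query genes present in the "
            "reference", RuntimeWarning,
        )
    if not up or not down:
        raise ValueError("query must retain both up and down genes in-reference")

    es_up = scorer.es_sets(scorer.to_idx(up)[None, :])[:, 0]
    es_down = scorer.es_sets(scorer.to_idx(down)[None, :])[:, 0]
    w = np.where(es_up * es_down > 0, 0.0, (es_up - es_down) / 2.0)
    ncs = normalize_ncs(pd.Series(w, index=scorer.drugs))

    seeds = np.random.SeedSequence(seed).spawn(2)
    rng_perm, rng_bank = (np.random.default_rng(s) for s in seeds)

    null_up, null_down = _null_index_sets(
        rng_perm, scorer.n_genes, len(up), len(down), n_perm
    )
    null_w = scorer.wtcs_sets(null_up, null_down)
    p = (1.0 + (null_w <= w[:, None]).sum(axis=1)) / (n_perm + 1.0)
    fdr = adjust_pvalues(p, "bh")

    # Tau bank: each null query is scored across all drugs then NCS-normalized
    # within the (single cell line) group, giving per-drug null NCS columns.
    bank_up, bank_down = _null_index_sets(
        rng_bank, scorer.n_genes, len(up), len(down), n_bank
    )
    bank_w = scorer.wtcs_sets(bank_up, bank_down)
    null_ncs = np.empty_like(bank_w)
    for j in range(bank_w.shape[1]):
        null_ncs[:, j] = normalize_ncs(
            pd.Series(bank_w[:, j], index=scorer.drugs)
        ).to_numpy()
    bank = ReferenceBank(
        null_ncs=pd.DataFrame(null_ncs, index=scorer.drugs),
        n_up=len(up), n_down=len(down),
    )
    tau = compute_tau(ncs, bank)

    table = pd.DataFrame(
        {
            "es_up": es_up,
            "es_down": es_down,
            "wtcs": w,
            "ncs": ncs.to_numpy(),
            "tau": tau.to_numpy(),
            "p": p,
            "fdr": fdr,
        },
        index=pd.Index(scorer.drugs, name="drug"),
    )
    return ConnectivityTable(table=table, cell_line=ref.cell_line)
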