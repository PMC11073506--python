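"""Functional enrichment and ontology semantic similarity.

Signature gene sets (and per-profile |z| > 2 gene sets) are tested for term
enrichment with the upper-tail hypergeometric and BH adjustment.  Enriched
terms are compared by Wang's graph-based semantic similarity — each term's
ancestors receive an S-value propagated down-weighted along is_a (0.8) and
part_of (0.6) edges; similarity is the shared-ancestor S-mass over the total
S-mass of both terms — and grouped by Ward clustering on 1 - similarity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import adjust_pvalues

__all__ = [
    "Ontology",
    "hypergeom_enrich",
    "profile_gene_sets",
    "wang_similarity",
    "group_terms",
]

EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class Ontology:
    """A small DAG ontology: child -> (parent, relation) edges + annotations."""

    terms: list[str]
    parents: dict = field(default_factory=dict)   # term -> [(parent, relation)]
    annotations: dict = field(default_factory=dict)  # term -> set of genes

    def __post_init__(self) -> None:
        known = set(self.terms)
        for child, plist in self.parents.items():
            for parent, rel in plist:
                if child not in known or parent not in known:
                    raise ValueError(f"edge {child}->{parent} uses unknown term")
                if rel not in EDGE_WEIGHTS:
                    raise ValueError(f"unknown relation {rel!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p, _ in self.parents.get(t, ()):
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"ontology contains a cycle through {p!r}")
                if s == 0:
                    visit(p)
            state[t] = 2

        for t in self.terms:
            if state.get(t, 0) == 0:
                visit(t)

    def term_size(self, term: str) -> int:
        return len(self.annotations.get(term, ()))


def hypergeom_enrich(
    query: set,
    collection: dict,
    universe: set,
    direction: str = "up",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term set.

    Term sets and the query are intersected with the universe; p is the
    probability of an overlap at least as large under random draws of
    |query| genes from the universe; BH adjustment across terms.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_univ, n_query = len(universe), len(query)
    rows = []
    for term, genes in sorted(collection.items()):
        term_set = set(genes) & universe
        k = len(term_set & query)
        K = len(term_set)
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_query)) if k > 0 else 1.0
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "query_size": n_query,
                "p": min(p, 1.0),
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    return out


def profile_gene_sets(
    profile: pd.Series, z_cut: float = 2.0
) -> tuple[set, set]:
    """Up/down gene sets from a perturbation profile: z > z_cut, z < -z_cut
    (strict inequalities)."""
    z = profile.astype(float)
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("profile must be finite")
    up = set(z.index[z > z_cut])
    down = set(z.index[z < -z_cut])
    return up, down


def _svalues(term: str, onto: Ontology, weights: dict) -> dict:
    """Wang S-values of ``term`` and its ancestors.

    S(term) = 1; walking edges upward, S(parent) = max over children c on
    paths from term of w_edge(c -> parent) * S(c).
    """
    if term not in set(onto.terms):
        raise KeyError(f"unknown term: {term}")
    s = {term: 1.0}
    frontier = [term]
    while frontier:
        nxt = []
        for child in frontier:
            for parent, rel in onto.parents.get(child, ()):
                cand = weights[rel] * s[child]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return s


def wang_similarity(
    a: str,
    b: str,
    onto: Ontology,
    w_is_a: float = 0.8,
    w_part_of: float = 0.6,
) -> float:
    """Wang semantic similarity of two ontology terms in [0, 1].

    sim = sum over shared ancestors t of (S_a(t) + S_b(t)) divided by
    (SV(a) + SV(b)) where SV is each term's total S-mass; two terms whose
    ancestor sets do not intersect (separate roots) score 0.
    """
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    sa = _svalues(a, onto, weights)
    sb = _svalues(b, onto, weights)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    return float(num / (sum(sa.values()) + sum(sb.values())))


def group_terms(
    sim: pd.DataFrame,
    threshold: float = 0.7,
    term_sizes: dict | None = None,
) -> pd.DataFrame:
    """Ward-linkage grouping of terms on the 1 - similarity distance.

    The dendrogram is cut at distance 1 - threshold; each group's
    representative is its largest-annotation term (ties broken
    lexicographically).  Returns a table (term -> group, representative).
    """
    terms = list(sim.index)
    if list(sim.columns) != terms:
        raise ValueError("similarity matrix must be square with matching labels")
    S = sim.to_numpy(dtype=float)
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    term_sizes = term_sizes or {}
    if len(terms) == 1:
        return pd.DataFrame(
            {"group": [0], "representative": [terms[0]]},
            index=pd.Index(terms, name="term"),
        )
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    linkage = hierarchy.linkage(squareform(D, checks=False), method="ward")
    labels = hierarchy.fcluster(linkage, t=1.0 - threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for t, lab in zip(terms, labels):
        groups.setdefault(int(lab), []).append(t)
    # contiguous group ids in order of first appearance; size-then-name reps
    remap: dict[int, int] = {}
    rep: dict[int, str] = {}
    for t, lab in zip(terms, labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = len(remap)
            members = groups[lab]
            rep[remap[lab]] = min(
                members, key=lambda m: (-term_sizes.get(m, 0), m)
            )
    return pd.DataFrame(
        {
            "group": [remap[int(lab)] for lab in labels],
            "representative": [rep[remap[int(lab)]] for lab in labels],
        },
        index=pd.Index(terms, name="term"),
    )
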