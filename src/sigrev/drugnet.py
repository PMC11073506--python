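"""Drug-drug similarity networks and PPI centrality comparison.

Pairwise drug similarity comes from either the cosine of perturbation
profiles or the Tanimoto coefficient of structure fingerprints; the network
keeps the globally highest 10% of off-diagonal pairs and is partitioned into
Leiden communities.  Signature gene sets are compared on a high-confidence
protein-protein-interaction network (combined score / 1000 > 0.7) by degree,
Brandes betweenness, and eigenvector centrality, with a Kruskal-Wallis
omnibus test followed by BH-adjusted pairwise rank-sum tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import adjust_pvalues

__all__ = [
    "SimilarityMatrix",
    "DrugNetwork",
    "cosine_matrix",
    "tanimoto_matrix",
    "top_edge_network",
    "detect_communities",
    "ppi_centrality",
    "centrality_group_test",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity with degenerate rows flagged."""

    values: pd.DataFrame
    metric: str                       # 'cosine' | 'tanimoto'
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class DrugNetwork:
    """Weighted undirected similarity graph with optional communities."""

    graph: nx.Graph
    communities: dict = field(default_factory=dict)     # node -> community id


def cosine_matrix(profiles: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise cosine similarity between drug profile rows.

    All-zero rows have undefined similarity: their off-diagonal entries (and
    diagonal) are NaN and the row id is flagged.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 drugs")
    X = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    degenerate = list(profiles.index[norms == 0])
    safe = np.where(norms > 0, norms, 1.0)
    S = (X / safe[:, None]) @ (X / safe[:, None]).T
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, np.where(norms > 0, 1.0, np.nan))
    bad = norms == 0
    S[bad, :] = np.nan
    S[:, bad] = np.nan
    return SimilarityMatrix(
        values=pd.DataFrame(S, index=profiles.index, columns=profiles.index),
        metric="cosine",
        degenerate=degenerate,
    )


def tanimoto_matrix(fingerprints: dict) -> SimilarityMatrix:
    """Pairwise Tanimoto coefficient |a AND b| / |a OR b| between bit vectors."""
    ids = list(fingerprints)
    if len(ids) < 2:
        raise ValueError("need >= 2 fingerprints")
    F = np.array([np.asarray(fingerprints[d], dtype=bool) for d in ids])
    if len({f.size for f in F}) > 1:
        raise ValueError("fingerprints must have equal length")
    inter = (F[:, None, :] & F[None, :, :]).sum(axis=2).astype(float)
    union = (F[:, None, :] | F[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / union, np.nan)
    degenerate = [ids[i] for i in range(len(ids)) if F[i].sum() == 0]
    return SimilarityMatrix(
        values=pd.DataFrame(S, index=ids, columns=ids),
        metric="tanimoto",
        degenerate=degenerate,
    )


def top_edge_network(
    sim: SimilarityMatrix,
    keep_fraction: float = 0.10,
    labels: dict | None = None,
) -> DrugNetwork:
    """Keep the ceil(keep_fraction * n_pairs) largest off-diagonal pairs.

    Ties at the cut value are all retained; isolated nodes stay in the graph.
    NaN pairs (degenerate rows) are never edges.
    """
    ids = list(sim.values.index)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    V = sim.values.to_numpy(dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    weights = V[iu, ju]
    ok = np.isfinite(weights)
    n_pairs = len(weights)
    m = int(np.ceil(keep_fraction * n_pairs))
    finite_sorted = np.sort(weights[ok])[::-1]
    m_eff = min(m, finite_sorted.size)
    g = nx.Graph()
    for i, d in enumerate(ids):
        lab = (labels or {}).get(d)
        if lab is None:
            g.add_node(d)
        else:
            g.add_node(d, label=lab)
    if m_eff > 0:
        cut = finite_sorted[m_eff - 1]
        keep = ok & (weights >= cut)
        for i, j in zip(iu[keep], ju[keep]):
            g.add_edge(ids[i], ids[j], weight=float(V[i, j]))
    return DrugNetwork(graph=g)


def detect_communities(
    net: DrugNetwork, resolution: float = 1.0, seed: int = 0
) -> dict:
    """Seeded Leiden partition maximizing (resolution-scaled) modularity.

    Community ids are contiguous from 0, ordered by first node appearance.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(g.nodes)
    if g.number_of_edges() == 0:
        assignment = {d: i for i, d in enumerate(nodes)}
        net.communities = assignment
        return assignment
    index = {d: i for i, d in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g.edges[u, v].get("weight", 1.0) for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges)
    if resolution == 1.0:
        part = leidenalg.find_partition(
            h, leidenalg.ModularityVertexPartition,
            weights=weights, seed=seed, n_iterations=-1,
        )
    else:
        part = leidenalg.find_partition(
            h, leidenalg.RBConfigurationVertexPartition,
            weights=weights, seed=seed, n_iterations=-1,
            resolution_parameter=resolution,
        )
    raw = part.membership
    remap: dict[int, int] = {}
    assignment = {}
    for d in nodes:
        c = raw[index[d]]
        if c not in remap:
            remap[c] = len(remap)
        assignment[d] = remap[c]
    net.communities = assignment
    return assignment


def _eigenvector_by_component(g: nx.Graph, tol: float = 1e-9) -> dict:
    """Power-iteration eigenvector centrality, unit-normalized per component."""
    out: dict = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            out[nodes[0]] = 1.0
            continue
        A = nx.to_numpy_array(g, nodelist=nodes, weight=None)
        # shift by I: same eigenvectors, but a unique dominant eigenvalue even
        # on bipartite components (plain iteration oscillates there)
        A = A + np.eye(len(nodes))
        x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
        for _ in range(10000):
            y = A @ x
            norm = np.linalg.norm(y)
            if norm == 0:
                break
            y /= norm
            if np.abs(y - x).max() < tol:
                x = y
                break
            x = y
        x = np.abs(x)
        x /= np.linalg.norm(x)
        out.update(dict(zip(nodes, x)))
    return out


def ppi_centrality(
    edges: pd.DataFrame, score_cut: float = 0.7
) -> pd.DataFrame:
    """Degree, Brandes betweenness (unnormalized), eigenvector centrality of
    the high-confidence PPI graph.

    ``edges`` has columns (protein_a, protein_b, combined_score) with scores
    on the raw 0-1000 scale; an edge is kept when score/1000 > score_cut
    (strict).  Eigenvector centrality is computed per connected component by
    power iteration to 1e-9 and unit-normalized within the component.
    """
    needed = {"protein_a", "protein_b", "combined_score"}
    if not needed <= set(edges.columns):
        raise ValueError(f"edge table must have columns {sorted(needed)}")
    kept = edges[edges["combined_score"] / 1000.0 > score_cut]
    g = nx.Graph()
    for _, row in kept.iterrows():
        g.add_edge(str(row["protein_a"]), str(row["protein_b"]))
    if g.number_of_nodes() == 0:
        raise ValueError("no edge passes the score filter")
    deg = dict(g.degree)
    btw = nx.betweenness_centrality(g, normalized=False)
    eig = _eigenvector_by_component(g)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
        },
        index=pd.Index(nodes, name="protein"),
    )


def centrality_group_test(
    groups: dict, alpha: float = 0.05
) -> dict:
    """Kruskal-Wallis omnibus over disjoint route-unique centrality samples;
    pairwise two-tailed rank-sum tests (BH primary, Bonferroni also reported)
    only when the omnibus rejects at ``alpha``."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for nm in names:
        if len(groups[nm]) < 2:
            raise ValueError(f"group {nm!r} has fewer than 2 values")
    samples = [np.asarray(groups[nm], dtype=float) for nm in names]
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0          # identical groups: no evidence of difference
    else:
        h, p = stats.kruskal(*samples)
    result = {"kruskal_h": float(h), "kruskal_p": float(p), "pairwise": None}
    if p < alpha:
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pw = stats.mannwhitneyu(
                    samples[i], samples[j], alternative="two-sided"
                ).pvalue
                rows.append(
                    {"group_a": names[i], "group_b": names[j], "p": float(pw)}
                )
        tab = pd.DataFrame(rows)
        tab["p_adj_bh"] = adjust_pvalues(tab["p"].to_numpy(), "bh")
        tab["p_adj_bonferroni"] = adjust_pvalues(tab["p"].to_numpy(), "bonferroni")
        result["pairwise"] = tab
    return result
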