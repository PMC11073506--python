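"""Independent brute-force oracles used to validate the implementations.

Each oracle is written directly from the mathematical definition, avoiding
the code paths (and the algorithmic shortcuts) of the package itself.
"""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd


def brute_force_es(profile: pd.Series, gene_set) -> float:
    """Weighted KS enrichment score by explicit full-length running sum."""
    gene_set = set(gene_set)
    order = sorted(profile.index, key=lambda g: (-profile[g], g))
    G = len(order)
    k = len(gene_set)
    hit_weight_total = sum(abs(profile[g]) for g in gene_set)
    running = 0.0
    path = []
    for g in order:
        if g in gene_set:
            if hit_weight_total > 0:
                running += abs(profile[g]) / hit_weight_total
            else:
                running += 1.0 / k
        else:
            running -= 1.0 / (G - k)
        path.append(running)
    hi = max(max(path), 0.0)
    lo = min(min(path), 0.0)
    # tie rule shared with the implementation: positive extremum wins
    return hi if hi >= -lo - 1e-12 else lo


def modularity(g: nx.Graph, partition: dict) -> float:
    """Newman modularity of a node -> community assignment (weighted)."""
    m2 = sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True)) * 2.0
    if m2 == 0:
        return 0.0
    deg = {
        v: sum(d.get("weight", 1.0) for _, _, d in g.edges(v, data=True))
        for v in g.nodes
    }
    q = 0.0
    for u, v, d in g.edges(data=True):
        if partition[u] == partition[v]:
            q += 2.0 * d.get("weight", 1.0)
    for u in g.nodes:
        for v in g.nodes:
            if partition[u] == partition[v]:
                q -= deg[u] * deg[v] / m2
    return q / m2


def _set_partitions(items: list):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity(g: nx.Graph) -> float:
    """Exhaustive maximum modularity over all partitions (tiny graphs only)."""
    nodes = list(g.nodes)
    assert len(nodes) <= 8, "exhaustive search is for <= 8 nodes"
    best = -np.inf
    for part in _set_partitions(nodes):
        assign = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, modularity(g, assign))
    return best


def naive_betweenness(g: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit all-pairs shortest-path counting."""
    out = {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        n_paths = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            via = sum(1 for p in paths if v in p)
            out[v] += via / n_paths
    return out


def wang_by_paths(a: str, b: str, terms, parents, weights) -> float:
    """Wang similarity via explicit enumeration of all upward edge paths.

    S_t(anc) = max over paths t -> anc of the product of edge weights.
    """

    def svalues(term: str) -> dict:
        s = {term: 1.0}
        stack = [(term, 1.0)]
        while stack:
            node, val = stack.pop()
            for parent, rel in parents.get(node, ()):  # walk every path
                cand = val * weights[rel]
                if cand > s.get(parent, 0.0) - 1e-15:
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                    stack.append((parent, cand))
        return s

    sa, sb = svalues(a), svalues(b)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    return sum(sa[t] + sb[t] for t in shared) / (
        sum(sa.values()) + sum(sb.values())
    )
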