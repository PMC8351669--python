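"""Enrichment map: term-similarity network, MCL clustering, auto-labels.

Significant gene-set terms become nodes; edges connect terms whose gene-set
similarity (overlap coefficient by default) reaches a cutoff (default 0.7).
Clusters are found with the Markov Clustering algorithm (MCL); each cluster
is labelled automatically from the most frequent words of its member term
names (with a bonus for words adjacent to already-selected words) and
collapsed into a meta-node whose summary FDR is the minimum member FDR.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_SIMILARITY_CUTOFF = 0.7
DEFAULT_METRIC = "overlap"
DEFAULT_INFLATION = 2.0
DEFAULT_MAX_ITER = 100
DEFAULT_PRUNE_EPS = 1e-5
DEFAULT_MAX_LABEL_WORDS = 4
DEFAULT_ADJACENCY_BONUS = 8

# English function words plus gene-ontology boilerplate; domain words such as
# "regulation" stay in because real cluster labels use them.
STOPWORDS = frozenset(
    """a an and are as at be by for from in into is it its of on or that the
    to via with process processes""".split()
)


@dataclass
class MetaNode:
    cluster_id: int
    label: str
    n_nodes: int
    summary_fdr: float
    member_terms: list[str]


@dataclass
class TermGraph:
    """GO-term similarity graph with optional MCL cluster ids."""

    graph: nx.Graph
    clusters: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def set_similarity(a: set[str], b: set[str], metric: str = DEFAULT_METRIC) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "overlap":
        return inter / min(len(a), len(b))
    if metric == "combined":
        return 0.5 * inter / len(a | b) + 0.5 * inter / min(len(a), len(b))
    raise ValueError(f"unknown metric {metric!r}")


def build_term_graph(
    rows: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    cutoff: float = DEFAULT_SIMILARITY_CUTOFF,
    metric: str = DEFAULT_METRIC,
) -> TermGraph:
    """Similarity graph over the terms of an enrichment table.

    ``gene_sets`` maps term_id to the gene set used for similarity (full
    within-universe membership by default upstream; hit-only sets are an
    accepted alternative).  Edges kept when similarity >= cutoff.
    """
    G = nx.Graph()
    terms = list(rows["term_id"])
    for _, r in rows.iterrows():
        G.add_node(r["term_id"], name=r.get("name", r["term_id"]), fdr=float(r["fdr"]))
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            s = set_similarity(gene_sets[terms[i]], gene_sets[terms[j]], metric)
            if s >= cutoff:
                G.add_edge(terms[i], terms[j], similarity=s)
    return TermGraph(graph=G)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(
    tg: TermGraph,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = DEFAULT_MAX_ITER,
    prune_eps: float = DEFAULT_PRUNE_EPS,
) -> dict[str, int]:
    """Markov clustering of the term graph.

    A column-stochastic transition matrix is built from edge similarities
    with self-loops weighted by each node's maximum incident weight; the MCL
    iteration alternates expansion (matrix squaring) and inflation
    (elementwise power + column renormalization), pruning entries below
    ``prune_eps``, until the matrix changes by < 1e-6 or ``max_iter`` is hit.
    Clusters are the connected components of the attractor support.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = list(tg.graph.nodes)
    n = len(nodes)
    if n == 0:
        tg.clusters = {}
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, d in tg.graph.edges(data=True):
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = d["similarity"]
    max_inc = M.max(axis=0)
    np.fill_diagonal(M, np.where(max_inc > 0, max_inc, 1.0))
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = M**inflation  # inflation
        M[M < prune_eps] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < 1e-6:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; interpreting the current matrix")
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows_nz, cols_nz = np.nonzero(M > prune_eps)
    support.add_edges_from(zip(rows_nz, cols_nz))
    clusters: dict[str, int] = {}
    for cid, comp in enumerate(
        sorted(nx.connected_components(support), key=lambda c: (-len(c), min(c))),
        start=1,
    ):
        for i in comp:
            clusters[nodes[i]] = cid
    tg.clusters = clusters
    return clusters


# ---------------------------------------------------------------------------
# Cluster labelling
# ---------------------------------------------------------------------------

def _tokenize(name: str) -> list[str]:
    return [w for w in re.split(r"[^a-z0-9\-]+", name.lower()) if w]


def label_cluster(
    term_names: list[str],
    max_words: int = DEFAULT_MAX_LABEL_WORDS,
    adjacency_bonus: float = DEFAULT_ADJACENCY_BONUS,
    stopwords: frozenset[str] = STOPWORDS,
) -> str:
    """Greedy word-frequency label for a cluster of term names.

    score(word) = occurrences across member names + adjacency_bonus for each
    adjacency (within a name) to an already-selected word; up to
    ``max_words`` words are picked greedily by descending score and joined in
    selection order.
    """
    if not term_names:
        raise ValueError("need at least one term name")
    token_lists = [_tokenize(name) for name in term_names]
    counts: dict[str, int] = {}
    neighbors: dict[str, dict[str, int]] = {}
    for toks in token_lists:
        for i, w in enumerate(toks):
            counts[w] = counts.get(w, 0) + 1
            for j in (i - 1, i + 1):
                if 0 <= j < len(toks):
                    neighbors.setdefault(w, {})
                    neighbors[w][toks[j]] = neighbors[w].get(toks[j], 0) + 1
    usable = {w: c for w, c in counts.items() if w not in stopwords}
    if not usable:
        # all-stopword names: fall back to the highest-count raw token
        return max(counts, key=lambda w: (counts[w], w))
    selected: list[str] = []
    while len(selected) < max_words and usable:
        def score(w: str) -> float:
            adj = sum(neighbors.get(w, {}).get(s, 0) for s in selected)
            return usable[w] + adjacency_bonus * adj

        best = max(sorted(usable), key=score)
        selected.append(best)
        del usable[best]
    return " ".join(selected)


# ---------------------------------------------------------------------------
# Meta-node collapse
# ---------------------------------------------------------------------------

def collapse_to_meta(
    tg: TermGraph,
    max_words: int = DEFAULT_MAX_LABEL_WORDS,
    adjacency_bonus: float = DEFAULT_ADJACENCY_BONUS,
) -> tuple[list[MetaNode], pd.DataFrame]:
    """Collapse each MCL cluster into a meta-node; cross-cluster meta-edges.

    Summary FDR of a meta-node is the minimum member FDR.  Meta-edges carry
    the mean similarity of the collapsed cross-cluster edges and their count.
    """
    if not tg.clusters:
        raise ValueError("run mcl_cluster before collapsing")
    G = tg.graph
    metas = []
    for cid in sorted(set(tg.clusters.values())):
        members = sorted(t for t, c in tg.clusters.items() if c == cid)
        names = [G.nodes[t]["name"] for t in members]
        metas.append(
            MetaNode(
                cluster_id=cid,
                label=label_cluster(names, max_words, adjacency_bonus),
                n_nodes=len(members),
                summary_fdr=float(min(G.nodes[t]["fdr"] for t in members)),
                member_terms=members,
            )
        )
    cross: dict[tuple[int, int], list[float]] = {}
    for u, v, d in G.edges(data=True):
        cu, cv = tg.clusters[u], tg.clusters[v]
        if cu != cv:
            key = (min(cu, cv), max(cu, cv))
            cross.setdefault(key, []).append(d["similarity"])
    edges = pd.DataFrame(
        [
            {"cluster_a": a, "cluster_b": b,
             "mean_similarity": float(np.mean(sims)), "n_edges": len(sims)}
            for (a, b), sims in sorted(cross.items())
        ],
        columns=["cluster_a", "cluster_b", "mean_similarity", "n_edges"],
    )
    return metas, edges


def write_term_graph(tg: TermGraph, graphml_path, edgelist_path=None) -> None:
    """Export the clustered graph as GraphML (plus an edge-list TSV fallback)."""
    G = tg.graph.copy()
    for t, cid in tg.clusters.items():
        G.nodes[t]["cluster"] = cid
    nx.write_graphml(G, graphml_path)
    if edgelist_path is not None:
        rows = [
            {"term_a": u, "term_b": v, "similarity": d["similarity"]}
            for u, v, d in G.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["term_a", "term_b", "similarity"]).to_csv(
            edgelist_path, sep="\t", index=False
        )
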