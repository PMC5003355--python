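"""Overlap statistics between a co-expression network and a reference network.

A thresholded co-expression ("query") network is validated against an
independently derived interaction ("reference") network over the shared node
set: Jaccard similarity of the edge sets, an exact upper-tail hypergeometric
p-value for the edge overlap, and an empirical p-value from Erdos-Renyi
randomisation (uniform random graphs with the query's node set and edge
count).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph_analysis import threshold_network
from .io_ingest import read_reference_network
from .netbuild import AdjacencyMatrix

__all__ = ["NetworkOverlap", "overlap_stats", "er_randomisation_p", "threshold_sweep"]


@dataclass
class NetworkOverlap:
    shared_nodes: int
    universe_edges: int
    q_edges: int
    r_edges: int
    intersection: int
    jaccard: float
    p_hyper: float
    p_empirical: float | None = None
    n_randomisations: int = 0
    seed: int | None = None


def _edge_set(g: nx.Graph, nodes: set) -> set[tuple]:
    return {
        tuple(sorted((str(a), str(b))))
        for a, b in g.edges
        if a in nodes and b in nodes and a != b
    }


def overlap_stats(query: nx.Graph, reference: nx.Graph) -> NetworkOverlap:
    """Jaccard and hypergeometric overlap over the shared node set.

    Both edge sets are restricted to nodes present in both networks; the
    universe is all C(shared, 2) unordered pairs.  The p-value is the exact
    upper tail P(X >= intersection) for drawing the query's edges uniformly
    from the universe containing the reference's edges as successes.
    """
    shared = {str(n) for n in query.nodes} & {str(n) for n in reference.nodes}
    if not shared:
        raise ValueError("the two networks share no nodes")
    q = _edge_set(query, shared)
    r = _edge_set(reference, shared)
    inter = len(q & r)
    union = len(q | r)
    s = len(shared)
    universe = s * (s - 1) // 2
    jaccard = inter / union if union else float("nan")
    p = float(stats.hypergeom.sf(inter - 1, universe, len(r), len(q)))
    return NetworkOverlap(
        shared_nodes=s,
        universe_edges=universe,
        q_edges=len(q),
        r_edges=len(r),
        intersection=inter,
        jaccard=jaccard,
        p_hyper=min(max(p, 0.0), 1.0),
    )


def er_randomisation_p(
    query: nx.Graph, reference: nx.Graph, n: int = 1000, seed: int = 0
) -> float:
    """Empirical overlap p-value under Erdos-Renyi randomisation of the query.

    The query is replaced n times by a uniform random graph on the same
    shared-node universe with the same edge count (G(n, m)); the p-value is
    (1 + #{randomised overlap >= observed}) / (n + 1) — never exactly zero.
    """
    obs = overlap_stats(query, reference)
    rng = np.random.default_rng(seed)
    shared = sorted({str(x) for x in query.nodes} & {str(x) for x in reference.nodes})
    pairs = list(combinations(shared, 2))
    ref_idx = {
        i for i, p in enumerate(pairs)
        if p in _edge_set(reference, set(shared))
    }
    hits = 0
    for _ in range(n):
        draw = rng.choice(len(pairs), size=obs.q_edges, replace=False)
        inter = sum(1 for i in draw if i in ref_idx)
        if inter >= obs.intersection:
            hits += 1
    return (1 + hits) / (n + 1)


def threshold_sweep(
    a: AdjacencyMatrix,
    reference_path,
    wgcna_cutoffs,
    ref_cutoffs,
    module_members=None,
    n_randomisations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Overlap statistics over the cross-product of query/reference cutoffs.

    Returns one row per cutoff pair with the edge counts, Jaccard, and the
    hypergeometric p-value (plus the empirical Erdos-Renyi p when
    `n_randomisations` > 0).
    """
    wgcna_cutoffs = list(wgcna_cutoffs)
    ref_cutoffs = list(ref_cutoffs)
    if not wgcna_cutoffs or not ref_cutoffs:
        raise ValueError("cutoff lists must be non-empty")
    rows = []
    for rc in ref_cutoffs:
        reference = read_reference_network(reference_path, score_cutoff=rc)
        for wc in wgcna_cutoffs:
            query = threshold_network(a, wc)
            if module_members is not None:
                query = query.subgraph([p for p in module_members if p in query]).copy()
            ov = overlap_stats(query, reference)
            row = {
                "wgcna_cutoff": wc,
                "ref_cutoff": rc,
                "shared_nodes": ov.shared_nodes,
                "q_edges": ov.q_edges,
                "r_edges": ov.r_edges,
                "intersection": ov.intersection,
                "jaccard": ov.jaccard,
                "p_hyper": ov.p_hyper,
            }
            if n_randomisations:
                row["p_empirical"] = er_randomisation_p(
                    query, reference, n=n_randomisations, seed=seed
                )
            rows.append(row)
    return pd.DataFrame(rows)
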