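"""Thresholded network analysis: MCODE dense clusters, hubs, sub-clusters.

The soft-threshold adjacency is cut at a module-specific weight (0.2-0.3 in
the study regime) to yield an export network.  On that network:

* MCODE extracts densely interconnected complexes by seeding from the
  highest-weighted vertices (weight = core number x density of the highest
  k-core of the closed neighbourhood) and growing outward while node weights
  stay within a fraction of the seed's weight.
* Hub proteins are module members whose within-module degree z-score exceeds
  2 ("two-fold greater than the SD above the mean number of interactions").
* Per-protein neighbourhoods (the protein plus its direct interactors) are
  extracted for focused inspection of individual proteins.
* The expression profiles of a cluster are partitioned by Ward hierarchical
  clustering of z-scored intensities into k sub-clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .io_ingest import ExpressionMatrix
from .module_detect import GREY, ModuleAssignment
from .netbuild import AdjacencyMatrix

__all__ = [
    "MCODEResult",
    "HubSet",
    "SubclusterResult",
    "threshold_network",
    "mcode_vertex_weights",
    "mcode_complexes",
    "hub_nodes",
    "neighbourhood",
    "ward_subclusters",
]


@dataclass
class MCODEResult:
    vertex_weight: dict[str, float]
    complexes: list[frozenset[str]]  # ranked by score, descending
    scores: list[float]  # density x size per complex
    parameters: dict[str, float] = field(default_factory=dict)


@dataclass
class HubSet:
    module: str
    degree: dict[str, int]
    z: dict[str, float]
    hubs: list[str]  # z > 2, sorted by descending z


@dataclass
class SubclusterResult:
    cluster_of: dict[str, str]  # protein -> label 'a', 'b', ... by descending size
    k: int
    linkage: str = "ward"

    def members(self, label: str) -> list[str]:
        return sorted(p for p, c in self.cluster_of.items() if c == label)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cluster_of.values():
            out[c] = out.get(c, 0) + 1
        return out


def threshold_network(a: AdjacencyMatrix, cutoff: float) -> nx.Graph:
    """Keep edges with a_ij >= cutoff; isolated nodes are retained."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    w = np.nan_to_num(a.a, nan=-np.inf)
    g = nx.Graph(threshold=cutoff)
    g.add_nodes_from(a.ids)
    ii, jj = np.where(np.triu(w >= cutoff, k=1))
    g.add_weighted_edges_from(
        (a.ids[i], a.ids[j], float(a.a[i, j])) for i, j in zip(ii, jj)
    )
    return g


def mcode_vertex_weights(g: nx.Graph) -> dict[str, float]:
    """MCODE vertex weighting on the unweighted view of the graph.

    weight(v) = k_max * density(highest k-core of N[v]), where N[v] is the
    closed neighbourhood of v and k_max its maximum core number.  Isolated
    nodes weigh 0.
    """
    weights: dict[str, float] = {}
    for v in g.nodes:
        nbhd = g.subgraph([v, *g.neighbors(v)])
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(nbhd)
        k_max = max(core.values())
        core_nodes = [u for u, k in core.items() if k >= k_max]
        weights[v] = k_max * nx.density(nbhd.subgraph(core_nodes))
    return weights


def mcode_complexes(
    g: nx.Graph,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    max_depth: int = 100,
) -> MCODEResult:
    """Seeded dense-complex extraction (plugin-default parameters).

    Unvisited vertices are taken as seeds in decreasing weight order (ties by
    node id); breadth-first expansion admits unvisited neighbours whose weight
    is >= (1 - node_score_cutoff) x the seed weight, up to `max_depth` hops.
    Complexes lacking a `k_core`-core are discarded; `haircut` trims the
    complex to its 2-core.  Complexes are ranked by density x size.
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not implemented")
    weights = mcode_vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    raw: list[set] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        floor = (1.0 - node_score_cutoff) * weights[seed]
        complex_nodes = {seed}
        frontier = [seed]
        depth = 0
        visited.add(seed)
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(g.neighbors(u), key=str):
                    if w in visited or w in complex_nodes:
                        continue
                    if weights[w] >= floor:
                        complex_nodes.add(w)
                        visited.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        raw.append(complex_nodes)

    complexes, scores = [], []
    for nodes in raw:
        sub = g.subgraph(nodes)
        core = nx.core_number(sub) if sub.number_of_edges() else {}
        if not core or max(core.values()) < k_core:
            continue
        if haircut:
            sub = nx.k_core(sub, 2)
            if sub.number_of_nodes() == 0:
                continue
        complexes.append(frozenset(sub.nodes))
        scores.append(nx.density(sub) * sub.number_of_nodes())
    ranked = sorted(
        zip(complexes, scores), key=lambda cs: (-cs[1], sorted(map(str, cs[0]))[0])
    )
    return MCODEResult(
        vertex_weight=weights,
        complexes=[c for c, _ in ranked],
        scores=[s for _, s in ranked],
        parameters={
            "node_score_cutoff": node_score_cutoff,
            "k_core": k_core,
            "haircut": haircut,
            "fluff": fluff,
            "max_depth": max_depth,
        },
    )


def hub_nodes(g: nx.Graph, m: ModuleAssignment, module: str) -> HubSet:
    """Within-module degree z-scores; hubs have z > 2.

    Degrees are counted inside the module's induced subgraph of the
    thresholded network.  A regular subgraph (degree SD = 0) has no hubs.
    """
    if module == GREY:
        raise ValueError("hubs are not defined for the grey (unassigned) module")
    members = [p for p in m.members(module) if p in g]
    if len(members) < 3:
        raise ValueError(f"module {module!r} has fewer than 3 nodes in the network")
    sub = g.subgraph(members)
    deg = {v: int(d) for v, d in sub.degree()}
    vals = np.array([deg[v] for v in members], dtype=float)
    sd = vals.std()
    if sd == 0:
        z = {v: 0.0 for v in members}
    else:
        mean = vals.mean()
        z = {v: float((deg[v] - mean) / sd) for v in members}
    hubs = sorted((v for v in members if z[v] > 2), key=lambda v: (-z[v], v))
    return HubSet(module=module, degree=deg, z=z, hubs=hubs)


def neighbourhood(g: nx.Graph, node: str) -> nx.Graph:
    """Induced subgraph on a protein and its direct interactors."""
    if node not in g:
        raise KeyError(f"node {node!r} not in graph")
    return g.subgraph([node, *g.neighbors(node)]).copy()


def ward_subclusters(x: ExpressionMatrix, members, k: int) -> SubclusterResult:
    """Ward clustering of z-scored expression profiles into k sub-clusters.

    Labels are letters a, b, c, ... assigned by decreasing sub-cluster size
    (ties by smallest member id).
    """
    members = list(members)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(members):
        raise ValueError(f"k={k} exceeds {len(members)} members")
    missing = [p for p in members if p not in set(x.protein_ids)]
    if missing:
        raise ValueError(f"unknown proteins: {missing[:5]}")
    sub = x.subset(members)
    vals = sub.values
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zs = (vals - vals.mean(axis=1, keepdims=True)) / sd
    if k == 1 or len(members) == 1:
        flat = np.ones(len(members), dtype=int)
    else:
        flat = fcluster(linkage(zs, method="ward"), t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for pid, lab in zip(members, flat):
        groups.setdefault(int(lab), []).append(pid)
    ordered = sorted(groups.values(), key=lambda c: (-len(c), min(c)))
    cluster_of = {}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", ordered):
        for p in grp:
            cluster_of[p] = letter
    return SubclusterResult(cluster_of=cluster_of, k=k)
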