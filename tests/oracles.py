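"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity from first principles (textbook formula,
exhaustive enumeration, naive loops) without touching the implementation
under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def pearson_matrix_naive(values: np.ndarray) -> np.ndarray:
    """Textbook Pearson r for every pair of rows, double loop."""
    n = values.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            x, y = values[i], values[j]
            xm, ym = x - x.mean(), y - y.mean()
            out[i, j] = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    return out


def tom_naive(a: np.ndarray) -> np.ndarray:
    """Unsigned TOM by explicit O(n^3) summation (diagonal of `a` ignored)."""
    a = a.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            denom = min(k_i, k_j) + 1.0 - a[i, j]
            out[i, j] = (l_ij + a[i, j]) / denom if denom > 0 else 0.0
    return out


def average_linkage_heights(d: np.ndarray) -> list[float]:
    """UPGMA-on-dissimilarity merge heights by naive cluster bookkeeping."""
    clusters: list[list[int]] = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            avg = float(
                np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or avg < best[0]:
                best = (avg, a, b)
        avg, a, b = best
        heights.append(avg)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def ward_heights(x: np.ndarray) -> list[float]:
    """Ward merge heights via the Lance-Williams recurrence on a naive matrix.

    Heights follow the scipy convention: sqrt of the (doubled) increase in
    within-cluster sum of squares.
    """
    n = x.shape[0]
    sizes = {i: 1 for i in range(n)}
    d2 = {}  # squared distances between current clusters
    for i, j in combinations(range(n), 2):
        d2[(i, j)] = float(((x[i] - x[j]) ** 2).sum())
    active = set(range(n))
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), best = min(
            ((k, v) for k, v in d2.items() if k[0] in active and k[1] in active),
            key=lambda kv: kv[1],
        )
        heights.append(math.sqrt(best))
        si, sj = sizes[i], sizes[j]
        for k in active - {i, j}:
            sk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            dij = best
            new = ((si + sk) * dik + (sj + sk) * djk - sk * dij) / (si + sj + sk)
            d2[tuple(sorted((nxt, k)))] = new
        sizes[nxt] = si + sj
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return heights


def bh_naive(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by the O(m^2) min-over-larger-p definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {idx: r + 1 for r, idx in enumerate(order)}
    q = []
    for i in range(m):
        vals = [
            m * p[j] / rank[j] for j in range(m) if p[j] >= p[i] or rank[j] >= rank[i]
        ]
        q.append(min(1.0, min(vals)))
    return q


def hypergeom_tail_naive(k: int, population: int, successes: int, draws: int) -> float:
    """P(X >= k) by summing the exact pmf with binomial coefficients."""
    total = 0.0
    for x in range(k, min(successes, draws) + 1):
        total += (
            math.comb(successes, x)
            * math.comb(population - successes, draws - x)
            / math.comb(population, draws)
        )
    return total


def overlap_p_enumerated(universe: int, r_edges: set, q_size: int, observed: int) -> float:
    """P(overlap >= observed) by enumerating every possible query edge set."""
    hits = 0
    total = 0
    for draw in combinations(range(universe), q_size):
        total += 1
        if len(set(draw) & r_edges) >= observed:
            hits += 1
    return hits / total


def mcode_weight_naive(adj: dict, v) -> float:
    """MCODE vertex weight by explicit k-core peeling of N[v]."""
    nodes = {v} | set(adj[v])
    edges = {
        frozenset((a, b)) for a in nodes for b in adj[a] if b in nodes and a != b
    }

    def k_core(nodes, edges, k):
        nodes, edges = set(nodes), set(edges)
        changed = True
        while changed:
            changed = False
            for u in list(nodes):
                deg = sum(1 for e in edges if u in e)
                if deg < k:
                    nodes.remove(u)
                    edges = {e for e in edges if u not in e}
                    changed = True
        return nodes, edges

    best_k, core_nodes, core_edges = 0, set(), set()
    for k in range(1, len(nodes) + 1):
        nk, ek = k_core(nodes, edges, k)
        if nk:
            best_k, core_nodes, core_edges = k, nk, ek
    if not core_nodes or len(core_nodes) < 2:
        return 0.0
    density = 2 * len(core_edges) / (len(core_nodes) * (len(core_nodes) - 1))
    return best_k * density


def fdr_counts_naive(obs: list[float], null: list[float], grid, tail: str):
    """Hand-counted FDR ratio per threshold."""
    out = []
    for t in grid:
        if tail == "negative":
            o = sum(1 for v in obs if v <= t)
            u = sum(1 for v in null if v <= t)
        else:
            o = sum(1 for v in obs if v >= t)
            u = sum(1 for v in null if v >= t)
        out.append(u / o if o else float("nan"))
    return out
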