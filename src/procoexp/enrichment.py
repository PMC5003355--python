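"""Hypergeometric term enrichment with Benjamini-Hochberg q-values.

Database-agnostic: annotations arrive as a flat protein->term TSV or a GMT
file.  Following the study design, the target set is one module's proteins
and the background is the remaining modules; the population is their union.
No ontology-graph propagation is performed — terms are tested as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentTable",
    "read_annotations",
    "hypergeometric_enrichment",
    "bh_adjust",
]


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # term, name, category, target_hits, target_size,
    #                      background_hits, background_size, p, q  (sorted by p)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def read_annotations(path) -> dict[str, set[str]]:
    """term -> protein set from a 2/3-column TSV (protein, term[, name]) or GMT."""
    terms: dict[str, set[str]] = {}
    if str(path).endswith(".gmt"):
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
        return terms
    df = pd.read_csv(path, sep="\t")
    prot_col, term_col = df.columns[0], df.columns[1]
    for prot, term in zip(df[prot_col].astype(str), df[term_col].astype(str)):
        terms.setdefault(term, set()).add(prot)
    return terms


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; always q_i >= p_i.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_enrichment(
    target,
    background,
    annotations: dict[str, set[str]],
    term_names: dict[str, str] | None = None,
    categories: dict[str, str] | None = None,
) -> EnrichmentTable:
    """Upper-tail hypergeometric enrichment of `target` vs `background`.

    The population is target | background (the two must be disjoint).  For a
    term annotating K population proteins of which k fall in the target of
    size n, p = P(X >= k) with X ~ Hypergeom(N=|population|, K, n).  Terms
    with zero target hits are skipped; q-values are BH-adjusted over the
    tested terms.
    """
    target = {str(p) for p in target}
    background = {str(p) for p in background}
    if not annotations:
        raise ValueError("empty annotation map")
    if target & background:
        raise ValueError(
            f"target and background overlap: {sorted(target & background)[:5]}"
        )
    population = target | background
    n_outside = len({p for s in annotations.values() for p in s} - population)
    if n_outside:
        warnings.warn(f"{n_outside} annotated proteins absent from the population; ignored")
    rows = []
    for term, prots in annotations.items():
        prots = {str(p) for p in prots} & population
        k = len(prots & target)
        if k == 0:
            continue
        p_val = float(stats.hypergeom.sf(k - 1, len(population), len(prots), len(target)))
        rows.append(
            {
                "term": term,
                "name": (term_names or {}).get(term, term),
                "category": (categories or {}).get(term, ""),
                "target_hits": k,
                "target_size": len(target),
                "background_hits": len(prots) - k,
                "background_size": len(background),
                "p": min(max(p_val, np.nextafter(0, 1)), 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term", "name", "category", "target_hits", "target_size",
            "background_hits", "background_size", "p",
        ],
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return EnrichmentTable(table=df)
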