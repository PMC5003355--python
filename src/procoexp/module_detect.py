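"""Module detection on the TOM dissimilarity and module-trait correlation.

Proteins are clustered by average-linkage hierarchical clustering of 1 - TOM;
branches are identified by an adaptive cut, branches below the minimum module
size fall into the grey (unassigned) module, and modules whose eigengenes are
highly correlated are merged.  Module colour labels follow the conventional
size-ranked palette (turquoise = largest, then blue, brown, yellow, ...) with
grey reserved for unassigned proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_ingest import ExpressionMatrix, TraitTable
from .netbuild import TOMMatrix

__all__ = [
    "COLOUR_SEQUENCE",
    "GREY",
    "Dendrogram",
    "ModuleAssignment",
    "EigengeneMatrix",
    "TraitCorrelationResult",
    "cluster_dendrogram",
    "cut_modules",
    "module_eigengenes",
    "module_trait_correlation",
]

GREY = "grey"
COLOUR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


@dataclass
class Dendrogram:
    """Average-linkage tree over proteins (scipy linkage matrix + leaf ids)."""

    ids: list[str]
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass
class ModuleAssignment:
    ids: list[str]
    module_of: dict[str, str]
    min_module_size: int
    merge_cut_height: float

    def members(self, colour: str) -> list[str]:
        return [p for p in self.ids if self.module_of[p] == colour]

    def colours(self, include_grey: bool = False) -> list[str]:
        """Non-grey colours in size-rank order (grey appended on request)."""
        seen = [c for c in COLOUR_SEQUENCE if any(v == c for v in self.module_of.values())]
        if include_grey and any(v == GREY for v in self.module_of.values()):
            seen.append(GREY)
        return seen

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.module_of.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein": self.ids, "module": [self.module_of[p] for p in self.ids]}
        )


@dataclass
class EigengeneMatrix:
    samples: list[str]
    eigengenes: pd.DataFrame  # samples x modules
    explained_variance: dict[str, float] = field(default_factory=dict)


@dataclass
class TraitCorrelationResult:
    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame
    n: int


def cluster_dendrogram(tom: TOMMatrix) -> Dendrogram:
    """Average-linkage hierarchical clustering of the 1 - TOM dissimilarity."""
    n = len(tom.ids)
    if n < 2:
        raise ValueError("need at least 2 proteins to cluster")
    d = tom.dissim.copy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(ids=list(tom.ids), linkage_matrix=z)


def _colour_labels(clusters: list[list[str]]) -> dict[str, str]:
    # size-rank colour assignment; ties broken by lexicographic smallest member
    order = sorted(clusters, key=lambda c: (-len(c), min(c)))
    if len(order) > len(COLOUR_SEQUENCE):
        raise ValueError(f"more than {len(COLOUR_SEQUENCE)} modules; extend the palette")
    out: dict[str, str] = {}
    for colour, members in zip(COLOUR_SEQUENCE, order):
        for p in members:
            out[p] = colour
    return out


def cut_modules(
    d: Dendrogram,
    tom: TOMMatrix,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
    expression: ExpressionMatrix | None = None,
    cut_height: float | None = None,
    kme_threshold: float = 0.5,
    reassign_iter: int = 2,
) -> ModuleAssignment:
    """Cut the dendrogram into colour-labelled modules.

    Branch identification is adaptive: candidate cut heights (quantiles of the
    dendrogram merge-height profile) are scanned; at each height, branches of
    at least `min_module_size` are kept, smaller ones go to grey, and modules
    whose eigengenes have correlation dissimilarity (1 - cor) below
    `merge_cut_height` are merged iteratively (standard eigengene merging at
    0.25).  The retained cut is the one yielding the most distinct modules
    after merging — a too-low cut fragments modules (the fragments merge
    back, but their sub-threshold pieces are lost to grey), a too-high cut
    fuses them outright — with ties broken by fewer grey proteins, then the
    lower height.  The 0.99 quantile serves as the static fallback and
    `cut_height` overrides the scan entirely.  Without `expression`,
    eigengene merging is unavailable and the scan scores unmerged branches.

    When `expression` is available, module membership is then curated by
    eigengene correlation (kME): each protein moves to the module whose
    eigengene it best correlates with in absolute value, proteins whose best
    |kME| falls below `kme_threshold` drop to grey, and modules shrinking
    below `min_module_size` dissolve (up to `reassign_iter` passes).  This
    cleans up dendrogram mis-placements that average linkage cannot resolve
    when modules are mutually (anti-)correlated.
    """
    if min_module_size < 1 or merge_cut_height < 0:
        raise ValueError("parameters must be positive")
    heights = np.sort(d.merge_heights)
    if cut_height is not None:
        candidates = [float(cut_height)]
    else:
        qs = np.quantile(heights, np.linspace(0.80, 0.998, 25))
        candidates = sorted(set(np.round(qs, 10)))
        candidates.append(float(np.quantile(heights, 0.99)))  # static fallback

    id_arr = np.array(d.ids)
    best: tuple | None = None  # (-n_modules_after_merge, n_grey, height)
    best_result: tuple[list[list[str]], list[str]] | None = None
    for h in candidates:
        flat = fcluster(d.linkage_matrix, t=h, criterion="distance")
        keep_h: list[list[str]] = []
        grey_h: list[str] = []
        for lab in np.unique(flat):
            members = id_arr[flat == lab].tolist()
            if len(members) >= min_module_size:
                keep_h.append(members)
            else:
                grey_h.extend(members)
        if expression is not None and len(keep_h) > 1:
            keep_h = _merge_close_modules(keep_h, expression, merge_cut_height)
        key = (-len(keep_h), len(grey_h), h)
        if best is None or key < best:
            best, best_result = key, (keep_h, grey_h)
    assert best_result is not None
    keep, grey = best_result

    if not keep:
        warnings.warn("no branch reached min_module_size; all proteins are grey")
        module_of = {p: GREY for p in d.ids}
        return ModuleAssignment(list(d.ids), module_of, min_module_size, merge_cut_height)

    if expression is not None and reassign_iter > 0:
        keep, grey = _kme_reassign(
            keep, list(d.ids), expression, kme_threshold, min_module_size, reassign_iter
        )

    module_of = _colour_labels(keep)
    for p in grey:
        module_of[p] = GREY
    return ModuleAssignment(list(d.ids), module_of, min_module_size, merge_cut_height)


def _kme_reassign(
    clusters: list[list[str]],
    ids: list[str],
    x: ExpressionMatrix,
    kme_threshold: float,
    min_module_size: int,
    n_iter: int,
) -> tuple[list[list[str]], list[str]]:
    """Curate membership by eigengene correlation (module membership, kME).

    Every protein — current members and grey alike — is assigned to the
    module whose eigengene it correlates with most strongly in absolute value
    (the network is unsigned), provided that |kME| reaches `kme_threshold`;
    otherwise it is grey.  Modules falling below `min_module_size` dissolve.
    Stops early once assignments are stable.
    """
    vals = x.subset(ids).values
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zs = (vals - vals.mean(axis=1, keepdims=True)) / sd
    for _ in range(n_iter):
        es = np.array([_first_pc(x.subset(c).values)[0] for c in clusters])
        ez = (es - es.mean(axis=1, keepdims=True)) / es.std(axis=1, keepdims=True)
        kme = zs @ ez.T / zs.shape[1]  # proteins x modules correlation
        best_mod = np.argmax(np.abs(kme), axis=1)
        best_kme = np.abs(kme)[np.arange(len(ids)), best_mod]
        new_clusters: list[list[str]] = [[] for _ in clusters]
        new_grey: list[str] = []
        for pid, mod, strength in zip(ids, best_mod, best_kme):
            if strength >= kme_threshold:
                new_clusters[mod].append(pid)
            else:
                new_grey.append(pid)
        kept = [c for c in new_clusters if len(c) >= min_module_size]
        for c in new_clusters:
            if 0 < len(c) < min_module_size:
                new_grey.extend(c)
        if not kept:  # refuse to dissolve everything; keep previous state
            break
        stable = sorted(map(sorted, kept)) == sorted(map(sorted, clusters))
        clusters = kept
        if stable:
            break
    assigned = {p for c in clusters for p in c}
    grey = [p for p in ids if p not in assigned]
    return clusters, grey


def _merge_close_modules(
    clusters: list[list[str]], x: ExpressionMatrix, cut: float
) -> list[list[str]]:
    """Iteratively merge the closest eigengene pair while 1 - cor < cut."""
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        es = np.array([_first_pc(x.subset(c).values)[0] for c in clusters])
        corr = np.corrcoef(es)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] >= cut:
            break
        a, b = sorted((i, j))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return clusters


def _first_pc(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector of row-standardised profiles + var share.

    Rows with zero variance carry no correlation information and are dropped.
    The eigengene is unit-normalised and sign-oriented so that its mean
    correlation with the member profiles is non-negative.
    """
    sd = values.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance proteins dropped from PCA")
        values = values[sd > 0]
        sd = sd[sd > 0]
    zs = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    e = vt[0]
    mean_profile = zs.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    explained = float(s[0] ** 2 / (s**2).sum())
    return e, explained


def module_eigengenes(x: ExpressionMatrix, m: ModuleAssignment) -> EigengeneMatrix:
    """Per-module eigengene: first PC of standardised member expression."""
    cols, ev = {}, {}
    for colour in m.colours():
        members = m.members(colour)
        if len(members) < 2:
            raise ValueError(f"module {colour!r} has fewer than 2 members")
        e, var = _first_pc(x.subset(members).values)
        cols[f"ME{colour}"] = e
        ev[colour] = var
    return EigengeneMatrix(
        samples=list(x.samples),
        eigengenes=pd.DataFrame(cols, index=list(x.samples)),
        explained_variance=ev,
    )


def module_trait_correlation(e: EigengeneMatrix, t: TraitTable) -> TraitCorrelationResult:
    """Pearson r and two-sided Student-t p per (module eigengene, trait)."""
    if list(t.samples) != list(e.samples):
        raise ValueError("trait samples do not match eigengene samples")
    n = len(e.samples)
    rows_r, rows_p = {}, {}
    for me in e.eigengenes.columns:
        rr, pp = {}, {}
        for trait in t.traits.columns:
            y = t.traits[trait].to_numpy()
            if np.std(y) == 0:
                warnings.warn(f"trait {trait!r} is constant; correlation undefined")
                rr[trait], pp[trait] = np.nan, np.nan
                continue
            res = stats.pearsonr(e.eigengenes[me].to_numpy(), y)
            rr[trait], pp[trait] = float(res.statistic), float(res.pvalue)
        rows_r[me], rows_p[me] = rr, pp
    return TraitCorrelationResult(
        r=pd.DataFrame(rows_r).T, p=pd.DataFrame(rows_p).T, n=n
    )
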