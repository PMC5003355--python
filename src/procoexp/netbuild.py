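"""Co-expression network construction.

Pairwise Pearson correlation over samples, soft-threshold adjacency
a_ij = corr(prot_i, prot_j)^beta, the scale-free topology fit used to choose
beta, and the unsigned topological overlap matrix (TOM) whose complement is
the module-detection dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_ingest import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ScaleFreeFit",
    "pairwise_correlation",
    "soft_adjacency",
    "scale_free_fit",
    "topological_overlap",
]


@dataclass
class CorrelationMatrix:
    ids: list[str]
    r: np.ndarray
    method: str = "pearson"
    zero_variance: list[str] = field(default_factory=list)


@dataclass
class AdjacencyMatrix:
    """a_ij = corr^beta.  mode='soft' (unsigned, beta>1) or 'hard' (beta=1, signed)."""

    ids: list[str]
    a: np.ndarray
    beta: int
    mode: str = "soft"

    def connectivity(self) -> np.ndarray:
        """Node connectivity k_i = sum_j a_ij with the diagonal excluded."""
        a = self.a.copy()
        np.fill_diagonal(a, 0.0)
        return a.sum(axis=1)


@dataclass
class TOMMatrix:
    ids: list[str]
    tom: np.ndarray

    @property
    def dissim(self) -> np.ndarray:
        return 1.0 - self.tom


@dataclass
class ScaleFreeFit:
    beta_grid: list[int]
    r2: list[float]  # signed R^2: negative when the log-log slope is positive
    mean_k: list[float]
    chosen_beta: int | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"beta": self.beta_grid, "signed_r2": self.r2, "mean_k": self.mean_k}
        )


def pairwise_correlation(x: ExpressionMatrix) -> CorrelationMatrix:
    """Full Pearson correlation matrix between protein intensity profiles.

    Requires arcsinh-transformed data and >= 4 samples.  Zero-variance rows
    cannot be correlated; they are flagged, their rows/columns set to NaN, and
    a warning emitted so downstream stages can exclude them.
    """
    if not x.transformed:
        raise ValueError("expression must be arcsinh-transformed first")
    if x.n_samples < 4:
        raise ValueError(f"need >= 4 samples, have {x.n_samples}")
    sd = x.values.std(axis=1)
    flat = np.where(sd == 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x.values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    zero_var = [x.protein_ids[i] for i in flat]
    if zero_var:
        r[flat, :] = np.nan
        r[:, flat] = np.nan
        warnings.warn(
            f"{len(zero_var)} zero-variance proteins excluded from correlations: "
            f"{zero_var[:5]}..."
        )
    return CorrelationMatrix(ids=list(x.protein_ids), r=r, zero_variance=zero_var)


def soft_adjacency(c: CorrelationMatrix, beta: int) -> AdjacencyMatrix:
    """Raise correlations to the power beta.

    For beta > 1 the network is unsigned: a_ij = |r_ij|^beta (identical to
    r^beta for even beta, where anti-correlation folds into positive weight).
    beta = 1 is the hard/validation case and keeps the signed correlation
    itself so positive and negative tails can be analysed separately.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if beta == 1:
        return AdjacencyMatrix(ids=list(c.ids), a=c.r.copy(), beta=1, mode="hard")
    a = np.abs(c.r) ** beta
    return AdjacencyMatrix(ids=list(c.ids), a=a, beta=beta, mode="soft")


def scale_free_fit(
    c: CorrelationMatrix,
    beta_grid=range(1, 21),
    n_bins: int = 10,
    r2_threshold: float = 0.8,
) -> ScaleFreeFit:
    """Scale-free topology fit across a grid of soft-threshold powers.

    For each beta, node connectivities k_i = sum_j |r_ij|^beta are binned into
    `n_bins` equal-count bins and log10(frequency) is regressed on
    log10(mean k per bin).  The fit index is the signed R^2 (negated when the
    slope is positive, i.e. the degree distribution is not heavy-tailed).
    `chosen_beta` is the lowest power whose signed R^2 reaches `r2_threshold`
    — the weakest soft threshold already giving a good scale-free topology.
    """
    beta_grid = list(beta_grid)
    if not beta_grid:
        raise ValueError("empty beta grid")
    r = np.nan_to_num(np.abs(c.r), nan=0.0)
    np.fill_diagonal(r, 0.0)
    r2s, mean_ks = [], []
    chosen = None
    for beta in beta_grid:
        k = (r**beta).sum(axis=1)
        r2 = _signed_scale_free_r2(k, n_bins)
        r2s.append(r2)
        mean_ks.append(float(k.mean()))
        if chosen is None and r2 >= r2_threshold:
            chosen = int(beta)
    if chosen is None:
        warnings.warn(
            f"no beta in {beta_grid[0]}..{beta_grid[-1]} reaches signed R^2 >= "
            f"{r2_threshold}; chosen_beta left unset"
        )
    return ScaleFreeFit(beta_grid=beta_grid, r2=r2s, mean_k=mean_ks, chosen_beta=chosen)


def _signed_scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    # equal-width bins over k; equal-count bins would make every bin
    # frequency identical by construction and the regression degenerate
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    occupied = [b for b in range(n_bins) if (idx == b).any()]
    mean_k = np.array([k[idx == b].mean() for b in occupied])
    p = np.array([(idx == b).sum() for b in occupied]) / k.size
    if mean_k.size < 3:
        return 0.0
    fit = stats.linregress(np.log10(mean_k), np.log10(p))
    r2 = float(fit.rvalue**2)
    return -r2 if fit.slope > 0 else r2


def topological_overlap(a: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap matrix.

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu (diagonal treated as 0,
    which also removes the u = i, j terms from l_ij).  Two proteins overlap
    strongly when they are directly connected *and* share neighbours.  The
    diagonal is 1; an isolated pair (k_i = k_j = a_ij = 0) has TOM = 0.
    """
    if a.mode != "soft":
        raise ValueError("TOM requires a soft (unsigned) adjacency")
    w = np.nan_to_num(a.a, nan=0.0).astype(float).copy()
    np.fill_diagonal(w, 0.0)
    k = w.sum(axis=1)
    l = w @ w
    denom = np.minimum.outer(k, k) + 1.0 - w
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + w) / denom
    tom[denom == 0] = 0.0
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrise away float drift
    return TOMMatrix(ids=list(a.ids), tom=tom)
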