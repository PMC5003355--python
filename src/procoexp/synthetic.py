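"""Synthetic expression data with planted co-expression modules.

Emulates the statistical regime of a small two-group label-free proteomics
study: ~800 proteins quantified in 12 samples (6 control, 6 tumour), a handful
of co-expression modules whose summary profiles (eigengenes) correlate with
disease state with either sign, a background of unassigned proteins, and a few
high-loading hub proteins per module.  Ground truth is returned alongside the
data so module/hub/trait recovery can be scored.

The generative model per module m:

    eigengene_m = r_m * z(state) + sqrt(1 - r_m^2) * z(noise ⟂ state)
    profile_i   = mu_i + loading_i * eigengene_m + eps_i,   eps ~ N(0, noise_sd)

so the sample Pearson correlation between eigengene and state equals r_m
exactly by construction (no rejection sampling — exact control matters at
n = 12).  Background proteins are pure noise around their baseline.  Values
are generated directly on the arcsinh (log-like) scale where the analysis
computes correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_ingest import ExpressionMatrix, TraitTable
import pandas as pd

__all__ = ["SyntheticTruth", "simulate_dataset", "DEFAULT_MODULE_SIZES", "DEFAULT_TRAIT_CORRS"]

# Study-regime geometry: 12 samples (6/6), ~800 proteins, four real modules.
# Trait correlations: one strongly anti-correlated large module, a second
# less-pronounced anti-correlated module, one strongly positively correlated
# module, and one trait-neutral module.
DEFAULT_MODULE_SIZES = (272, 256, 177, 76)
DEFAULT_TRAIT_CORRS = (-0.90, -0.80, 0.93, 0.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a simulated dataset.

    module_of maps protein id -> planted module index (int) or -1 for
    background; eigengene_trait_corr maps module index -> the planted Pearson
    correlation between that module's eigengene and disease state.
    """

    module_of: dict[str, int]
    eigengene_trait_corr: dict[int, float]
    hub_ids: frozenset[str]
    eigengenes: np.ndarray  # (n_modules, n_samples)
    loadings: dict[str, float]
    seed: int

    def labels(self, protein_ids) -> np.ndarray:
        return np.array([self.module_of[p] for p in protein_ids])


def _standardise(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def simulate_dataset(
    n_proteins: int = 800,
    n_samples: int = 12,
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES,
    trait_corrs: tuple[float, ...] = DEFAULT_TRAIT_CORRS,
    loading_range: tuple[float, float] = (0.5, 0.95),
    noise_sd: float = 0.4,
    hubs_per_module: int = 3,
    hub_noise_factor: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TraitTable, SyntheticTruth]:
    """Generate (expression, traits, truth) with planted module structure.

    Samples split into two equal groups (state 0 then state 1).  Module
    members load on their module eigengene with loadings drawn uniformly from
    `loading_range`; the first `hubs_per_module` members of each module are
    hubs and receive the top loading of the range.  `noise_sd` is the SD of
    the additive Gaussian noise on the arcsinh scale; the default 0.4 against
    loadings 0.5-0.95 puts pairwise correlations roughly in the ±0.5-0.8
    band of tight proteomic co-expression structure while keeping planted
    modules statistically recoverable at n = 12 even though their eigengenes
    are strongly mutually (anti-)correlated through the shared trait.
    """
    if n_samples % 2 or n_samples < 4:
        raise ValueError("n_samples must be even and >= 4")
    if len(trait_corrs) != len(module_sizes):
        raise ValueError("need one trait correlation per module")
    if sum(module_sizes) > n_proteins:
        raise ValueError("module sizes exceed n_proteins")
    if any(s < 2 for s in module_sizes):
        raise ValueError("module size must be >= 2")
    if any(abs(r) > 1 for r in trait_corrs):
        raise ValueError("trait correlations must lie in [-1, 1]")

    rng = np.random.default_rng(seed)
    half = n_samples // 2
    state = np.r_[np.zeros(half), np.ones(half)]
    z_state = _standardise(state)

    # Eigengenes with exact sample correlation to state: mix the standardised
    # state vector with a module-specific component orthogonal to state AND to
    # the other modules' components (Gram-Schmidt).  Mutual orthogonality makes
    # the between-module eigengene correlation exactly r_m * r_m' — modules
    # share no variation beyond the trait — so module separation is a
    # controlled property of the planted trait correlations, not of chance
    # overlap among random vectors at small n.
    if len(module_sizes) + 2 > n_samples:
        raise ValueError("need n_samples >= n_modules + 2 for orthogonal eigengenes")
    basis = [np.ones(n_samples) / np.sqrt(n_samples), z_state / np.linalg.norm(z_state)]
    eigengenes = np.empty((len(module_sizes), n_samples))
    for m, r in enumerate(trait_corrs):
        g = rng.standard_normal(n_samples)
        for b in basis:
            g -= (g @ b) * b
        basis.append(g / np.linalg.norm(g))
        eigengenes[m] = r * z_state + np.sqrt(1.0 - r * r) * _standardise(g)

    lo, hi = loading_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("loading_range must lie in (0, 1]")
    # Hubs are defined by elevated loadings: they sit at the top of the range
    # while regular members span its lower three quarters, so hub membership
    # is a property of the planted geometry rather than of sampling luck.
    member_hi = lo + 0.75 * (hi - lo)

    ids = [f"P{i:04d}" for i in range(n_proteins)]
    module_of: dict[str, int] = {}
    loadings: dict[str, float] = {}
    hubs: set[str] = set()
    values = np.empty((n_proteins, n_samples))
    baselines = rng.uniform(6.0, 10.0, size=n_proteins)  # arcsinh-scale intensity level

    row = 0
    for m, size in enumerate(module_sizes):
        for j in range(size):
            pid = ids[row]
            module_of[pid] = m
            if j < hubs_per_module:
                # Hubs carry the module signal most faithfully: top loading
                # and reduced residual noise (near-unit module membership).
                # Loading alone cannot make connectivity rankings robust at
                # n = 12 because cor(profile, eigengene) = l / sqrt(l^2 + s^2)
                # saturates near the top of the loading range.
                load, s = hi, noise_sd * hub_noise_factor
                hubs.add(pid)
            else:
                load, s = rng.uniform(lo, member_hi), noise_sd
            loadings[pid] = load
            values[row] = baselines[row] + load * eigengenes[m] \
                + rng.standard_normal(n_samples) * s
            row += 1
    for i in range(row, n_proteins):  # background: pure noise, zero loading
        pid = ids[i]
        module_of[pid] = -1
        loadings[pid] = 0.0
        values[i] = baselines[i] + rng.standard_normal(n_samples) * noise_sd

    samples = [f"Ct{i + 1}" for i in range(half)] + [f"Tu{i + 1}" for i in range(half)]
    expr = ExpressionMatrix(
        protein_ids=ids,
        samples=samples,
        values=values,
        transformed=True,
        group=["control"] * half + ["tumour"] * half,
    )
    traits = TraitTable(
        samples=samples,
        traits=pd.DataFrame(
            {
                "state": state,
                "age": np.round(rng.uniform(40, 75, n_samples)),
                "gender": rng.integers(0, 2, n_samples).astype(float),
            },
            index=samples,
        ),
    )
    truth = SyntheticTruth(
        module_of=module_of,
        eigengene_trait_corr={m: r for m, r in enumerate(trait_corrs)},
        hub_ids=frozenset(hubs),
        eigengenes=eigengenes,
        loadings=loadings,
        seed=seed,
    )
    return expr, traits, truth


def write_dataset(expr: ExpressionMatrix, traits: TraitTable, out_dir) -> dict[str, str]:
    """Write a simulated dataset as the raw-scale TSVs the ingest step reads.

    The generator works on the arcsinh scale; on disk we store sinh(values) so
    a round trip through ingest + arcsinh reproduces the simulated matrix.
    """
    import os

    from .io_ingest import write_expression

    os.makedirs(out_dir, exist_ok=True)
    raw = ExpressionMatrix(
        protein_ids=expr.protein_ids,
        samples=expr.samples,
        values=np.sinh(expr.values),
        transformed=False,
        gene_symbols=expr.gene_symbols,
        group=expr.group,
    )
    epath = os.path.join(out_dir, "expression.tsv")
    tpath = os.path.join(out_dir, "traits.tsv")
    write_expression(raw, epath)
    tdf = traits.traits.copy()
    tdf.index.name = "sample"
    tdf.to_csv(tpath, sep="\t")
    return {"expression": epath, "traits": tpath}
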