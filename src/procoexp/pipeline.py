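"""End-to-end orchestration of the co-expression workflow.

ingest -> arcsinh -> correlation -> (optional) soft-power selection ->
adjacency -> TOM -> modules -> eigengenes -> trait correlation -> permutation
FDR -> per-module network/MCODE/hubs/sub-clusters -> reference-network
comparison -> enrichment, with every artefact written into one run directory
and a machine-readable summary.  Identical config + seed gives an identical
summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import fdr_calibration as fdrc
from . import graph_analysis as ga
from . import module_detect as md
from . import net_compare as nc
from . import netbuild as nb
from .enrichment import hypergeometric_enrichment, read_annotations
from .io_ingest import (
    ExpressionMatrix,
    TraitTable,
    arcsinh_transform,
    read_expression,
    read_traits,
    write_graph,
)

log = logging.getLogger("procoexp")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat run configuration; serialised verbatim into the output directory."""

    expression: str | None = None
    traits: str | None = None
    reference_network: str | None = None
    annotations: str | None = None
    out_dir: str = "procoexp_run"
    beta: int = 10
    pick_beta: bool = False
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    network_cutoff: float = 0.2
    module_cutoffs: dict[str, float] = field(default_factory=dict)
    fdr_target: float = 0.05
    n_permutations: int = 10
    mcode_node_score_cutoff: float = 0.2
    subcluster_k: int = 5
    ref_score_cutoff: float = 0.4
    n_randomisations: int = 0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(
    cfg: RunConfig,
    expression: ExpressionMatrix | None = None,
    traits: TraitTable | None = None,
) -> dict:
    """Run the full workflow; returns the summary dict (also written as JSON).

    `expression` / `traits` may be passed in-memory (e.g. straight from the
    simulator, already transformed); otherwise they are read from the
    configured paths and the arcsinh transform is applied.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    cfg.dump(os.path.join(out, "config.yaml"))
    stage = "ingest"
    try:
        if expression is None:
            expression = read_expression(cfg.expression)
        if not expression.transformed:
            expression = arcsinh_transform(expression)
        if traits is None and cfg.traits:
            traits = read_traits(cfg.traits, expression=expression)
        log.info("ingest: %d proteins x %d samples", expression.n_proteins, expression.n_samples)

        stage = "netbuild"
        corr = nb.pairwise_correlation(expression)
        beta = cfg.beta
        sf = nb.scale_free_fit(corr, beta_grid=cfg.beta_grid)
        sf.to_frame().to_csv(os.path.join(out, "scale_free_fit.tsv"), sep="\t", index=False)
        if cfg.pick_beta and sf.chosen_beta is not None:
            beta = sf.chosen_beta
        adj = nb.soft_adjacency(corr, beta)
        tom = nb.topological_overlap(adj)

        stage = "module_detect"
        dend = md.cluster_dendrogram(tom)
        modules = md.cut_modules(
            dend,
            tom,
            min_module_size=cfg.min_module_size,
            merge_cut_height=cfg.merge_cut_height,
            expression=expression,
        )
        eig = md.module_eigengenes(expression, modules)
        eig.eigengenes.to_csv(os.path.join(out, "eigengenes.tsv"), sep="\t")
        trait_corr = None
        if traits is not None:
            trait_corr = md.module_trait_correlation(eig, traits)
            trait_corr.r.to_csv(os.path.join(out, "module_trait_r.tsv"), sep="\t")
            trait_corr.p.to_csv(os.path.join(out, "module_trait_p.tsv"), sep="\t")

        stage = "fdr_calibration"
        thresholds = {}
        for label, b, tail in [
            ("beta1_positive", 1, "positive"),
            ("beta1_negative", 1, "negative"),
            (f"beta{beta}_adjacency", beta, "adjacency"),
        ]:
            curve = fdrc.build_fdr_curve(
                expression, beta=b, tail=tail,
                n_permutations=cfg.n_permutations, seed=cfg.seed,
            )
            curve.to_frame().to_csv(
                os.path.join(out, f"fdr_curve_{label}.tsv"), sep="\t", index=False
            )
            thresholds[label] = fdrc.threshold_at_fdr(curve, cfg.fdr_target)

        stage = "graph_analysis"
        module_report = {}
        conn = adj.connectivity()
        conn_of = dict(zip(adj.ids, conn))
        module_df = modules.to_frame()
        for colour in modules.colours():
            cut = cfg.module_cutoffs.get(colour, cfg.network_cutoff)
            g_full = ga.threshold_network(adj, cut)
            members = modules.members(colour)
            sub = g_full.subgraph(members).copy()
            write_graph(sub, os.path.join(out, f"network_{colour}.graphml"))
            write_graph(sub, os.path.join(out, f"network_{colour}_edges.tsv"), fmt="tsv")
            mc = ga.mcode_complexes(sub, node_score_cutoff=cfg.mcode_node_score_cutoff)
            hubs = ga.hub_nodes(g_full, modules, colour) if len(members) >= 3 else None
            main = max(mc.complexes, key=len) if mc.complexes else frozenset()
            subc = None
            if main and cfg.subcluster_k and len(main) >= cfg.subcluster_k:
                subc = ga.ward_subclusters(expression, sorted(main), k=cfg.subcluster_k)
            module_report[colour] = {
                "size": len(members),
                "cutoff": cut,
                "n_edges": sub.number_of_edges(),
                "n_complexes": len(mc.complexes),
                "main_complex_size": len(main),
                "hubs": hubs.hubs if hubs else [],
                "subcluster_sizes": sorted(subc.sizes().values(), reverse=True) if subc else [],
            }
            with open(os.path.join(out, f"complexes_{colour}.tsv"), "w") as fh:
                fh.write("complex\tscore\tproteins\n")
                for i, (cx, sc) in enumerate(zip(mc.complexes, mc.scores), 1):
                    fh.write(f"{i}\t{sc:.6g}\t{','.join(sorted(cx))}\n")
            if hubs:
                with open(os.path.join(out, f"hubs_{colour}.tsv"), "w") as fh:
                    fh.write("protein\tdegree\tz\n")
                    for p in sorted(hubs.z, key=lambda v: (-hubs.z[v], v)):
                        fh.write(f"{p}\t{hubs.degree[p]}\t{hubs.z[p]:.6g}\n")
        module_df["connectivity"] = [conn_of[p] for p in module_df["protein"]]
        module_df.to_csv(os.path.join(out, "modules.tsv"), sep="\t", index=False)

        stage = "net_compare"
        comparison = None
        if cfg.reference_network:
            comparison = nc.threshold_sweep(
                adj,
                cfg.reference_network,
                wgcna_cutoffs=[cfg.network_cutoff],
                ref_cutoffs=[cfg.ref_score_cutoff],
                n_randomisations=cfg.n_randomisations,
                seed=cfg.seed,
            )
            comparison.to_csv(os.path.join(out, "network_overlap.tsv"), sep="\t", index=False)

        stage = "enrichment"
        if cfg.annotations:
            ann = read_annotations(cfg.annotations)
            all_assigned = [p for p in modules.ids if modules.module_of[p] != md.GREY]
            for colour in modules.colours():
                members = set(modules.members(colour))
                rest = [p for p in all_assigned if p not in members]
                et = hypergeometric_enrichment(members, rest, ann)
                et.table.to_csv(
                    os.path.join(out, f"enrichment_{colour}.tsv"), sep="\t", index=False
                )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    summary = {
        "n_proteins": expression.n_proteins,
        "n_samples": expression.n_samples,
        "beta": int(beta),
        "chosen_beta": sf.chosen_beta,
        "n_modules": len(modules.colours()),
        "module_sizes": {c: len(modules.members(c)) for c in modules.colours(include_grey=True)},
        "fdr_thresholds": thresholds,
        "modules": module_report,
        "seed": cfg.seed,
    }
    if trait_corr is not None:
        summary["trait_state_r"] = {
            me: (None if not np.isfinite(v) else float(v))
            for me, v in trait_corr.r["state"].items()
        }
    if comparison is not None:
        summary["overlap_jaccard"] = float(comparison["jaccard"].iloc[0])
        summary["overlap_p_hyper"] = float(comparison["p_hyper"].iloc[0])
    summary = _round_floats(summary)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
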