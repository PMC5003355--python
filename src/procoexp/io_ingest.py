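"""Tabular and graph I/O plus the arcsinh intensity transform.

The pipeline's substrate is a wide intensity table (proteins x samples,
label-free quantitation), a per-sample trait table (disease state 0/1 plus
covariates), and a reference protein-protein interaction network given as a
scored edge list (STRING-export style).  Intensities are arcsinh-transformed
before any correlation is computed: arcsinh behaves like a log for large
values but is defined (and zero) at zero intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "read_expression",
    "write_expression",
    "arcsinh_transform",
    "read_traits",
    "read_reference_network",
    "write_graph",
]


@dataclass
class ExpressionMatrix:
    """Proteins x samples intensity matrix.

    Parameters
    ----------
    protein_ids : list of str
        Unique protein identifiers (row order).
    samples : list of str
        Sample names (column order).
    values : ndarray of shape (n_proteins, n_samples)
        Raw non-negative intensities, or reals after transformation.
    transformed : bool
        Whether :func:`arcsinh_transform` has been applied.
    gene_symbols : list of str, optional
        Parallel gene symbols; defaults to the protein ids.
    group : list of str, optional
        Per-sample group label (e.g. ``control`` / ``tumour``).
    """

    protein_ids: list[str]
    samples: list[str]
    values: np.ndarray
    transformed: bool = False
    gene_symbols: list[str] | None = None
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.samples)} samples"
            )
        dups = _duplicates(self.protein_ids)
        if dups:
            raise ValueError(f"duplicate protein ids: {sorted(dups)}")
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample names")
        if not np.isfinite(self.values).any(axis=1).all():
            bad = [self.protein_ids[i] for i in
                   np.where(~np.isfinite(self.values).any(axis=1))[0]]
            raise ValueError(f"rows with no finite value: {bad}")
        if np.isnan(self.values).any():
            r, c = map(int, next(zip(*np.where(np.isnan(self.values)))))
            raise ValueError(
                f"missing intensity at protein {self.protein_ids[r]!r}, "
                f"sample {self.samples[c]!r}; missing values are not supported"
            )

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def symbols(self) -> list[str]:
        return self.gene_symbols if self.gene_symbols is not None else self.protein_ids

    def subset(self, protein_ids) -> "ExpressionMatrix":
        """Row-subset preserving the stored order of `protein_ids`."""
        index = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [index[p] for p in protein_ids]
        sym = self.gene_symbols
        return replace(
            self,
            protein_ids=list(protein_ids),
            values=self.values[rows],
            gene_symbols=[sym[i] for i in rows] if sym is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.samples)


@dataclass
class TraitTable:
    """Per-sample numeric traits; `state` is the binary disease indicator."""

    samples: list[str]
    traits: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.traits = self.traits.astype(float)
        if list(self.traits.index) != list(self.samples):
            self.traits = self.traits.loc[list(self.samples)]
        if "state" in self.traits.columns:
            state = self.traits["state"]
            if not state.isin([0.0, 1.0]).all():
                bad = sorted(state[~state.isin([0.0, 1.0])].unique())
                raise ValueError(f"state must be 0/1, found {bad}")

    @property
    def state(self) -> np.ndarray:
        return self.traits["state"].to_numpy()

    def group_labels(self) -> list[str]:
        return ["tumour" if s else "control" for s in self.state]


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _read_table(path, dialect: str | None) -> pd.DataFrame:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    return pd.read_csv(path, sep=sep)


def read_expression(
    path,
    dialect: str | None = None,
    id_col: str | None = None,
    symbol_col: str | None = None,
    min_peptides_col: str | None = None,
    min_peptides: int = 2,
) -> ExpressionMatrix:
    """Read a wide intensity table into an :class:`ExpressionMatrix`.

    The first column (or `id_col`) holds protein identifiers; every remaining
    column except `symbol_col` / `min_peptides_col` is a sample.  When
    `min_peptides_col` is given, rows quantified with fewer than
    `min_peptides` peptides are dropped (the usual >=2-peptide identification
    filter).
    """
    df = _read_table(path, dialect)
    if id_col is None:
        id_col = df.columns[0]
    dups = _duplicates(df[id_col].astype(str))
    if dups:
        raise ValueError(f"duplicate protein ids in {path}: {sorted(dups)}")
    if min_peptides_col is not None:
        df = df[pd.to_numeric(df[min_peptides_col]) >= min_peptides]
    meta = [id_col] + [c for c in (symbol_col, min_peptides_col) if c is not None]
    sample_cols = [c for c in df.columns if c not in meta]
    block = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if block.isna().any().any():
        r = block.isna().any(axis=1).idxmax()
        c = block.columns[block.loc[r].isna().to_numpy().argmax()]
        raise ValueError(
            f"non-numeric or missing cell at protein "
            f"{df.loc[r, id_col]!r}, sample {c!r}"
        )
    return ExpressionMatrix(
        protein_ids=df[id_col].astype(str).tolist(),
        samples=list(sample_cols),
        values=block.to_numpy(dtype=float),
        transformed=False,
        gene_symbols=df[symbol_col].astype(str).tolist() if symbol_col else None,
    )


def write_expression(x: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = x.to_frame()
    df.index.name = "protein"
    df.to_csv(path, sep=sep, float_format="%.17g")


def arcsinh_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Apply v -> ln(v + sqrt(v^2 + 1)) elementwise.

    A log-like variance-stabilising transform that, unlike log, is defined at
    zero intensity (arcsinh(0) = 0).  Guards against double application.
    """
    if x.transformed:
        raise ValueError("matrix is already arcsinh-transformed")
    return replace(x, values=np.arcsinh(x.values), transformed=True)


def read_traits(
    path,
    expression: ExpressionMatrix | None = None,
    dialect: str | None = None,
    sample_col: str | None = None,
    on_reorder: str = "reorder",
) -> TraitTable:
    """Read the per-sample trait table; sample order follows the expression file.

    `on_reorder`: ``"reorder"`` silently aligns (with a warning) a trait table
    whose rows are a permutation of the expression samples; ``"error"`` rejects
    any order mismatch.
    """
    df = _read_table(path, dialect)
    if sample_col is None:
        sample_col = df.columns[0]
    df = df.set_index(df[sample_col].astype(str)).drop(columns=[sample_col])
    samples = list(df.index)
    if expression is not None:
        missing = [s for s in expression.samples if s not in samples]
        extra = [s for s in samples if s not in expression.samples]
        if missing or extra:
            raise ValueError(
                f"trait/expression sample mismatch; missing={missing} extra={extra}"
            )
        if samples != list(expression.samples):
            if on_reorder == "error":
                raise ValueError("trait table sample order differs from expression")
            warnings.warn("trait table reordered to match expression sample order")
            samples = list(expression.samples)
            df = df.loc[samples]
    return TraitTable(samples=samples, traits=df)


def read_reference_network(path, score_cutoff: float = 0.4) -> nx.Graph:
    """Read a 3-column (nodeA, nodeB, score) edge list into an undirected graph.

    Scores on a 0-1000 scale (STRING export) are auto-detected and rescaled to
    0-1.  Self-loops are dropped; duplicate edges collapse keeping the maximum
    score; only edges with score >= `score_cutoff` are kept, but every node
    seen in the file is retained.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            if lineno == 1 and len(parts) >= 3:
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header row
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: unparsable score {parts[2]!r}") from e
            rows.append((parts[0].strip(), parts[1].strip(), score))
    if rows:
        max_score = max(s for _, _, s in rows)
        if max_score > 1.0:  # STRING 0-1000 combined-score convention
            rows = [(a, b, s / 1000.0) for a, b, s in rows]
    g = nx.Graph()
    for a, b, s in rows:
        g.add_nodes_from((a, b))
        if a == b:
            continue
        if g.has_edge(a, b):
            s = max(s, g[a][b]["weight"])
            g[a][b]["weight"] = s
        elif s >= score_cutoff:
            g.add_edge(a, b, weight=s)
    # collapsing duplicates may have raised a sub-cutoff edge above it; redo filter
    drop = [(a, b) for a, b, w in g.edges(data="weight") if w < score_cutoff]
    g.remove_edges_from(drop)
    return g


def write_graph(g: nx.Graph, path, fmt: str | None = None) -> None:
    """Export a graph as GraphML or a 3-column TSV edge list (Cytoscape-ready)."""
    if fmt is None:
        fmt = "graphml" if str(path).endswith(".graphml") else "tsv"
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("nodeA\tnodeB\tweight\n")
            for a, b, w in sorted(g.edges(data="weight", default=1.0)):
                fh.write(f"{a}\t{b}\t{w:.6g}\n")
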