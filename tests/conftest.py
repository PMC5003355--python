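import numpy as np
import pytest

from procoexp import (
    ExpressionMatrix,
    cluster_dendrogram,
    cut_modules,
    pairwise_correlation,
    simulate_dataset,
    soft_adjacency,
    topological_overlap,
)

RECOVERY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def default_sims():
    """Five study-regime simulations (800 proteins, 12 samples, 4 modules)."""
    return [simulate_dataset(seed=s) for s in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def recovered_modules(default_sims):
    """Full network -> TOM -> module detection on each default simulation."""
    out = []
    for expr, traits, truth in default_sims:
        adj = soft_adjacency(pairwise_correlation(expr), 10)
        tom = topological_overlap(adj)
        assign = cut_modules(cluster_dendrogram(tom), tom, expression=expr)
        out.append((expr, traits, truth, adj, assign))
    return out


@pytest.fixture
def toy_expression():
    """3 proteins x 4 samples, transformed, hand-enterable values."""
    return ExpressionMatrix(
        protein_ids=["A", "B", "C"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 3.0, 2.0, 5.0]]
        ),
        transformed=True,
    )
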