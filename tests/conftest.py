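import numpy as np
import pandas as pd
import pytest

from fcmediation.config import CohortConfig
from fcmediation.cohort import (
    generate_beliefs,
    generate_covariates,
    generate_mediator_matrix_mode,
    generate_task_scores,
    mediator_column,
)
from fcmediation.connectivity import AdjacencyMatrix, ConnectivityMatrix


def make_adjacency(weights) -> AdjacencyMatrix:
    w = np.asarray(weights, dtype=float)
    return AdjacencyMatrix(
        parcel_ids=[f"p{i:04d}" for i in range(w.shape[0])],
        weights=w,
        threshold_used=0.0,
    )


def make_connectivity(values, method="peak_crosscorr") -> ConnectivityMatrix:
    v = np.asarray(values, dtype=float)
    return ConnectivityMatrix(
        parcel_ids=[f"p{i:04d}" for i in range(v.shape[0])], values=v, method=method
    )


def matrix_cohort(n: int, seed: int, **overrides) -> tuple[pd.DataFrame, CohortConfig]:
    """Matrix-mode cohort (mediator emitted directly) with planted effects."""
    cfg = CohortConfig(n_subjects=n, seed=seed, **overrides).validate()
    df = generate_covariates(cfg)
    df = generate_beliefs(df, cfg)
    df = generate_mediator_matrix_mode(df, cfg)
    df = generate_task_scores(df, df[mediator_column(cfg)].to_numpy(), cfg)
    return df, cfg


@pytest.fixture(scope="session")
def medium_cohort():
    """One n=2000 cohort with the default planted structure, shared by tests."""
    return matrix_cohort(2000, seed=424242)


@pytest.fixture(scope="session")
def graph_ensemble():
    """Seeded ensemble of small weighted/binary graphs (<= 8 nodes)."""
    rng = np.random.default_rng(20240901)
    graphs = []
    for n in (3, 4, 5, 6, 7, 8):
        for _ in range(3):
            # random binary graph, edge prob 0.45, at least one edge
            while True:
                b = (rng.random((n, n)) < 0.45).astype(float)
                b = np.triu(b, 1)
                b = b + b.T
                if b.sum() > 0:
                    break
            graphs.append(b)
            # weighted variant with positive weights on the same support
            w = b * rng.uniform(0.2, 1.0, size=(n, n))
            w = np.triu(w, 1)
            graphs.append(w + w.T)
    # planted two-block graphs
    for n, k in ((6, 3), (8, 4)):
        b = np.zeros((n, n))
        b[:k, :k] = 1.0
        b[k:, k:] = 1.0
        np.fill_diagonal(b, 0.0)
        b[0, k] = b[k, 0] = 1.0
        graphs.append(b)
    return graphs
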