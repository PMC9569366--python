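"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by a route different from the library
implementation (relaxation instead of Dijkstra, exhaustive enumeration
instead of heuristics, matrix exponentials or power iteration instead of
eigvalsh), so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def bellman_ford_distances(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by repeated edge relaxation."""
    n = lengths.shape[0]
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for _ in range(n):
        for k in range(n):
            d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def efficiency_oracle(weights: np.ndarray) -> float:
    n = weights.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), 0.0)
    d = bellman_ford_distances(lengths)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def transitivity_oracle(binary: np.ndarray) -> float:
    """Transitivity as closed ordered triples / connected ordered triples."""
    n = binary.shape[0]
    closed = 0
    total = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i != j and j != k and i != k and binary[i, j] and binary[j, k]:
                    total += 1
                    if binary[i, k]:
                        closed += 1
    if total == 0:
        return float("nan")
    return closed / total


def _restricted_growth_strings(n: int):
    """All set partitions of range(n) as label vectors (RGS enumeration)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, maxl: int):
        if i == n:
            yield labels.copy()
            return
        for l in range(maxl + 2):
            labels[i] = l
            yield from rec(i + 1, max(maxl, l))

    if n == 0:
        return
    yield from rec(1, 0)


def modularity_oracle(weights: np.ndarray) -> float:
    """Maximum weighted Newman-Girvan Q by exhaustive partition search."""
    two_m = weights.sum()
    deg = weights.sum(axis=1)
    best = -np.inf
    for labels in _restricted_growth_strings(weights.shape[0]):
        same = labels[:, None] == labels[None, :]
        q = (weights[same].sum() / two_m) - sum(
            (deg[labels == c].sum() / two_m) ** 2 for c in np.unique(labels)
        )
        best = max(best, q)
    return float(best)


def natural_connectivity_oracle(weights: np.ndarray) -> float:
    """ln(trace(expm(A))/N) via the dense matrix exponential."""
    n = weights.shape[0]
    return float(np.log(np.trace(expm(weights)) / n))


def lambda_max_oracle(weights: np.ndarray, iters: int = 20000) -> float:
    """Largest eigenvalue by shifted power iteration."""
    n = weights.shape[0]
    shift = np.abs(weights).sum() + 1.0
    m = weights + shift * np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        w = m @ v
        v = w / np.linalg.norm(w)
    return float(v @ weights @ v)


def centrality_oracle(weights: np.ndarray, iters: int = 20000) -> np.ndarray:
    """Unit-maximum principal eigenvector by shifted power iteration."""
    n = weights.shape[0]
    shift = np.abs(weights).sum() + 1.0
    m = weights + shift * np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        w = m @ v
        v = w / np.linalg.norm(w)
    v = np.abs(v)
    return v / v.max()


def median_oracle(values) -> float:
    """Sort-based median independent of numpy's."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else 0.5 * (v[mid - 1] + v[mid])


def bh_oracle(pvalues) -> np.ndarray:
    """Hand step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def bootstrap_indirect(table, belief, med_col, score, covs, n_boot=1000, seed=0):
    """Nonparametric bootstrap of the indirect effect a*b (OLS refits)."""
    import pandas as pd
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    df = table.reset_index(drop=True)
    n = len(df)

    def fit_ab(d):
        def z(c):
            x = d[c].astype(float).to_numpy()
            return (x - x.mean()) / x.std(ddof=0)

        xb = sm.add_constant(
            np.column_stack([z(belief)] + [z(c) for c in covs]), prepend=True
        )
        a = np.linalg.lstsq(xb, z(med_col), rcond=None)[0][1]
        xd = sm.add_constant(
            np.column_stack([z(med_col), z(belief)] + [z(c) for c in covs]),
            prepend=True,
        )
        b = np.linalg.lstsq(xd, z(score), rcond=None)[0][1]
        return a * b

    draws = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        draws[k] = fit_ab(df.iloc[idx])
    return draws
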