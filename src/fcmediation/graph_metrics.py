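"""Global and local topological properties of thresholded brain graphs.

Metrics follow the conventions of the common brain-connectivity toolboxes:

* global efficiency — mean inverse shortest-path length; weighted paths use
  edge lengths 1/weight, unreachable pairs contribute 0;
* clustering — transitivity / local triangle density on the binary view
  (weighted geometric-mean variant behind a flag);
* modularity — weighted Newman-Girvan Q; exact exhaustive optimization for
  graphs with <= 8 nodes, seeded Louvain above;
* small-worldness — sigma = (C/C_rand)/(L/L_rand) against degree-preserving
  rewired (Maslov-Sneppen) nulls;
* natural connectivity — ln of the mean exponentiated adjacency eigenvalue
  (a spectral robustness index);
* spectral stability — the largest adjacency eigenvalue;
* node metrics — eigenvector centrality (unit-maximum), degree, local
  clustering.

Undefined quantities (empty scopes, edgeless graphs) are reported as NaN,
never as silent zeros.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.special import logsumexp

from .connectivity import AdjacencyMatrix, ConnectivityMatrix

UNDEFINED = float("nan")


def _weights(adj: AdjacencyMatrix, view: str) -> np.ndarray:
    if view == "weighted":
        return adj.weights
    if view == "binary":
        return adj.binarized_view.astype(float)
    raise ValueError(f"unknown view {view!r}")


def to_graph(adj: AdjacencyMatrix, view: str = "weighted") -> nx.Graph:
    w = _weights(adj, view)
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from((int(i), int(j), float(w[i, j])) for i, j in zip(ii, jj))
    return g


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

def global_efficiency(adj: AdjacencyMatrix, view: str = "weighted") -> float:
    """Mean over ordered node pairs of 1/d(i,j); unreachable pairs add 0."""
    w = _weights(adj, view)
    n = w.shape[0]
    if n < 2:
        return UNDEFINED
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    d = shortest_path(lengths, method="D", directed=False)
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_clustering(adj: AdjacencyMatrix) -> float:
    """Transitivity: 3 * triangles / connected triples, on the binary view."""
    b = adj.binarized_view.astype(float)
    n = b.shape[0]
    if n < 3:
        return UNDEFINED
    deg = b.sum(axis=1)
    triples = float((deg * (deg - 1)).sum() / 2.0)
    if triples == 0:
        return UNDEFINED
    triangles = float(np.trace(b @ b @ b) / 6.0)
    return 3.0 * triangles / triples


def local_clustering(adj: AdjacencyMatrix, weighted: bool = False) -> np.ndarray:
    """Per-node triangle density among neighbors.

    The weighted variant uses the geometric-mean edge-weight form
    (Onnela et al.), normalized by the maximum weight.
    """
    g = to_graph(adj, "weighted" if weighted else "binary")
    cc = nx.clustering(g, weight="weight" if weighted else None)
    return np.array([cc[i] for i in range(adj.weights.shape[0])], dtype=float)


def _modularity_q(w: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman-Girvan Q for a labels vector."""
    two_m = w.sum()
    if two_m == 0:
        return UNDEFINED
    deg = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        within = w[np.ix_(idx, idx)].sum()
        dc = deg[idx].sum()
        q += within / two_m - (dc / two_m) ** 2
    return float(q)


def _set_partitions(items: list[int]) -> Iterable[list[list[int]]]:
    """All partitions of ``items`` (deterministic order)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity(
    adj: AdjacencyMatrix, seed: int = 0, exact_max_nodes: int = 8
) -> tuple[Optional[list[set[int]]], float]:
    """Best community partition and its weighted Newman-Girvan Q.

    Graphs with <= ``exact_max_nodes`` nodes are optimized by exhaustive
    partition search (guaranteed optimum at desk scale); larger graphs use
    seeded Louvain with deterministic node order.
    """
    w = adj.weights
    n = w.shape[0]
    if np.count_nonzero(np.triu(w, k=1)) == 0:
        return None, UNDEFINED
    if n <= exact_max_nodes:
        best_q, best_part = -np.inf, None
        labels = np.empty(n, dtype=np.int64)
        for part in _set_partitions(list(range(n))):
            for ci, block in enumerate(part):
                labels[block] = ci
            q = _modularity_q(w, labels)
            if q > best_q + 1e-12:
                best_q, best_part = q, [set(b) for b in part]
        return best_part, float(best_q)
    g = to_graph(adj, "weighted")
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    labels = np.empty(n, dtype=np.int64)
    for ci, block in enumerate(communities):
        labels[list(block)] = ci
    return [set(c) for c in communities], _modularity_q(w, labels)


class SmallWorldResult(NamedTuple):
    sigma: float
    on_largest_component: bool


def _binary_c_and_l(g: nx.Graph) -> tuple[float, float]:
    c = nx.transitivity(g)
    l = nx.average_shortest_path_length(g)
    return float(c), float(l)


def small_worldness(
    adj: AdjacencyMatrix, n_nulls: int = 20, seed: int = 0
) -> SmallWorldResult:
    """sigma = (C/C_rand)/(L/L_rand) vs degree-preserving rewired nulls.

    Computed on the binary view; a disconnected graph is restricted to its
    largest connected component and flagged.
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    g = to_graph(adj, "binary")
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0 or g.number_of_nodes() < 3:
        return SmallWorldResult(UNDEFINED, False)
    flagged = not nx.is_connected(g)
    if flagged:
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    c, l = _binary_c_and_l(g)

    c_rand, l_rand = [], []
    m = g.number_of_edges()
    for k in range(n_nulls):
        null = g.copy()
        if m > 1 and null.number_of_nodes() >= 4:
            nx.double_edge_swap(null, nswap=10 * m, max_tries=200 * m, seed=seed + k)
        if not nx.is_connected(null):
            null = null.subgraph(max(nx.connected_components(null), key=len)).copy()
        ck, lk = _binary_c_and_l(null)
        c_rand.append(ck)
        l_rand.append(lk)
    c_rand_m = float(np.mean(c_rand))
    l_rand_m = float(np.mean(l_rand))
    if c_rand_m == 0.0 or l_rand_m == 0.0:
        return SmallWorldResult(UNDEFINED, flagged)
    return SmallWorldResult((c / c_rand_m) / (l / l_rand_m), flagged)


def natural_connectivity(adj: AdjacencyMatrix, view: str = "weighted") -> float:
    """ln((1/N) * sum_k exp(lambda_k)) over adjacency eigenvalues."""
    w = _weights(adj, view)
    n = w.shape[0]
    if n < 1:
        return UNDEFINED
    lam = np.linalg.eigvalsh(w)
    return float(logsumexp(lam) - np.log(n))


def spectral_stability(adj: AdjacencyMatrix, view: str = "weighted") -> float:
    """Largest eigenvalue of the symmetric adjacency."""
    w = _weights(adj, view)
    if w.shape[0] < 1:
        return UNDEFINED
    return float(np.linalg.eigvalsh(w)[-1])


# ---------------------------------------------------------------------------
# Node metrics
# ---------------------------------------------------------------------------

def eigenvector_centrality(adj: AdjacencyMatrix) -> np.ndarray:
    """Principal eigenvector of the weighted adjacency, unit-maximum scaled."""
    w = adj.weights
    n = w.shape[0]
    if np.count_nonzero(w) == 0:
        return np.full(n, UNDEFINED)
    vals, vecs = np.linalg.eigh(w)
    v = np.abs(vecs[:, -1])
    vmax = v.max()
    if vmax == 0:
        return np.full(n, UNDEFINED)
    return v / vmax


def degree(adj: AdjacencyMatrix) -> np.ndarray:
    """Binary-view degree (number of connections per node)."""
    return adj.binarized_view.sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# Median connectivity and multiscale driver
# ---------------------------------------------------------------------------

def _network_indices(
    parcel_ids: list[str], pmap: pd.DataFrame, network: str, hemisphere: str
) -> np.ndarray:
    lookup = {
        str(r.parcel_id): (str(r.network), str(r.hemisphere))
        for r in pmap.itertuples(index=False)
    }
    missing = [p for p in parcel_ids if p not in lookup]
    if missing:
        raise KeyError(f"parcel {missing[0]!r} missing from parcellation map")
    return np.array(
        [i for i, p in enumerate(parcel_ids) if lookup[p] == (network, hemisphere)],
        dtype=np.int64,
    )


def median_connectivity(
    conn: ConnectivityMatrix,
    pmap: pd.DataFrame,
    network: str,
    hemisphere: str,
) -> tuple[float, float]:
    """(within-network, network-to-rest) median raw connectivity."""
    idx = _network_indices(conn.parcel_ids, pmap, network, hemisphere)
    if idx.size == 0:
        raise ValueError(f"network {(network, hemisphere)!r} has no parcels")
    v = conn.values
    n = v.shape[0]
    inside = np.zeros(n, dtype=bool)
    inside[idx] = True
    if idx.size < 2:
        med_in = UNDEFINED
    else:
        within = v[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
        med_in = float(np.median(within))
    outside = ~inside
    if outside.sum() == 0:
        med_out = UNDEFINED
    else:
        med_out = float(np.median(v[np.ix_(idx, np.flatnonzero(outside))]))
    return med_in, med_out


def induced_adjacency(adj: AdjacencyMatrix, idx: np.ndarray) -> AdjacencyMatrix:
    return AdjacencyMatrix(
        parcel_ids=[adj.parcel_ids[i] for i in idx],
        weights=adj.weights[np.ix_(idx, idx)],
        threshold_used=adj.threshold_used,
    )


def _global_row(
    scope: str,
    adj: AdjacencyMatrix,
    med_in: float,
    med_out: float,
    n_nulls: int,
    seed: int,
    with_small_world: bool,
) -> dict:
    n = adj.weights.shape[0]
    if n == 0:
        keys = (
            "efficiency modularity_q global_clustering small_worldness "
            "natural_connectivity spectral_stability".split()
        )
        return {"scope": scope, "n_nodes": 0, **{k: UNDEFINED for k in keys},
                "median_conn_in": med_in, "median_conn_out": med_out}
    _, q = modularity(adj, seed=seed)
    sw = (
        small_worldness(adj, n_nulls=n_nulls, seed=seed).sigma
        if with_small_world
        else UNDEFINED
    )
    return {
        "scope": scope,
        "n_nodes": n,
        "efficiency": global_efficiency(adj),
        "modularity_q": q,
        "global_clustering": global_clustering(adj),
        "small_worldness": sw,
        "natural_connectivity": natural_connectivity(adj),
        "spectral_stability": spectral_stability(adj),
        "median_conn_in": med_in,
        "median_conn_out": med_out,
    }


def compute_all_scales(
    adj: AdjacencyMatrix,
    conn: ConnectivityMatrix,
    pmap: pd.DataFrame,
    n_nulls: int = 20,
    seed: int = 0,
    with_small_world: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics at all three spatial scales.

    Returns ``(global_df, node_df)``: one global row for the whole brain and
    one per (network, hemisphere) computed on the induced subgraph; node
    metrics computed on the whole-brain graph, one row per parcel, in parcel
    order.
    """
    # validate coverage up front, naming the offending parcel
    _ = _network_indices(adj.parcel_ids, pmap, "__none__", "__none__")

    all_vals = conn.upper_triangle()
    rows = [
        _global_row(
            "whole_brain",
            adj,
            float(np.median(all_vals)),
            UNDEFINED,
            n_nulls,
            seed,
            with_small_world,
        )
    ]
    scopes = pmap[["network", "hemisphere"]].drop_duplicates().itertuples(index=False)
    for network, hemisphere in scopes:
        idx = _network_indices(adj.parcel_ids, pmap, network, hemisphere)
        med_in, med_out = median_connectivity(conn, pmap, network, hemisphere)
        rows.append(
            _global_row(
                f"{network}/{hemisphere}",
                induced_adjacency(adj, idx),
                med_in,
                med_out,
                n_nulls,
                seed,
                with_small_world,
            )
        )
    global_df = pd.DataFrame(rows)

    cent = eigenvector_centrality(adj)
    deg = degree(adj)
    locc = local_clustering(adj)
    node_df = pd.DataFrame(
        {
            "parcel_id": list(adj.parcel_ids),
            "eigenvector_centrality": cent,
            "degree": deg,
            "local_clustering": locc,
        }
    )
    return global_df, node_df
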