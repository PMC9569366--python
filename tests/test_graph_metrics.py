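"""Topological metrics: analytic cases, oracle agreement, invariances."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_adjacency, make_connectivity
from oracles import (
    centrality_oracle,
    efficiency_oracle,
    lambda_max_oracle,
    median_oracle,
    modularity_oracle,
    natural_connectivity_oracle,
    transitivity_oracle,
)
from fcmediation.graph_metrics import (
    compute_all_scales,
    degree,
    eigenvector_centrality,
    global_clustering,
    global_efficiency,
    induced_adjacency,
    local_clustering,
    median_connectivity,
    modularity,
    natural_connectivity,
    small_worldness,
    spectral_stability,
)

K3 = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
STAR5 = np.zeros((5, 5))
STAR5[0, 1:] = STAR5[1:, 0] = 1.0


class TestAnalyticCases:
    def test_efficiency_triangle_path_empty(self):
        assert global_efficiency(make_adjacency(K3)) == pytest.approx(1.0)
        assert global_efficiency(make_adjacency(PATH3)) == pytest.approx(5 / 6)
        assert global_efficiency(make_adjacency(np.zeros((4, 4)))) == 0.0

    def test_clustering_triangle_path_pendant(self):
        assert global_clustering(make_adjacency(K3)) == pytest.approx(1.0)
        assert global_clustering(make_adjacency(PATH3)) == pytest.approx(0.0)
        tri_pendant = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]], dtype=float
        )
        assert global_clustering(make_adjacency(tri_pendant)) == pytest.approx(0.6)
        assert local_clustering(make_adjacency(K3)) == pytest.approx([1.0, 1.0, 1.0])

    def test_modularity_two_triangles_and_complete_graph(self):
        two_k3 = np.zeros((6, 6))
        two_k3[:3, :3] = K3
        two_k3[3:, 3:] = K3
        part, q = modularity(make_adjacency(two_k3))
        assert q == pytest.approx(0.5)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]
        _, q4 = modularity(make_adjacency(1.0 - np.eye(4)))
        assert q4 == pytest.approx(0.0, abs=1e-12)

    def test_natural_connectivity_closed_forms(self):
        assert natural_connectivity(make_adjacency(np.zeros((7, 7)))) == pytest.approx(0.0)
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(make_adjacency(K3)) == pytest.approx(expected)

    def test_spectral_stability_closed_forms(self):
        assert spectral_stability(make_adjacency(K3)) == pytest.approx(2.0)
        assert spectral_stability(make_adjacency(np.zeros((3, 3)))) == pytest.approx(0.0)
        assert spectral_stability(make_adjacency(STAR5)) == pytest.approx(2.0)

    def test_centrality_and_degree_closed_forms(self):
        cent = eigenvector_centrality(make_adjacency(1.0 - np.eye(4)))
        assert cent == pytest.approx([1.0, 1.0, 1.0, 1.0])
        star_cent = eigenvector_centrality(make_adjacency(STAR5))
        assert star_cent == pytest.approx([1.0, 0.5, 0.5, 0.5, 0.5])
        assert degree(make_adjacency(PATH3)).tolist() == [1, 2, 1]

    def test_edgeless_graph_markers(self):
        adj = make_adjacency(np.zeros((4, 4)))
        assert np.isnan(modularity(adj)[1])
        assert np.isnan(global_clustering(adj))
        assert np.all(np.isnan(eigenvector_centrality(adj)))
        assert degree(adj).tolist() == [0, 0, 0, 0]


class TestOracleEnsemble:
    def test_metrics_match_bruteforce_on_small_graphs(self, graph_ensemble):
        for w in graph_ensemble:
            adj = make_adjacency(w)
            assert global_efficiency(adj) == pytest.approx(
                efficiency_oracle(w), abs=1e-8
            )
            b = (w > 0).astype(float)
            t_impl = global_clustering(adj)
            t_oracle = transitivity_oracle(b)
            if np.isnan(t_oracle):
                assert np.isnan(t_impl)
            else:
                assert t_impl == pytest.approx(t_oracle, abs=1e-8)
            assert modularity(adj)[1] == pytest.approx(modularity_oracle(w), abs=1e-8)
            assert natural_connectivity(adj) == pytest.approx(
                natural_connectivity_oracle(w), abs=1e-8
            )
            assert spectral_stability(adj) == pytest.approx(
                lambda_max_oracle(w), abs=1e-8
            )
            np.testing.assert_allclose(
                eigenvector_centrality(adj), centrality_oracle(w), atol=1e-6
            )

    def test_planted_two_block_partition_recovered(self):
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        w[0, 4] = w[4, 0] = 1.0
        part, _ = modularity(make_adjacency(w))
        assert sorted(sorted(c) for c in part) == [[0, 1, 2, 3], [4, 5, 6, 7]]


class TestSmallWorldness:
    def test_erdos_renyi_sigma_near_one(self):
        import networkx as nx

        g = nx.erdos_renyi_graph(60, 0.15, seed=3)
        w = nx.to_numpy_array(g)
        res = small_worldness(make_adjacency(w), n_nulls=15, seed=0)
        assert res.sigma == pytest.approx(1.0, abs=0.2)

    def test_watts_strogatz_sigma_above_one(self):
        import networkx as nx

        g = nx.watts_strogatz_graph(60, 6, 0.1, seed=4)
        w = nx.to_numpy_array(g)
        res = small_worldness(make_adjacency(w), n_nulls=15, seed=0)
        assert res.sigma > 1.0

    def test_edgeless_guard_and_component_flag(self):
        assert np.isnan(small_worldness(make_adjacency(np.zeros((5, 5)))).sigma)
        two_k3 = np.zeros((6, 6))
        two_k3[:3, :3] = K3
        two_k3[3:, 3:] = K3
        res = small_worldness(make_adjacency(two_k3), n_nulls=2, seed=0)
        assert res.on_largest_component

    def test_deterministic_under_seed(self):
        import networkx as nx

        w = nx.to_numpy_array(nx.erdos_renyi_graph(30, 0.2, seed=9))
        a = small_worldness(make_adjacency(w), n_nulls=5, seed=11)
        b = small_worldness(make_adjacency(w), n_nulls=5, seed=11)
        assert a.sigma == b.sigma


def _pmap_for(n, networks):
    rows = []
    for i in range(n):
        net, hemi = networks[i]
        rows.append((f"p{i:04d}", net, hemi))
    return pd.DataFrame(rows, columns=["parcel_id", "network", "hemisphere"])


class TestMedianConnectivityAndScales:
    def test_two_parcel_network_median(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.4
        v[0, 2] = v[2, 0] = 0.1
        v[1, 2] = v[2, 1] = 0.3
        conn = make_connectivity(v)
        pmap = _pmap_for(3, {0: ("A", "left"), 1: ("A", "left"), 2: ("B", "left")})
        med_in, med_out = median_connectivity(conn, pmap, "A", "left")
        assert med_in == pytest.approx(0.4)
        assert med_out == pytest.approx(0.2)  # median of {0.1, 0.3}

    def test_odd_count_median(self):
        v = np.zeros((4, 4))
        vals = {(0, 1): 0.1, (0, 2): 0.2, (1, 2): 0.3}
        for (i, j), x in vals.items():
            v[i, j] = v[j, i] = x
        conn = make_connectivity(v)
        pmap = _pmap_for(
            4, {0: ("A", "left"), 1: ("A", "left"), 2: ("A", "left"), 3: ("B", "left")}
        )
        assert median_connectivity(conn, pmap, "A", "left")[0] == pytest.approx(0.2)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(0, 1, size=(8, 8))
        v = np.triu(v, 1)
        v = v + v.T
        conn = make_connectivity(v)
        pmap = _pmap_for(8, {i: ("A" if i < 4 else "B", "left") for i in range(8)})
        med_in, _ = median_connectivity(conn, pmap, "A", "left")
        within = [v[i, j] for i in range(4) for j in range(i + 1, 4)]
        assert med_in == median_oracle(within)

    def test_whole_graph_scope_equals_whole_brain_metrics(self):
        rng = np.random.default_rng(13)
        w = rng.uniform(0, 1, size=(6, 6)) * (rng.random((6, 6)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        adj = make_adjacency(w)
        conn = make_connectivity(w)
        pmap = _pmap_for(6, {i: ("all", "left") for i in range(6)})
        gdf, ndf = compute_all_scales(adj, conn, pmap, with_small_world=False)
        whole = gdf[gdf.scope == "whole_brain"].iloc[0]
        net = gdf[gdf.scope == "all/left"].iloc[0]
        for col in ("efficiency", "modularity_q", "global_clustering",
                    "natural_connectivity", "spectral_stability"):
            assert whole[col] == pytest.approx(net[col], abs=1e-12)
        assert len(ndf) == 6

    def test_disconnected_networks_match_standalone(self):
        w = np.zeros((6, 6))
        w[:3, :3] = K3
        w[3:, 3:] = PATH3
        adj = make_adjacency(w)
        conn = make_connectivity(w)
        pmap = _pmap_for(6, {i: ("A" if i < 3 else "B", "left") for i in range(6)})
        gdf, _ = compute_all_scales(adj, conn, pmap, with_small_world=False)
        eff_a = gdf[gdf.scope == "A/left"].iloc[0]["efficiency"]
        eff_b = gdf[gdf.scope == "B/left"].iloc[0]["efficiency"]
        assert eff_a == pytest.approx(global_efficiency(make_adjacency(K3)))
        assert eff_b == pytest.approx(global_efficiency(make_adjacency(PATH3)))

    def test_missing_parcel_named(self):
        adj = make_adjacency(K3)
        conn = make_connectivity(K3 * 0.5)
        pmap = _pmap_for(2, {0: ("A", "left"), 1: ("A", "left")})
        with pytest.raises(KeyError, match="p0002"):
            compute_all_scales(adj, conn, pmap, with_small_world=False)


class TestInvariances:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        w = rng.uniform(0.1, 1, size=(7, 7)) * (rng.random((7, 7)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        a, ap = make_adjacency(w), make_adjacency(wp)
        assert global_efficiency(a) == pytest.approx(global_efficiency(ap), abs=1e-12)
        assert natural_connectivity(a) == pytest.approx(
            natural_connectivity(ap), abs=1e-12
        )
        assert spectral_stability(a) == pytest.approx(spectral_stability(ap), abs=1e-12)
        assert modularity(a)[1] == pytest.approx(modularity(ap)[1], abs=1e-12)
        np.testing.assert_allclose(degree(a)[perm], degree(ap), atol=0)
        np.testing.assert_allclose(
            eigenvector_centrality(a)[perm], eigenvector_centrality(ap), atol=1e-9
        )

    def test_adding_edge_never_decreases_spectral_metrics(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            w = rng.uniform(0.1, 1, size=(6, 6)) * (rng.random((6, 6)) < 0.4)
            w = np.triu(w, 1)
            w = w + w.T
            zeros = np.argwhere((np.triu(np.ones((6, 6)), 1) > 0) & (w == 0))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 1)
            assert natural_connectivity(make_adjacency(w2)) >= natural_connectivity(
                make_adjacency(w)
            ) - 1e-12
            assert spectral_stability(make_adjacency(w2)) >= spectral_stability(
                make_adjacency(w)
            ) - 1e-12

    def test_lower_within_correlation_lowers_network_metrics(self):
        # pipeline-level sensitivity: weaker within-network coupling ->
        # lower efficiency, clustering, robustness, stability of that network
        from fcmediation.config import CohortConfig
        from fcmediation.cohort import (
            generate_beliefs,
            generate_covariates,
            generate_timeseries,
            generate_true_topology,
            parcellation_map,
        )
        from fcmediation.connectivity import apply_threshold, peak_crosscorr

        def network_metrics(rho_w, seed):
            layout = [["netA", "left", 6], ["netB", "left", 6]]
            cfg = CohortConfig(
                n_subjects=6, n_parcels=12, n_timepoints=400,
                n_runs_per_subject=1, network_layout=layout,
                rho_within=rho_w, rho_between=0.05, belief_topology_d=0.0,
                subject_rho_sd=1e-6, target_network="netA",
                target_hemisphere="left", seed=seed,
            ).validate()
            df = generate_true_topology(
                generate_beliefs(generate_covariates(cfg), cfg), cfg
            )
            pmap = parcellation_map(cfg)
            out = []
            for i in range(len(df)):
                ts = generate_timeseries(df.iloc[i], cfg, i)[0]
                conn = peak_crosscorr(ts, max_lag=0)
                adj = apply_threshold(conn, 0.2)
                idx = np.arange(6)
                sub = induced_adjacency(adj, idx)
                out.append(
                    [
                        global_efficiency(sub),
                        natural_connectivity(sub),
                        spectral_stability(sub),
                    ]
                )
            return np.mean(out, axis=0)

        strong = network_metrics(0.6, seed=77)
        weak = network_metrics(0.3, seed=77)
        assert np.all(weak < strong)
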