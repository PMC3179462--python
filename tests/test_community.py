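"""Modularity, fast-greedy community detection, and node-role cartography."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import connectome_backbone as cb
from conftest import random_graph
from oracles import brute_modularity, exhaustive_max_modularity


def two_triangles():
    return cb.BackboneGraph.from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    )


class TestModularity:
    def test_single_module_is_zero(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 8, p=0.5)
        assert cb.modularity(g, np.zeros(8, dtype=int)) == pytest.approx(0.0)

    def test_two_disjoint_triangles_true_split(self):
        # Q = 2 * (3/6 - (6/12)^2) = 0.5
        assert cb.modularity(two_triangles(), [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            g = random_graph(rng, 8, p=0.5)
            labels = rng.integers(0, 3, size=8)
            assert cb.modularity(g, labels) == pytest.approx(
                brute_modularity(g, labels)
            )

    def test_random_assignment_on_er_graphs_mean_q_matches_expectation(self):
        # for labels uniform over M modules, independent of edges:
        # E[l_s/L] sums to 1/M and E[sum_s (d_s/2L)^2] = 1/M + (1-1/M)
        # * sum_i d_i^2 / (sum_i d_i)^2, so E[Q] = -(1-1/M) sum d^2/(sum d)^2
        # (slightly negative at finite n, -> 0 for large graphs)
        rng = np.random.default_rng(2)
        m = 3
        devs = []
        for _ in range(60):
            g = random_graph(rng, 12, p=0.5)
            if g.n_edges == 0:
                continue
            q = cb.modularity(g, rng.integers(0, m, size=12))
            d = g.degree.astype(float)
            expected = -(1 - 1 / m) * (d @ d) / d.sum() ** 2
            devs.append(q - expected)
        devs = np.array(devs)
        se = devs.std(ddof=1) / np.sqrt(devs.size)
        assert abs(devs.mean()) < 3 * se

    def test_partition_tallies(self):
        part = cb.partition_from_labels(two_triangles(), [0, 0, 0, 1, 1, 1])
        assert part.l_s.tolist() == [3, 3]
        assert part.d_s.tolist() == [6, 6]
        assert part.d_s.sum() == 2 * part.n_edges

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            cb.modularity(cb.BackboneGraph(3, frozenset()), [0, 0, 0])


class TestDetectCommunities:
    def test_two_triangles_recovered(self):
        part = cb.detect_communities(two_triangles())
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)
        assert len(set(part.assignment[:3])) == 1
        assert len(set(part.assignment[3:])) == 1

    def test_internal_q_consistency(self, default_snr):
        g = cb.threshold_to_cost(default_snr, 0.21)
        part = cb.detect_communities(g)
        assert part.q == pytest.approx(cb.modularity(g, part.assignment))

    def test_planted_partition_recovery_and_q_bound(self):
        # 4 planted modules of 20 at p_in=0.8, p_out=0.02: near-perfect
        # recovery, with detected Q at least the planted partition's Q - 0.02
        mods = [list(range(20 * k, 20 * (k + 1))) for k in range(4)]
        aris = []
        for seed in range(20):
            cfg = cb.CohortConfig(
                n_regions=80, modules_truth=mods, p_in=0.8, p_out=0.02, seed=seed
            )
            g, truth = cb.plant_backbone(cfg)
            part = cb.detect_communities(g)
            aris.append(adjusted_rand_score(truth, part.assignment))
            assert part.q >= cb.modularity(g, truth) - 0.02
        assert np.mean(aris) >= 0.9

    def test_greedy_never_beats_exhaustive_optimum(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 8:
            g = random_graph(rng, int(rng.integers(4, 8)), p=0.45)
            if g.n_edges == 0:
                continue
            assert cb.detect_communities(g).q <= exhaustive_max_modularity(g) + 1e-9
            checked += 1

    def test_isolated_nodes_stay_singletons(self):
        g = cb.BackboneGraph.from_edges(5, [(0, 1), (1, 2), (0, 2)])
        part = cb.detect_communities(g)
        assert part.assignment[3] != part.assignment[4]
        assert part.assignment[3] not in part.assignment[:3]

    def test_deterministic(self, default_snr):
        g = cb.threshold_to_cost(default_snr, 0.15)
        p1 = cb.detect_communities(g)
        p2 = cb.detect_communities(g)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)


class TestNodeRoles:
    def test_all_edges_inside_module_p_zero(self):
        g = two_triangles()
        part = cb.partition_from_labels(g, [0, 0, 0, 1, 1, 1])
        roles = cb.node_roles(g, part)
        assert np.all(roles["p"] == 0.0)
        assert set(roles["role"]) == {"A"}

    def test_half_split_participation(self):
        # k=4 split 2/2 across two modules: P = 1 - 2*(1/2)^2 = 0.5
        edges = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (3, 4)]
        g = cb.BackboneGraph.from_edges(5, edges)
        part = cb.partition_from_labels(g, [0, 0, 0, 1, 1])
        roles = cb.node_roles(g, part)
        assert roles.loc[0, "p"] == pytest.approx(0.5)

    def test_uniform_module_z_zero(self):
        roles = cb.node_roles(
            two_triangles(),
            cb.partition_from_labels(two_triangles(), [0, 0, 0, 1, 1, 1]),
        )
        assert np.all(roles["z"] == 0.0)

    def test_degree_zero_flagged_role_a(self):
        g = cb.BackboneGraph.from_edges(4, [(0, 1), (1, 2), (0, 2)])
        part = cb.partition_from_labels(g, [0, 0, 0, 1])
        roles = cb.node_roles(g, part)
        assert roles.loc[3, "role"] == "A"
        assert bool(roles.loc[3, "degenerate"])

    def test_kappa_sums_to_degree_and_p_range(self, default_snr):
        g = cb.threshold_to_cost(default_snr, 0.21)
        part = cb.detect_communities(g)
        roles = cb.node_roles(g, part)
        assert np.all(roles["kappa"] <= roles["degree"])
        m = part.n_modules
        assert np.all(roles["p"] >= 0.0)
        assert np.all(roles["p"] <= 1 - 1 / m + 1e-12)

    def test_p_invariant_under_module_relabeling(self):
        g = two_triangles()
        r1 = cb.node_roles(g, cb.partition_from_labels(g, [0, 0, 0, 1, 1, 1]))
        r2 = cb.node_roles(g, cb.partition_from_labels(g, [1, 1, 1, 0, 0, 0]))
        np.testing.assert_allclose(r1["p"], r2["p"])

    def test_role_boundaries(self):
        # synthetic z/P combinations hit each role letter
        th = cb.RoleThresholds()
        g = two_triangles()
        part = cb.partition_from_labels(g, [0, 0, 0, 1, 1, 1])
        roles = cb.node_roles(g, part, thresholds=th)
        assert list(roles["role"]) == ["A"] * 6  # all-intra nodes are ultra-peripheral


class TestNonrandomModularity:
    def test_modular_backbone_q_above_null(self, default_snr):
        rec = cb.nonrandom_modularity_sweep(default_snr, [0.15, 0.21], n_null=10,
                                            seed=3)
        for r in rec:
            assert r["q_brain"] > r["q_random_mean"] + 3 * r["q_random_sd"]

    def test_no_structure_control(self):
        # p_in == p_out is impossible by config validation; use a nearly
        # flat SBM: detected Q should sit within the null band
        cfg = cb.CohortConfig(
            n_regions=40,
            n_subjects=6,
            modules_truth=[list(range(20)), list(range(20, 40))],
            p_in=0.3501,
            p_out=0.3499,
            seed=4,
        )
        g, _ = cb.plant_backbone(cfg)
        snr_mat = g.adjacency().astype(float) * 5
        snr = cb.SNRMatrix(mean=snr_mat.copy(), sd=np.ones_like(snr_mat),
                           snr=snr_mat, n_subjects=6)
        rec = cb.nonrandom_modularity_sweep(
            snr, [g.n_edges / g.max_edges], n_null=20, seed=5
        )[0]
        assert abs(rec["q_brain"] - rec["q_random_mean"]) <= 3 * rec["q_random_sd"]
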