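"""Graph representation, BFS path statistics, and file I/O."""

import numpy as np
import pandas as pd
import pytest

import connectome_backbone as cb
from conftest import complete_graph, path_graph, random_graph
from oracles import floyd_warshall


class TestBackboneGraph:
    def test_rejects_self_loops_and_bad_edges(self):
        with pytest.raises(ValueError, match="self-loop"):
            cb.BackboneGraph.from_edges(3, [(1, 1)])
        with pytest.raises(ValueError):
            cb.BackboneGraph(3, frozenset({(2, 1)}))  # non-canonical order

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_graph(rng, int(rng.integers(2, 9)))
            assert g.degree.sum() == 2 * g.n_edges
            assert 0 <= g.n_edges <= g.max_edges

    def test_from_adjacency_requires_symmetry(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            cb.BackboneGraph.from_adjacency(a)


class TestShortestPaths:
    def test_complete_graph_all_distance_one(self):
        ps = cb.shortest_paths(complete_graph(4))
        off = ~np.eye(4, dtype=bool)
        assert np.all(ps.dist[off] == 1)
        assert np.all(ps.sigma[off] == 1)

    def test_three_node_path_counts(self):
        # a-b-c: d(a,c)=2 via the single path through b
        ps = cb.shortest_paths(path_graph(3))
        assert ps.dist[0, 2] == 2
        assert ps.sigma[0, 2] == 1
        assert ps.through(1)[0, 2] == 1

    def test_disconnected_pairs_inf_and_zero_sigma(self):
        g = cb.BackboneGraph.from_edges(4, [(0, 1), (2, 3)])
        ps = cb.shortest_paths(g)
        assert np.isinf(ps.dist[0, 2]) and ps.sigma[0, 2] == 0

    def test_empty_graph_allowed(self):
        ps = cb.shortest_paths(cb.BackboneGraph(3, frozenset()))
        assert np.isinf(ps.dist[0, 1])

    def test_agrees_with_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            g = random_graph(rng, int(rng.integers(2, 9)))
            np.testing.assert_array_equal(cb.shortest_paths(g).dist, floyd_warshall(g))

    def test_path_counts_satisfy_brandes_recursion(self):
        # sigma_jk = sum over predecessors m of k (d(j,m) = d(j,k)-1, m~k)
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(3, 9)))
            ps = cb.shortest_paths(g)
            nbr = g.neighbors()
            for j in range(g.n_nodes):
                for k in range(g.n_nodes):
                    if j == k or np.isinf(ps.dist[j, k]):
                        continue
                    pred = [m for m in nbr[k] if ps.dist[j, m] == ps.dist[j, k] - 1]
                    assert ps.sigma[j, k] == sum(ps.sigma[j, m] for m in pred)

    def test_through_counts_bounded_by_sigma(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_graph(rng, 7)
            ps = cb.shortest_paths(g)
            for i in range(7):
                assert np.all(ps.through(i) <= ps.sigma + 1e-12)


class TestComponents:
    @pytest.mark.parametrize(
        "edges,n,expected",
        [
            ([], 5, 1),                                   # edgeless: singletons
            ([(0, 1), (1, 2), (0, 2)], 4, 3),             # triangle + isolate
            (None, 78, 78),                               # complete graph
        ],
    )
    def test_largest_component_size(self, edges, n, expected):
        g = complete_graph(n) if edges is None else cb.BackboneGraph.from_edges(n, edges)
        assert cb.largest_component_size(g) == expected


class TestPajek:
    def test_triangle_export_format(self, tmp_path):
        g = cb.BackboneGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        p = tmp_path / "tri.net"
        cb.write_pajek(g, ["A", "B", "C"], p)
        lines = p.read_text().splitlines()
        assert lines[0] == "*Vertices 3"
        assert lines[1] == '1 "A"'
        assert lines[4] == "*Edges"
        assert set(lines[5:]) == {"1 2", "1 3", "2 3"}

    def test_empty_edge_set(self, tmp_path):
        p = tmp_path / "empty.net"
        cb.write_pajek(cb.BackboneGraph(2, frozenset()), ["A", "B"], p)
        assert p.read_text().rstrip().endswith("*Edges")

    def test_partition_clu_is_one_based(self, tmp_path):
        g = cb.BackboneGraph.from_edges(3, [(0, 1)])
        p = tmp_path / "g.net"
        cb.write_pajek(g, ["A", "B", "C"], p, partition=[0, 0, 1])
        assert (tmp_path / "g.clu").read_text().splitlines()[1:] == ["1", "1", "2"]

    def test_roundtrip_reproduces_edge_set(self, tmp_path):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 10)
        labels = [f"R{i}" for i in range(10)]
        cb.write_pajek(g, labels, tmp_path / "g.net")
        g2, labels2 = cb.read_pajek(tmp_path / "g.net")
        assert g2.edges == g.edges
        assert labels2 == labels


class TestCohortIO:
    def _write_cohort_inputs(self, tmp_path, n=4, counts=None):
        atlas = cb.synthetic_atlas(n)
        cb.write_atlas(atlas, tmp_path / "atlas.tsv")
        if counts is None:
            counts = np.zeros((n, n), dtype=int)
            counts[0, 1] = counts[1, 0] = 7
        np.savetxt(tmp_path / "s1.tsv", counts, fmt="%d", delimiter="\t")
        pd.DataFrame(
            {"scan_id": ["s1"], "subject_id": ["s1"], "age_group": ["g"], "sex": ["F"]}
        ).to_csv(tmp_path / "meta.csv", index=False)
        return tmp_path

    def test_single_pair_count(self, tmp_path):
        d = self._write_cohort_inputs(tmp_path)
        c = cb.read_cohort({"s1": d / "s1.tsv"}, d / "atlas.tsv", d / "meta.csv")
        assert c.counts[0, 0, 1] == 7
        assert (c.counts > 0).sum() == 2  # the symmetric pair only

    def test_shape_mismatch_rejected(self, tmp_path):
        d = self._write_cohort_inputs(tmp_path)
        np.savetxt(d / "bad.tsv", np.zeros((3, 4), dtype=int), fmt="%d", delimiter="\t")
        with pytest.raises(ValueError, match="shape mismatch"):
            cb.read_cohort({"s1": d / "bad.tsv"}, d / "atlas.tsv", d / "meta.csv")

    def test_asymmetric_counts_rejected(self, tmp_path):
        bad = np.zeros((4, 4), dtype=int)
        bad[0, 1] = 3  # transpose entry missing
        d = self._write_cohort_inputs(tmp_path, counts=bad)
        with pytest.raises(ValueError, match="asymmetric"):
            cb.read_cohort({"s1": d / "s1.tsv"}, d / "atlas.tsv", d / "meta.csv")

    def test_negative_counts_rejected(self, tmp_path):
        bad = np.zeros((4, 4), dtype=int)
        bad[0, 1] = bad[1, 0] = -2
        d = self._write_cohort_inputs(tmp_path, counts=bad)
        with pytest.raises(ValueError, match="nonnegative"):
            cb.read_cohort({"s1": d / "s1.tsv"}, d / "atlas.tsv", d / "meta.csv")

    def test_unknown_subject_id_rejected(self, tmp_path):
        d = self._write_cohort_inputs(tmp_path)
        with pytest.raises(ValueError, match="unknown subject id"):
            cb.read_cohort({"sX": d / "s1.tsv"}, d / "atlas.tsv", d / "meta.csv")

    def test_roundtrip_identity(self, tmp_path):
        cohort, _, _ = cb.sample_cohort(
            cb.CohortConfig(n_regions=10, n_subjects=3, seed=9)
        )
        cb.write_cohort(cohort, tmp_path / "out")
        back = cb.read_cohort_dir(tmp_path / "out")
        np.testing.assert_array_equal(back.counts, cohort.counts)
        np.testing.assert_allclose(back.lengths, cohort.lengths)
        assert back.atlas.labels == cohort.atlas.labels
        assert list(back.subjects["scan_id"]) == list(cohort.subjects["scan_id"])


class TestAtlas:
    def test_default_atlas_is_78_regions_paired(self):
        atlas = cb.default_atlas()
        assert atlas.n_regions == 78
        assert len(atlas.hemisphere_pairs()) == 39

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            cb.RegionAtlas(("A-L", "A-L"), ("L", "L"))

    def test_unpaired_label_reported(self):
        atlas = cb.RegionAtlas(("A-L", "A-R", "B-L", "C-R"), ("L", "R", "L", "R"))
        with pytest.raises(ValueError, match="B-L"):
            atlas.hemisphere_pairs()
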