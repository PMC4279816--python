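"""Within-group connectivity, clustering, triangles, and surrogate rewiring."""

import numpy as np
import pytest

from enzloc import (
    clustering_coefficients,
    degree_and_path_contrast,
    degree_preserving_rewire,
    surrogate_triangle_ratio,
    triangle_composition,
    wgc_contrast,
    within_group_connectivity,
)
from enzloc.groups import _swap_edges

from conftest import make_net, net_from_matrix, random_digraph


class TestWgc:
    def test_directed_pair_normalization(self):
        net = make_net("ABC", [("A", "B"), ("B", "C")])
        mask = np.array([True, True, True])
        assert within_group_connectivity(net, mask) == pytest.approx(2 / 6)

    def test_full_triad(self):
        edges = [(a, b) for a in "ABC" for b in "ABC" if a != b]
        net = make_net("ABC", edges)
        assert within_group_connectivity(net, np.ones(3, bool)) == 1.0

    def test_no_internal_edges(self):
        net = make_net("ABCD", [("A", "C"), ("B", "D")])
        assert within_group_connectivity(net, np.array([1, 1, 0, 0], bool)) == 0.0

    def test_small_group_rejected(self):
        net = make_net("AB", [("A", "B")])
        with pytest.raises(ValueError):
            within_group_connectivity(net, np.array([True, False]))

    def test_whole_set_wgc_is_edge_density(self, rng):
        M = random_digraph(20, 0.2, rng)
        net = net_from_matrix(M)
        assert within_group_connectivity(net, np.ones(20, bool)) == pytest.approx(
            M.sum() / (20 * 19))

    def test_alternative_normalizations(self):
        net = make_net("ABC", [("A", "B"), ("B", "C")])
        mask = np.ones(3, bool)
        assert within_group_connectivity(net, mask, norm="unordered") == pytest.approx(2 / 3)
        assert within_group_connectivity(net, mask, norm="per_node") == pytest.approx(2 / 3)


class TestWgcContrast:
    def test_complement_mask_flips_sign(self, rng):
        M = random_digraph(30, 0.15, rng)
        mask = np.arange(30) < 10
        net = net_from_matrix(M, mask)
        a = wgc_contrast(net, mask, n_draws=50, seed=1)
        b = wgc_contrast(net, ~mask, n_draws=50, seed=1)
        assert a.observed == pytest.approx(-b.observed)

    def test_null_centered_under_random_mask(self, rng):
        zs = []
        for r in range(30):
            M = random_digraph(40, 0.12, np.random.default_rng(100 + r))
            mask = np.zeros(40, bool)
            mask[np.random.default_rng(200 + r).choice(40, 10, replace=False)] = True
            zs.append(wgc_contrast(net_from_matrix(M, mask), n_draws=300, seed=r).z)
        assert abs(np.mean(zs)) < 3 / np.sqrt(30)


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        net = make_net("ABC", [("A", "B"), ("B", "C"), ("C", "A")])
        series, _ = clustering_coefficients(net, np.array([1, 0, 0], bool))
        assert series.tolist() == [1.0, 1.0, 1.0]

    def test_path_center_unclustered(self):
        net = make_net("ABC", [("A", "B"), ("B", "C")])
        series, _ = clustering_coefficients(net, np.array([1, 0, 0], bool))
        assert series["B"] == 0.0

    def test_triangle_with_pendant(self):
        net = make_net("ABCD", [("A", "B"), ("B", "C"), ("C", "A"), ("A", "D")])
        series, _ = clustering_coefficients(net, np.array([1, 0, 0, 0], bool))
        assert series["A"] == pytest.approx(1 / 3)

    def test_coefficients_in_unit_interval(self, rng):
        net = net_from_matrix(random_digraph(25, 0.2, rng), np.arange(25) < 8)
        series, contrast = clustering_coefficients(net)
        assert ((series >= 0) & (series <= 1)).all()
        assert 0 < contrast["ks_p"] <= 1


class TestTriangles:
    def test_single_triangle_one_localized(self, caplog):
        net = make_net("ABC", [("A", "B"), ("B", "C"), ("C", "A")])
        with caplog.at_level("WARNING"):
            tc = triangle_composition(net, np.array([1, 0, 0], bool))
        assert (tc.t1loc2non, tc.t2loc1non, tc.t3loc, tc.t0loc) == (1, 0, 0, 0)
        assert tc.ratio_1to2 is None
        assert "undefined" in caplog.text

    def test_two_disjoint_triangles(self):
        edges = [("A", "B"), ("B", "C"), ("C", "A"),
                 ("D", "E"), ("E", "F"), ("F", "D")]
        net = make_net("ABCDEF", edges)
        tc = triangle_composition(net, np.array([1, 0, 0, 1, 1, 0], bool))
        assert (tc.t1loc2non, tc.t2loc1non) == (1, 1)
        assert tc.ratio_1to2 == 1.0

    def test_k4_with_two_localized(self):
        ids = "ABCD"
        edges = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        net = make_net(ids, edges)
        tc = triangle_composition(net, np.array([1, 1, 0, 0], bool))
        assert tc.total == 4
        assert (tc.t2loc1non, tc.t1loc2non) == (2, 2)
        assert tc.ratio_1to2 == 1.0

    def test_total_matches_trace_oracle(self, rng):
        M = random_digraph(30, 0.25, rng)
        net = net_from_matrix(M, np.arange(30) < 9)
        tc = triangle_composition(net)
        A = ((M + M.T) > 0).astype(np.int64)
        np.fill_diagonal(A, 0)
        assert tc.total == int(np.trace(A @ A @ A) // 6)

    def test_random_mask_composition_ratio(self):
        # under a uniformly random mask with fraction f the expected class
        # ratio E[t1loc2non]/E[t2loc1non] is (1-f)/f (binomial composition)
        rng = np.random.default_rng(17)
        M = random_digraph(40, 0.3, rng)
        f = 0.25
        t1, t2 = 0, 0
        for r in range(150):
            mask = np.random.default_rng(300 + r).random(40) < f
            tc = triangle_composition(net_from_matrix(M), mask)
            t1 += tc.t1loc2non
            t2 += tc.t2loc1non
        assert t1 / t2 == pytest.approx((1 - f) / f, rel=0.15)


class TestRewiring:
    def test_parallel_paths_single_swap(self):
        net = make_net("ABCD", [("A", "B"), ("C", "D")])
        rewired = degree_preserving_rewire(net, n_swaps=1, seed=0)
        assert sorted(rewired.edge_list()) == [("A", "D"), ("C", "B")]

    def test_three_cycle_is_rigid(self, caplog):
        net = make_net("ABC", [("A", "B"), ("B", "C"), ("C", "A")])
        with caplog.at_level("WARNING"):
            rewired = degree_preserving_rewire(net, n_swaps=5, seed=1, attempt_factor=20)
        assert np.array_equal(rewired.M, net.M)
        assert "rigid" in caplog.text

    def test_degrees_preserved_on_random_networks(self, rng):
        for r in range(50):
            M = random_digraph(15, 0.2, np.random.default_rng(r))
            if M.sum() < 2:
                continue
            net = net_from_matrix(M)
            rewired = degree_preserving_rewire(net, seed=r)
            assert np.array_equal(rewired.M.sum(1), M.sum(1))
            assert np.array_equal(rewired.M.sum(0), M.sum(0))
            assert np.diagonal(rewired.M).sum() == 0

    def test_swap_core_never_duplicates_edges(self, rng):
        edges = [(int(a), int(b)) for a, b in zip(*np.nonzero(random_digraph(12, 0.25, rng)))]
        new_edges, _ = _swap_edges(edges, 200, rng)
        assert len(set(new_edges)) == len(edges)


class TestSurrogates:
    def test_fixed_seed_reproducible(self, rng):
        net = net_from_matrix(random_digraph(30, 0.25, rng), np.arange(30) < 10)
        a = surrogate_triangle_ratio(net, n_surrogates=5, seed=42)
        b = surrogate_triangle_ratio(net, n_surrogates=5, seed=42)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_zero_localized_mask_degenerate(self, rng):
        net = net_from_matrix(random_digraph(20, 0.3, rng))
        ens = surrogate_triangle_ratio(net, n_surrogates=3, seed=1)
        assert ens.degenerate

    def test_er_network_ratio_within_ensemble(self, rng):
        # an already-random network should sit near its surrogate ensemble
        net = net_from_matrix(random_digraph(40, 0.25, rng), np.arange(40) < 12)
        ens = surrogate_triangle_ratio(net, n_surrogates=30, seed=3)
        assert not ens.degenerate
        assert abs(ens.observed - ens.mean) < 4 * ens.sd


class TestDegreeAndPaths:
    def test_three_cycle_paths(self):
        net = make_net("ABC", [("A", "B"), ("B", "C"), ("C", "A")],
                       localized=np.array([1, 0, 0], bool))
        res = degree_and_path_contrast(net)
        assert res["unreachable_pairs"] == {"localized_source": 0,
                                            "nonlocalized_source": 0}
        assert res["in_degree"]["mean_a"] == 1.0
        assert res["shortest_path"]["mean_a"] == pytest.approx(1.5)

    def test_unreachable_pairs_counted(self):
        net = make_net("ABC", [("A", "B")], localized=np.array([1, 0, 0], bool))
        res = degree_and_path_contrast(net)
        # A reaches B only (C unreachable); B and C reach nothing
        assert res["unreachable_pairs"]["localized_source"] == 1
        assert res["unreachable_pairs"]["nonlocalized_source"] == 4

    def test_star_out_degrees(self):
        net = make_net("ABCD", [("A", "B"), ("A", "C"), ("A", "D")],
                       localized=np.array([1, 0, 0, 0], bool))
        res = degree_and_path_contrast(net)
        assert res["out_degree"]["mean_a"] == 3.0
        assert res["out_degree"]["mean_b"] == 0.0
        # hub reaches everything in one step; the leaves reach nothing, so
        # the path contrast is omitted rather than fabricated
        assert res["shortest_path"] is None
        assert res["unreachable_pairs"]["nonlocalized_source"] == 9
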