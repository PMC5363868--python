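import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connfp import (RoiTimeSeries, SparsityGrid, binarize_at_sparsity,
                    correlation_matrix, fisher_z, is_connected,
                    minimum_common_sparsity)
from connfp.network import BinaryNetwork, ZMatrix, _ranked_edges

from conftest import union_find_connected


def _ts(data):
    data = np.asarray(data, dtype=float)
    return RoiTimeSeries(data, 3.0, [f"r{i}" for i in range(data.shape[1])])


def _random_z(rng, r):
    m = rng.standard_normal((r, r))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return ZMatrix(m, [f"r{i}" for i in range(r)])


class TestCorrelation:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        c = correlation_matrix(_ts(np.column_stack([x, x, -x])))
        assert c.values[0, 1] == pytest.approx(1.0)
        assert c.values[0, 2] == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((136, 10))
        c = correlation_matrix(_ts(data))
        centred = data - data.mean(axis=0)
        oracle = (centred.T @ centred) / np.outer(
            np.linalg.norm(centred, axis=0), np.linalg.norm(centred, axis=0))
        np.testing.assert_allclose(c.values, oracle, atol=1e-12)

    def test_zero_variance_column_named(self):
        data = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="r1"):
            correlation_matrix(_ts(data))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(_ts(np.random.default_rng(0).standard_normal((2, 3))))


class TestFisherZ:
    def test_closed_form_values(self):
        from connfp import CorrMatrix
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [0.5, -0.5, 1.0]])
        z = fisher_z(CorrMatrix(r, ["a", "b", "c"]))
        assert z.values[0, 1] == 0.0
        assert z.values[0, 2] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert z.values[0, 2] == pytest.approx(0.5493, abs=1e-4)
        assert z.values[1, 2] == pytest.approx(-z.values[0, 2])  # odd symmetry
        assert (np.diag(z.values) == 0).all()

    def test_perfect_correlation_clipped_with_warning(self):
        from connfp import CorrMatrix
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(CorrMatrix(r, ["a", "b"]))
        assert np.isfinite(z.values).all()


class TestBinarize:
    def test_full_sparsity_gives_complete_graph(self):
        z = _random_z(np.random.default_rng(0), 6)
        net = binarize_at_sparsity(z, 1.0)
        expected = 1 - np.eye(6, dtype=np.int8)
        np.testing.assert_array_equal(net.adjacency, expected)

    def test_top_k_edges_match_sort_oracle(self):
        rng = np.random.default_rng(1)
        z = _random_z(rng, 4)
        s = 2 / 6  # k = 2 of the 6 pairs
        net = binarize_at_sparsity(z, s)
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        top2 = sorted(pairs, key=lambda p: -z.values[p])[:2]
        for i, j in pairs:
            assert net.adjacency[i, j] == ((i, j) in top2)

    def test_all_equal_values_tie_broken_deterministically(self):
        z = ZMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        nets = [binarize_at_sparsity(z, 0.5) for _ in range(3)]
        assert nets[0].n_edges == 3  # k = round(0.5 * 6)
        for net in nets[1:]:
            np.testing.assert_array_equal(net.adjacency, nets[0].adjacency)
        # lexicographically smallest pairs win: (0,1), (0,2), (0,3)
        assert nets[0].adjacency[0].sum() == 3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(5, 12))
    def test_density_exact_on_grid(self, seed, r):
        z = _random_z(np.random.default_rng(seed), r)
        n_pairs = r * (r - 1) // 2
        for s in (0.01, 0.19, 0.5, 0.77, 1.0):
            net = binarize_at_sparsity(z, s)
            assert net.n_edges == int(round(s * n_pairs))

    def test_rank_invariance_under_fisher_transform(self):
        # atanh is strictly increasing, so thresholding r or z is identical
        rng = np.random.default_rng(3)
        data = rng.standard_normal((60, 8))
        c = correlation_matrix(_ts(data))
        z = fisher_z(c)
        r_as_z = ZMatrix(c.values - np.eye(8), c.roi_names)
        for s in (0.1, 0.19, 0.4):
            np.testing.assert_array_equal(binarize_at_sparsity(z, s).adjacency,
                                          binarize_at_sparsity(r_as_z, s).adjacency)

    def test_absolute_ranking_keeps_strong_negative_edges(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = -0.9
        vals[0, 2] = vals[2, 0] = 0.2
        vals[1, 2] = vals[2, 1] = 0.1
        z = ZMatrix(vals, list("abc"))
        signed = binarize_at_sparsity(z, 1 / 3, ranking="signed")
        absolute = binarize_at_sparsity(z, 1 / 3, ranking="absolute")
        assert signed.adjacency[0, 2] == 1 and signed.adjacency[0, 1] == 0
        assert absolute.adjacency[0, 1] == 1 and absolute.adjacency[0, 2] == 0

    def test_out_of_range_sparsity_rejected(self):
        z = _random_z(np.random.default_rng(0), 4)
        for s in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                binarize_at_sparsity(z, s)


class TestConnectivity:
    def _net(self, edges, n):
        adj = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            adj[i, j] = adj[j, i] = 1
        return BinaryNetwork(adj, adj.sum() / (n * (n - 1)), [f"r{i}" for i in range(n)])

    def test_path_graph_connected(self):
        assert is_connected(self._net([(0, 1), (1, 2)], 3))

    def test_disjoint_edges_disconnected(self):
        assert not is_connected(self._net([(0, 1), (2, 3)], 4))

    def test_agrees_with_union_find_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            adj = np.triu((rng.random((n, n)) < rng.uniform(0.05, 0.6)), 1)
            adj = (adj + adj.T).astype(np.int8)
            net = self._net([], n)
            net.adjacency = adj
            assert is_connected(net) == union_find_connected(adj)


class TestMinimumCommonSparsity:
    def test_spanning_tree_subject(self):
        # star-like z: node 0 strongly tied to everyone; top R-1 edges span
        r = 8
        vals = np.full((r, r), -1.0)
        vals[0, :] = vals[:, 0] = 1.0
        np.fill_diagonal(vals, 0.0)
        z = ZMatrix(vals, [f"r{i}" for i in range(r)])
        n_pairs = r * (r - 1) // 2
        got = minimum_common_sparsity([z], SparsityGrid(0.01, 1.0, 0.01))
        grid = SparsityGrid(0.01, 1.0, 0.01).values()
        expected = grid[np.searchsorted(np.round(grid * n_pairs), r - 1)]
        assert got == pytest.approx(expected)

    def test_duplication_invariance(self):
        z = _random_z(np.random.default_rng(5), 10)
        single = minimum_common_sparsity([z])
        assert minimum_common_sparsity([z, z, z]) == single

    def test_adversarial_subject_sets_the_maximum(self):
        rng = np.random.default_rng(6)
        zs = [_random_z(rng, 10) for _ in range(5)]
        joint = minimum_common_sparsity(zs)
        solo = max(minimum_common_sparsity([z]) for z in zs)
        assert joint == solo

    def test_connectivity_monotone_across_grid(self):
        rng = np.random.default_rng(7)
        z = _random_z(rng, 12)
        grid = SparsityGrid().values()
        connected = [is_connected(binarize_at_sparsity(z, s)) for s in grid]
        first = connected.index(True)
        assert all(connected[first:])

    def test_infeasible_grid_reports_subjects(self):
        # two isolated cliques: never connected at any sparsity on a tiny grid
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = vals[2, 3] = vals[3, 2] = 1.0
        z = ZMatrix(vals, list("abcd"))
        with pytest.raises(ValueError, match="subject 0"):
            minimum_common_sparsity([z], SparsityGrid(0.01, 0.3, 0.01))

    def test_mismatched_sizes_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            minimum_common_sparsity([_random_z(rng, 5), _random_z(rng, 6)])
        with pytest.raises(ValueError):
            minimum_common_sparsity([])


def test_sparsity_grid_values():
    grid = SparsityGrid(0.01, 0.5, 0.01).values()
    assert grid[0] == 0.01 and grid[-1] == 0.5 and len(grid) == 50
    with pytest.raises(ValueError):
        SparsityGrid(0.0, 0.5, 0.01)
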