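"""Mutual-information estimation, DPI pruning, thresholding, clusters."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oncotrack import synthetic_data as synth
from oncotrack.mi_network import (
    dpi_prune,
    entropy,
    extract_clusters,
    mi_matrix,
    mutual_information_knn,
    mutual_information_plugin,
    read_edge_list,
    threshold_network,
    write_edge_list,
)


class TestEntropy:
    def test_point_mass_is_zero(self):
        assert entropy([1.0, 0.0, 0.0]) == 0.0

    def test_uniform_four_states(self):
        assert entropy([0.25] * 4) == pytest.approx(np.log(4))

    def test_half_quarter_quarter(self):
        assert entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            entropy([0.5, 0.6])


class TestPluginMi:
    def test_independent_table_is_zero(self):
        px = np.array([0.2, 0.3, 0.5])
        py = np.array([0.6, 0.4])
        joint = np.outer(px, py) * 1000
        assert abs(mutual_information_plugin(joint)) < 1e-12

    def test_identical_fair_bits_give_ln2(self):
        joint = np.array([[50, 0], [0, 50]])
        assert mutual_information_plugin(joint) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_direct_kl_formula(self, rng):
        """Plug-in MI equals the sum p(x,y) ln(p(x,y)/(p(x)p(y)))."""
        for _ in range(10):
            table = rng.integers(1, 30, size=(3, 3)).astype(float)
            p = table / table.sum()
            px, py = p.sum(1), p.sum(0)
            direct = sum(
                p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
                for i in range(3) for j in range(3) if p[i, j] > 0
            )
            assert mutual_information_plugin(table) == pytest.approx(direct, abs=1e-12)

    def test_bounded_by_marginal_entropies(self, rng):
        for _ in range(20):
            table = rng.integers(0, 20, size=(4, 4)).astype(float)
            if table.sum() == 0:
                continue
            p = table / table.sum()
            mi = mutual_information_plugin(table)
            assert -1e-12 <= mi <= min(entropy(p.sum(1)), entropy(p.sum(0))) + 1e-12


class TestKnnMi:
    def test_independent_near_zero(self, rng):
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert abs(mutual_information_knn(x, y, seed=1)) < 0.05

    def test_gaussian_closed_form(self, rng):
        rho = 0.9
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000)
        mi = mutual_information_knn(xy[:, 0], xy[:, 1], seed=1)
        assert mi == pytest.approx(-0.5 * np.log(1 - rho ** 2), abs=0.1)

    def test_low_bias_across_seeds(self):
        """Mean over 20 seeds at rho = 0.6 sits within 0.05 of the truth."""
        rho = 0.6
        truth = -0.5 * np.log(1 - rho ** 2)
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000)
            vals.append(mutual_information_knn(xy[:, 0], xy[:, 1], seed=seed))
        assert np.mean(vals) == pytest.approx(truth, abs=0.05)

    def test_identity_dominates_noisy_pairs(self, rng):
        x = rng.normal(size=500)
        noisy = x + rng.normal(0, 0.5, 500)
        assert mutual_information_knn(x, x.copy(), seed=2) > \
            mutual_information_knn(x, noisy, seed=2)

    def test_constant_vector_returns_zero(self, rng):
        assert mutual_information_knn(np.ones(50), rng.normal(size=50)) == 0.0

    def test_deterministic_given_seed(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert mutual_information_knn(x, y, seed=5) == \
            mutual_information_knn(x, y, seed=5)


class TestMiMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 20)))
        mi = mi_matrix(m, seed=0)
        np.testing.assert_allclose(mi, mi.T)
        assert np.all(np.diag(mi) == 0)

    def test_duplicated_rows_are_row_maximum(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 40)), index=list("abcde"))
        m.loc["e"] = m.loc["a"]
        mi = mi_matrix(m, seed=0)
        assert mi.loc["a", "e"] == pytest.approx(mi.loc["a"].max())

    def test_sample_permutation_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 30)))
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            mi_matrix(m, seed=0), mi_matrix(m.iloc[:, perm], seed=0))

    def test_planted_modules_have_higher_within_mi(self):
        matrix, labels = synth.simulate_modular_expression(
            9, [8, 8], n_samples=60, rho_within=0.9)
        mi = mi_matrix(matrix, seed=0).to_numpy()
        same = np.equal.outer(labels.to_numpy(), labels.to_numpy())
        off = ~np.eye(len(labels), dtype=bool)
        assert mi[same & off].mean() > mi[~same].mean()


class TestDpi:
    @staticmethod
    def brute_force(m, eps):
        p = m.shape[0]
        keep = np.ones((p, p), bool)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                for k in range(p):
                    if k in (i, j):
                        continue
                    if m[i, j] < min(m[i, k], m[j, k]) - eps:
                        keep[i, j] = False
        out = np.where(keep & keep.T, m, 0.0)
        np.fill_diagonal(out, 0.0)
        return out

    @pytest.mark.parametrize("eps", [0.0, 0.05, 0.3])
    def test_matches_brute_force_triple_scan(self, eps, rng):
        for _ in range(15):
            p = int(rng.integers(3, 9))
            m = rng.random((p, p))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mi = pd.DataFrame(m)
            np.testing.assert_allclose(
                dpi_prune(mi, eps).to_numpy(), self.brute_force(m, eps))

    def test_markov_chain_indirect_edge_removed(self):
        """X -> Y -> Z: the data-processing inequality forces MI(X,Z) lowest."""
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.integers(0, 3, n)
        y = np.where(rng.random(n) < 0.8, x, rng.integers(0, 3, n))
        z = np.where(rng.random(n) < 0.8, y, rng.integers(0, 3, n))

        def mi_pair(a, b):
            t = np.zeros((3, 3))
            np.add.at(t, (a, b), 1)
            return mutual_information_plugin(t)

        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = mi_pair(x, y)
        m[1, 2] = m[2, 1] = mi_pair(y, z)
        m[0, 2] = m[2, 0] = mi_pair(x, z)
        pruned = dpi_prune(pd.DataFrame(m, index=list("XYZ"), columns=list("XYZ")),
                           eps=0.0)
        assert pruned.loc["X", "Z"] == 0.0
        assert pruned.loc["X", "Y"] > 0 and pruned.loc["Y", "Z"] > 0

    def test_equal_triangle_untouched(self):
        m = np.full((3, 3), 0.7)
        np.fill_diagonal(m, 0)
        pruned = dpi_prune(pd.DataFrame(m), eps=0.0)
        np.testing.assert_allclose(pruned.to_numpy(), m)

    def test_never_adds_edges_and_eps_orders_strictness(self, rng):
        m = rng.random((10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        mi = pd.DataFrame(m)
        loose = dpi_prune(mi, eps=1e9).to_numpy()
        mid = dpi_prune(mi, eps=0.05).to_numpy()
        strict = dpi_prune(mi, eps=0.0).to_numpy()
        np.testing.assert_allclose(loose, m)  # infinite tolerance removes nothing
        assert (strict > 0).sum() <= (mid > 0).sum() <= (loose > 0).sum()


class TestThresholdAndClusters:
    def mi_frame(self):
        m = np.zeros((5, 5))
        for (i, j), v in {(0, 1): 1.5, (1, 2): 1.2, (3, 4): 0.8}.items():
            m[i, j] = m[j, i] = v
        return pd.DataFrame(m, index=list("abcde"), columns=list("abcde"))

    def test_above_max_gives_empty_network(self):
        assert threshold_network(self.mi_frame(), 99.0).number_of_edges() == 0

    def test_min_mi_zero_keeps_all_nonzero_pairs(self):
        net = threshold_network(self.mi_frame(), 0.0)
        assert net.number_of_edges() == 3

    def test_threshold_keeps_supra_threshold_pairs_and_drops_isolated(self):
        net = threshold_network(self.mi_frame(), 1.0)
        assert sorted(net.edges) == [("a", "b"), ("b", "c")]
        assert "d" not in net  # isolated after thresholding

    def test_strict_vs_inclusive_boundary(self):
        frame = self.mi_frame()
        assert threshold_network(frame, 1.2).number_of_edges() == 2
        assert threshold_network(frame, 1.2, strict=True).number_of_edges() == 1

    def test_clusters_match_bfs_components(self, rng):
        g = nx.gnp_random_graph(40, 0.05, seed=4)
        clusters, sub = extract_clusters(g, min_size=3)
        expected = sorted(
            (set(c) for c in nx.connected_components(g) if len(c) >= 3),
            key=lambda c: (-len(c), min(map(str, c))))
        assert clusters == expected
        assert set(sub.nodes) == set().union(*expected) if expected else True

    def test_min_size_filter(self):
        g = nx.Graph()
        nx.add_path(g, range(12))
        nx.add_path(g, range(100, 104))
        clusters, _ = extract_clusters(g, min_size=10)
        assert [len(c) for c in clusters] == [12]

    def test_empty_network(self):
        clusters, sub = extract_clusters(nx.Graph(), min_size=2)
        assert clusters == [] and sub.number_of_nodes() == 0


def test_edge_list_round_trip(tmp_path, rng):
    g = nx.gnp_random_graph(15, 0.3, seed=2)
    nx.set_edge_attributes(g, {e: {"weight": float(rng.random())} for e in g.edges})
    g = nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes})
    path = tmp_path / "edges.tsv"
    write_edge_list(g, str(path))
    back = read_edge_list(str(path))
    assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))


def test_pipeline_determinism_same_seed_same_network(rng):
    matrix = pd.DataFrame(rng.normal(size=(10, 25)))
    nets = []
    for _ in range(2):
        mi = mi_matrix(matrix, seed=3)
        net = threshold_network(dpi_prune(mi, 0.05), 0.2)
        nets.append(frozenset(map(frozenset, net.edges)))
    assert nets[0] == nets[1]
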