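import math

import numpy as np
import pytest

from driverank.io_formats import PPINetwork
from driverank.kernels import (
    KernelMatrix,
    align_items,
    degree_binned_shuffle,
    degree_kernel,
    diffusion_kernel,
    integrated_kernel,
    mutation_kernel,
    normalized_laplacian,
    permute_kernel,
    ppi_kernel,
)
from driverank.mutation_features import GeneFeatureTable
from driverank.synthetic_data import SyntheticConfig, generate


def feature_table(genes, phi):
    return GeneFeatureTable(mode="TSG", genes=tuple(genes), phi=np.array(phi, dtype=float))


def series_expm(L, terms=30):
    """Independent oracle: truncated series sum_k (-L)^k / k!."""
    n = L.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms + 1):
        term = term @ (-L) / k
        out = out + term
    return out


def random_network(rng, n, p=0.2):
    nodes = tuple(f"N{i:02d}" for i in range(n))
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add(frozenset({nodes[i], nodes[j]}))
    return PPINetwork(nodes=nodes, edges=frozenset(edges))


class TestMutationKernel:
    def test_dot_products_unstandardized(self):
        ft = feature_table(["g1", "g2"], [[1, 2, 0], [0, 1, 1]])
        K = mutation_kernel(ft, standardize=False)
        assert K.loc("g1", "g2") == 2.0
        assert K.loc("g1", "g1") == 5.0

    def test_identical_rows_identical_entries(self):
        ft = feature_table(["a", "b"], [[3, 1, 2], [3, 1, 2]])
        K = mutation_kernel(ft, standardize=False)
        assert K.loc("a", "b") == K.loc("a", "a") == K.loc("b", "b")

    def test_rank_at_most_three(self, rng):
        phi = rng.poisson(3, size=(10, 3)).astype(float)
        K = mutation_kernel(feature_table([f"g{i}" for i in range(10)], phi))
        assert np.linalg.matrix_rank(K.values, tol=1e-8) <= 3

    def test_zero_variance_column_centered(self, caplog):
        ft = feature_table(["a", "b"], [[1, 5, 0], [2, 5, 0]])
        K = mutation_kernel(ft, standardize=True)  # must not raise
        K.check_psd()


class TestNormalizedLaplacian:
    def test_single_edge(self):
        net = PPINetwork(nodes=("A", "B"), edges=frozenset({frozenset({"A", "B"})}))
        L = normalized_laplacian(net)
        np.testing.assert_allclose(L.values, [[1, -1], [-1, 1]], atol=1e-12)

    def test_isolated_node_zero_row(self):
        net = PPINetwork(nodes=("A", "B", "C"), edges=frozenset({frozenset({"A", "B"})}))
        L = normalized_laplacian(net)
        np.testing.assert_array_equal(L.values[2], [0, 0, 0])
        np.testing.assert_array_equal(L.values[:, 2], [0, 0, 0])

    def test_path_off_diagonal(self, path_net):
        L = normalized_laplacian(path_net)
        i, j = L.items.index("A"), L.items.index("B")
        assert math.isclose(L.values[i, j], -1 / math.sqrt(2), rel_tol=1e-12)

    def test_eigenvalues_in_0_2(self, rng):
        net = random_network(rng, 15)
        lam = np.linalg.eigvalsh(normalized_laplacian(net).values)
        assert lam.min() >= -1e-10 and lam.max() <= 2 + 1e-10


class TestDiffusionKernel:
    def test_two_node_closed_form(self):
        net = PPINetwork(nodes=("A", "B"), edges=frozenset({frozenset({"A", "B"})}))
        K = diffusion_kernel(normalized_laplacian(net))
        diag = (1 + math.exp(-2)) / 2
        off = (1 - math.exp(-2)) / 2
        np.testing.assert_allclose(
            K.values, [[diag, off], [off, diag]], rtol=1e-12
        )

    def test_empty_graph_identity(self):
        net = PPINetwork(nodes=("A", "B", "C"), edges=frozenset())
        K = diffusion_kernel(normalized_laplacian(net))
        np.testing.assert_allclose(K.values, np.eye(3), atol=1e-12)

    def test_matches_series_oracle(self, rng):
        for _ in range(5):
            net = random_network(rng, int(rng.integers(5, 21)))
            L = normalized_laplacian(net)
            K = diffusion_kernel(L)
            np.testing.assert_allclose(K.values, series_expm(L.values), atol=1e-8)

    def test_psd(self, rng):
        net = random_network(rng, 12)
        diffusion_kernel(normalized_laplacian(net)).check_psd()

    def test_permutation_equivariance(self, rng):
        net = random_network(rng, 8)
        K = diffusion_kernel(normalized_laplacian(net))
        perm = dict(zip(net.nodes, rng.permutation(net.nodes)))
        K_perm = diffusion_kernel(normalized_laplacian(net.relabel(perm)))
        for a in net.nodes:
            for b in net.nodes:
                assert math.isclose(K.loc(a, b), K_perm.loc(perm[a], perm[b]), rel_tol=1e-9)

    def test_component_support(self):
        # two components: edge A-B and edge C-D
        net = PPINetwork(
            nodes=("A", "B", "C", "D"),
            edges=frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}),
        )
        K = diffusion_kernel(normalized_laplacian(net))
        assert K.loc("A", "B") > 0
        assert K.loc("A", "C") == pytest.approx(0.0, abs=1e-15)


class TestDegreeKernel:
    def test_path(self, path_net):
        K = degree_kernel(path_net)
        np.testing.assert_array_equal(K.values, [[1, 2, 1], [2, 4, 2], [1, 2, 1]])

    def test_isolated_zero(self):
        net = PPINetwork(nodes=("A", "B", "C"), edges=frozenset({frozenset({"A", "B"})}))
        K = degree_kernel(net)
        assert np.all(K.values[K.items.index("C")] == 0)

    def test_rank_one(self, rng):
        net = random_network(rng, 10)
        assert np.linalg.matrix_rank(degree_kernel(net).values, tol=1e-8) <= 1


class TestIntegratedKernel:
    def test_self_average_identity(self, rng):
        net = random_network(rng, 6)
        K = diffusion_kernel(normalized_laplacian(net))
        np.testing.assert_array_equal(integrated_kernel(K, K).values, K.values)

    def test_identity_plus_zero(self):
        items = ("a", "b")
        K1 = KernelMatrix(items, np.eye(2))
        K2 = KernelMatrix(items, np.zeros((2, 2)))
        np.testing.assert_array_equal(integrated_kernel(K1, K2).values, np.eye(2) / 2)

    def test_mismatch_names_difference(self):
        K1 = KernelMatrix(("a", "b"), np.eye(2))
        K2 = KernelMatrix(("a", "c"), np.eye(2))
        with pytest.raises(ValueError, match="'b'"):
            integrated_kernel(K1, K2)

    def test_psd_preserved(self, rng):
        net = random_network(rng, 8)
        K1 = diffusion_kernel(normalized_laplacian(net))
        K2 = degree_kernel(net)
        assert integrated_kernel(K1, K2).min_eigenvalue() >= -1e-8


class TestDegreeBinnedShuffle:
    def test_singleton_bins_identity(self, path_net):
        mapping = degree_binned_shuffle(path_net, n_bins=3, seed=0)
        assert mapping == {g: g for g in path_net.nodes}

    def test_degree_multiset_preserved_within_bins(self, rng):
        net = random_network(rng, 30)
        deg = net.degree
        mapping = degree_binned_shuffle(net, n_bins=5, seed=7)
        ordered = sorted(net.nodes, key=lambda g: (-deg[g], g))
        for start in range(0, 30, 6):
            bin_nodes = ordered[start : start + 6]
            assert sorted(mapping[g] for g in bin_nodes) == sorted(bin_nodes)

    def test_seed_reproducibility(self, rng):
        net = random_network(rng, 25)
        maps = [degree_binned_shuffle(net, n_bins=5, seed=s) for s in range(20)]
        again = [degree_binned_shuffle(net, n_bins=5, seed=s) for s in range(20)]
        assert maps == again

    def test_permute_kernel_matches_relabeled_network(self, rng):
        net = random_network(rng, 10)
        K = ppi_kernel(net)
        mapping = degree_binned_shuffle(net, n_bins=3, seed=2)
        K_fast = permute_kernel(K, mapping)
        K_slow = ppi_kernel(net.relabel(mapping))
        for a in net.nodes:
            for b in net.nodes:
                assert math.isclose(K_fast.loc(a, b), K_slow.loc(a, b), abs_tol=1e-10)


class TestAlignItems:
    def test_isolated_extension(self):
        K = KernelMatrix(("A", "B"), np.array([[1.0, 0.3], [0.3, 1.0]]))
        K2 = align_items(K, ("A", "B", "C"), fill_diag=1.0)
        assert K2.loc("C", "C") == 1.0
        assert K2.loc("C", "A") == 0.0

    def test_idempotent(self):
        K = KernelMatrix(("A",), np.array([[2.0]]))
        once = align_items(K, ("A", "B"), fill_diag=1.0)
        twice = align_items(once, ("A", "B"), fill_diag=1.0)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_psd_preserved(self, rng):
        net = random_network(rng, 6)
        K = diffusion_kernel(normalized_laplacian(net))
        aligned = align_items(K, tuple(sorted(set(net.nodes) | {"X", "Y"})), fill_diag=1.0)
        assert aligned.min_eigenvalue() >= -1e-8


def test_all_synthetic_kernels_psd():
    table, net, truth, _ = generate(SyntheticConfig(n_genes=60, n_samples=20, n_drivers=5, seed=0))
    from driverank.evaluation import build_gene_kernel

    for choice in ("mutation", "ppi", "degree", "mutation+ppi", "mutation+degree"):
        K = build_gene_kernel(table, net, mode="TSG", choice=choice)
        assert K.min_eigenvalue() >= -1e-8
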