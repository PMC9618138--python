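import numpy as np
import pytest
import scipy.sparse as sparse

from ecotraitmap.abundance_io import AbundanceTable
from ecotraitmap.diffusion_map import (DistanceMatrix, SimilarityMatrix,
                                       TrustedNetwork, diffusion_distance,
                                       embed, infer_traits, laplacian,
                                       spearman_similarity, trusted_links)


def table_from(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return AbundanceTable([f"sp{i}" for i in range(matrix.shape[0])],
                          [f"s{j}" for j in range(matrix.shape[1])], matrix)


class TestSpearmanSimilarity:
    def test_identical_vectors_give_one(self):
        t = table_from([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        S = spearman_similarity(t).S_full
        assert S[0, 1] == pytest.approx(1.0)

    def test_rank_difference_formula_example(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/120 = 0.8
        t = table_from([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5], [5, 4, 3, 2, 1]])
        S = spearman_similarity(t).S_full
        assert S[0, 1] == pytest.approx(0.8)

    def test_reversed_vectors_give_minus_one(self):
        t = table_from([[1, 2, 3], [3, 2, 1], [2, 1, 3]])
        assert spearman_similarity(t).S_full[0, 1] == pytest.approx(-1.0)

    def test_constant_species_is_error(self):
        t = table_from([[1, 1, 1], [1, 2, 3], [3, 1, 2]])
        with pytest.raises(ValueError, match="min_occurrence"):
            spearman_similarity(t)

    def test_zeros_participate_as_ties(self):
        t = table_from([[0, 0, 1, 2], [0, 0, 2, 1], [1, 2, 0, 0]])
        S = spearman_similarity(t).S_full
        # shared zero block makes the pair strongly but not perfectly correlated
        assert 0 < S[0, 1] < 1


class TestTrustedLinks:
    def test_exhaustive_k1_example(self):
        # nominations: 1->2 (0.9), 2->1 (0.9), 3->2 (0.8), 4->3 (0.7)
        S = np.zeros((4, 4))
        S[0, 1] = 0.9; S[0, 2] = 0.5; S[0, 3] = 0.1
        S[1, 2] = 0.8; S[1, 3] = 0.2; S[2, 3] = 0.7
        S = S + S.T
        net = trusted_links(SimilarityMatrix(list("abcd"), S), k=1)
        W = net.S.toarray()
        edges = {(i, j) for i in range(4) for j in range(i + 1, 4) if W[i, j] > 0}
        assert edges == {(0, 1), (1, 2), (2, 3)}

    def test_k_at_least_n_minus_1_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(0.1, 0.9, (6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        net = trusted_links(SimilarityMatrix([str(i) for i in range(6)], S), k=10)
        W = net.S.toarray()
        assert ((W > 0).sum(axis=1) == 5).all()

    def test_degree_lower_bound_union_rule(self):
        # with nonnegative similarities every node keeps its k nominations
        rng = np.random.default_rng(1)
        for trial in range(5):
            n = int(rng.integers(5, 15))
            S = rng.uniform(0.01, 1, (n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 0)
            net = trusted_links(SimilarityMatrix([str(i) for i in range(n)], S), k=3)
            deg = net.degrees()
            assert (deg >= min(3, n - 1)).all()
            assert (deg <= n - 1).all()

    def test_tied_kth_rank_all_admitted(self):
        S = np.array([[0.0, 0.5, 0.5, 0.1],
                      [0.5, 0.0, 0.2, 0.2],
                      [0.5, 0.2, 0.0, 0.3],
                      [0.1, 0.2, 0.3, 0.0]])
        net = trusted_links(SimilarityMatrix(list("abcd"), S), k=1)
        W = net.S.toarray()
        # node a ties b and c at rank 1: both links retained
        assert W[0, 1] > 0 and W[0, 2] > 0


class TestLaplacian:
    def test_path_of_three_matrix(self, path3_network):
        L, ids = laplacian(path3_network)
        np.testing.assert_array_equal(L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])
        assert ids == ["a", "b", "c"]

    def test_row_sums_zero_on_random_network(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 1, (8, 8))
        W = np.triu(W, 1); W = W + W.T
        net = TrustedNetwork([str(i) for i in range(8)], sparse.csr_matrix(W), 3)
        L, _ = laplacian(net)
        np.testing.assert_allclose(L.sum(axis=1), 0, atol=1e-12)

    def test_path_of_three_eigenvalues(self, path3_network):
        L, _ = laplacian(path3_network)
        np.testing.assert_allclose(np.linalg.eigvalsh(L), [0, 1, 3], atol=1e-12)

    def test_empty_network_error(self):
        net = TrustedNetwork(["a", "b"], sparse.csr_matrix((2, 2)), 1)
        with pytest.raises(ValueError, match="empty"):
            laplacian(net)


class TestEmbed:
    def test_path_of_three_coordinates(self, path3_network):
        ts = embed(path3_network, 2)
        np.testing.assert_allclose(ts.eigenvalues, [1.0, 3.0], atol=1e-12)
        s2, s6 = 1 / np.sqrt(2), 1 / np.sqrt(6)
        # axis 1 has two tied-magnitude entries, so only the shape is pinned
        np.testing.assert_allclose(np.abs(ts.coords[:, 0]), [s2, 0, s2], atol=1e-9)
        assert ts.coords[0, 0] * ts.coords[2, 0] < 0
        np.testing.assert_allclose(np.abs(ts.coords[:, 1]),
                                   np.array([s6, 2 * s6, s6]) / 3, atol=1e-9)
        assert ts.coords[1, 1] > 0  # largest-magnitude entry oriented positive

    def test_axis_importance_non_increasing(self, small_sim):
        _, _, table = small_sim
        ts = infer_traits(table, n_axes=10)
        norms = np.linalg.norm(ts.coords, axis=0)
        assert (np.diff(norms) <= 1e-9).all()

    def test_eigenvectors_orthogonal_and_nonconstant(self, small_sim):
        _, _, table = small_sim
        ts = infer_traits(table, n_axes=6)
        V = ts.coords * ts.eigenvalues[None, :]  # back to unit eigenvectors
        G = V.T @ V
        np.testing.assert_allclose(G, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(V.sum(axis=0), 0, atol=1e-8)

    def test_too_many_axes_rejected(self, path3_network):
        with pytest.raises(ValueError, match="n_axes"):
            embed(path3_network, 3)


class TestDiffusionDistance:
    def test_path_of_three_worked_distances(self, path3_network):
        ts = embed(path3_network, 2)
        D = diffusion_distance(ts).D
        assert D[0, 2] == pytest.approx(np.sqrt(2), abs=1e-9)
        assert D[0, 1] == pytest.approx(np.sqrt(0.5 + (1.2247448 / 3) ** 2), abs=1e-6)
        np.testing.assert_allclose(np.diag(D), 0, atol=1e-12)

    def test_complete_graph_equidistant(self):
        W = np.ones((5, 5)) - np.eye(5)
        net = TrustedNetwork([str(i) for i in range(5)], sparse.csr_matrix(W), 4)
        D = diffusion_distance(embed(net, 4)).D
        off = D[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, off[0], atol=1e-9)

    def test_truncation_monotone(self, small_sim):
        _, _, table = small_sim
        ts_full = infer_traits(table, n_axes=12)
        D12 = diffusion_distance(ts_full).D
        ts6 = infer_traits(table, n_axes=6)
        D6 = diffusion_distance(ts6).D
        assert (D6 <= D12 + 1e-9).all()

    def test_unknown_species_error(self, path3_network):
        ts = embed(path3_network, 2)
        with pytest.raises(KeyError, match="zz"):
            diffusion_distance(ts, ["a", "zz"])


def random_connected_network(rng, n):
    """Random weighted graph guaranteed connected via a random spanning tree."""
    W = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        W[order[i], j] = W[j, order[i]] = rng.uniform(0.2, 1.0)
    extra = rng.uniform(0, 1, (n, n)) < 0.3
    vals = rng.uniform(0.2, 1.0, (n, n))
    W = np.maximum(W, np.triu(extra * vals, 1))
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0)
    return TrustedNetwork([str(i) for i in range(n)], sparse.csr_matrix(W), n - 1)


def brute_force_diffusion_distance(W):
    """Independent oracle: full dense eigendecomposition + direct double loop."""
    L = np.diag(W.sum(axis=1)) - W
    lam, V = np.linalg.eigh(L)
    n = len(W)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(1, n):  # skip the zero eigenvalue
                acc += (V[i, k] - V[j, k]) ** 2 / lam[k] ** 2
            D[i, j] = np.sqrt(acc)
    return D


def test_oracle_equivalence_on_random_connected_graphs():
    """Spectral-embedding distances match the brute-force double loop."""
    rng = np.random.default_rng(42)
    for trial in range(100):
        n = int(rng.integers(4, 13))
        net = random_connected_network(rng, n)
        ts = embed(net, n - 1)
        D = diffusion_distance(ts).D
        D_oracle = brute_force_diffusion_distance(net.S.toarray())
        np.testing.assert_allclose(D, D_oracle, atol=1e-8)


def test_pipeline_permutation_equivariance(small_sim):
    """Relabelling species permutes coordinates and distances consistently."""
    _, _, table = small_sim
    ts = infer_traits(table, n_axes=5)
    rng = np.random.default_rng(7)
    perm = rng.permutation(table.n_species)
    shuffled = AbundanceTable([table.species_ids[i] for i in perm],
                              list(table.sample_ids), table.biomass[perm],
                              table.sample_meta)
    ts_p = infer_traits(shuffled, n_axes=5)
    np.testing.assert_allclose(ts_p.eigenvalues, ts.eigenvalues, atol=1e-9)
    D = diffusion_distance(ts, sorted(ts.species_ids)).D
    D_p = diffusion_distance(ts_p, sorted(ts_p.species_ids)).D
    np.testing.assert_allclose(D_p, D, atol=1e-7)


def test_distance_matrix_round_trip(tmp_path, path3_network):
    D = diffusion_distance(embed(path3_network, 2))
    path = tmp_path / "d.csv"
    D.to_csv(path)
    back = DistanceMatrix.from_csv(path)
    assert back.species_ids == D.species_ids
    np.testing.assert_allclose(back.D, D.D, atol=1e-12)


def test_trait_space_round_trip(tmp_path, small_sim):
    _, _, table = small_sim
    ts = infer_traits(table, n_axes=4)
    prefix = str(tmp_path / "ts_")
    ts.to_csv(prefix)
    from ecotraitmap.diffusion_map import TraitSpace
    back = TraitSpace.from_csv(prefix)
    assert back.species_ids == ts.species_ids
    np.testing.assert_allclose(back.coords, ts.coords, atol=1e-12)
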