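"""Embedding, k-NN graph, Laplacian eigenmaps and graph cutting, each
checked against small closed-form or brute-force constructions."""

import numpy as np
import pytest
from scipy import sparse

from ploidbin.clustering import (BinningState, cluster, embed, knn_graph,
                                 spectral_embed)
from ploidbin.fragmentation import Fragment, FragmentSet


def _fragment_set(n, length=100):
    frs = [Fragment(f"s::{i * length}-{(i + 1) * length}", "s", i * length,
                    (i + 1) * length) for i in range(n)]
    return FragmentSet(frs, length, 1)


class TestEmbed:
    def test_proportional_rows_coincide(self):
        x = np.array([1.0, 2.0, 0.0, 1.0])
        X = sparse.csr_matrix(np.vstack([x, 3 * x, [0, 0, 5, 0], [1, 0, 4, 2]]))
        emb = embed(X, d=2, seed=0)
        assert np.allclose(emb.coords[0], emb.coords[1], atol=1e-8)

    def test_zero_rows_collapse_to_one_point(self):
        X = sparse.csr_matrix(np.array([
            [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0], [0, 0, 0]]))
        emb = embed(X, d=2, seed=0)
        assert np.allclose(emb.coords[3], emb.coords[4], atol=1e-8)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(3)
        X = sparse.csr_matrix(rng.poisson(2.0, size=(30, 50)).astype(float))
        d1 = embed(X, d=3, seed=5).coords
        d2 = embed(X, d=3, seed=5).coords
        assert np.allclose(d1, d2, atol=1e-8)

    def test_too_few_nonzero_rows_is_fatal(self):
        X = sparse.csr_matrix(np.array([[1.0, 0], [0, 0], [0, 0], [0, 0]]))
        with pytest.raises(ValueError, match="repeat k-mers"):
            embed(X, d=3)


class TestKnnGraph:
    def test_collinear_points_symmetrization(self):
        coords = np.array([[0.0], [1.0], [2.0]])
        adj = knn_graph(coords, n_neighbors=1).toarray()
        # ends both pick the middle, so it ends with degree 2
        assert adj.sum(axis=1).tolist() == [1, 2, 1]
        assert np.allclose(adj, adj.T)
        assert np.all(np.diag(adj) == 0)

    def test_complete_graph_when_k_is_n_minus_1(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(8, 2))
        adj = knn_graph(coords, n_neighbors=7).toarray()
        assert np.array_equal(adj, 1 - np.eye(8))

    def test_separated_clouds_have_no_cross_edges(self):
        rng = np.random.default_rng(1)
        a = rng.normal(scale=0.5, size=(25, 2))
        b = rng.normal(scale=0.5, size=(25, 2)) + 100.0
        adj = knn_graph(np.vstack([a, b]), n_neighbors=20).toarray()
        assert adj[:25, 25:].sum() == 0
        # oracle: every within-cloud distance beats every cross-cloud one
        from scipy.spatial.distance import cdist
        assert cdist(a, a).max() < cdist(a, b).min()

    def test_n_neighbors_must_be_less_than_n(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((3, 2)), n_neighbors=3)


def _dense_laplacian_coords(adj: np.ndarray, d_spec: int) -> np.ndarray:
    """Independent brute-force Laplacian eigenmaps for the oracle check."""
    deg = adj.sum(axis=1)
    keep = deg > 0
    sub = adj[np.ix_(keep, keep)]
    dsub = sub.sum(axis=1)
    lap = np.eye(sub.shape[0]) - sub / np.sqrt(np.outer(dsub, dsub))
    w, v = np.linalg.eigh(lap)
    order = np.argsort(w)
    vecs = v[:, order[1 : d_spec + 1]]
    out = np.zeros((adj.shape[0], vecs.shape[1]))
    out[keep] = vecs
    return out


class TestSpectralEmbed:
    def test_two_components_give_piecewise_constant_eigenvector(self):
        blocks = np.kron(np.eye(2), np.ones((4, 4))) - np.eye(8)
        coords, isolated = spectral_embed(sparse.csr_matrix(blocks), d_spec=1)
        assert not isolated.any()
        first, second = coords[:4, 0], coords[4:, 0]
        assert np.allclose(first, first[0], atol=1e-8)
        assert np.allclose(second, second[0], atol=1e-8)

    def test_complete_graph_nontrivial_eigenvalues(self):
        # normalized Laplacian of K_n has nontrivial eigenvalues n/(n-1)
        n = 7
        adj = sparse.csr_matrix(np.ones((n, n)) - np.eye(n))
        deg = np.full(n, n - 1.0)
        lap = np.eye(n) - adj.toarray() / deg
        eigvals = np.sort(np.linalg.eigvalsh(lap))
        assert np.allclose(eigvals[1:], n / (n - 1), atol=1e-8)
        coords, _ = spectral_embed(adj, d_spec=2)  # runs without error
        assert coords.shape == (n, 2)

    def test_isolated_node_does_not_perturb_others(self):
        rng = np.random.default_rng(2)
        base = (rng.random((10, 10)) < 0.4).astype(float)
        base = np.triu(base, 1)
        base = base + base.T
        base[base.sum(axis=1) == 0, 0] = 1  # ensure no isolated in the base
        base[0, base.sum(axis=1) == 0] = 1
        with_iso = np.zeros((11, 11))
        with_iso[:10, :10] = base
        c1, iso1 = spectral_embed(sparse.csr_matrix(base), d_spec=2)
        c2, iso2 = spectral_embed(sparse.csr_matrix(with_iso), d_spec=2)
        assert iso2[10] and not iso2[:10].any()
        assert np.allclose(c1, c2[:10], atol=1e-8)
        assert np.allclose(c2[10], 0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for trial in range(3):
            n = 40
            adj = (rng.random((n, n)) < 0.15).astype(float)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            coords, _ = spectral_embed(sparse.csr_matrix(adj), d_spec=3)
            oracle = _dense_laplacian_coords(adj, 3)
            for j in range(3):
                dot = coords[:, j] @ oracle[:, j]
                norm = np.linalg.norm(coords[:, j]) * np.linalg.norm(oracle[:, j])
                if norm > 1e-12:
                    assert abs(abs(dot) / norm - 1) < 1e-6  # equal up to sign


class TestCluster:
    def test_two_cliques_split_exactly(self):
        # the component-indicator structure lives in the first nontrivial
        # eigenvector; cut on it alone (higher ones are arbitrary within the
        # degenerate clique eigenspace)
        blocks = np.kron(np.eye(2), np.ones((5, 5))) - np.eye(10)
        coords, isolated = spectral_embed(sparse.csr_matrix(blocks), d_spec=1)
        bins = cluster(coords, 2, _fragment_set(10), seed=0, isolated=isolated)
        assert len(set(bins.labels[:5])) == 1
        assert len(set(bins.labels[5:])) == 1
        assert bins.labels[0] != bins.labels[5]

    def test_degenerate_identical_points(self, caplog):
        coords = np.zeros((6, 2))
        with caplog.at_level("WARNING"):
            bins = cluster(coords, 2, _fragment_set(6), seed=0)
        assert set(bins.labels.tolist()) == {0}

    def test_partition_invariant_to_label_names(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        a = cluster(coords, 2, _fragment_set(20), seed=0)
        b = cluster(coords, 2, _fragment_set(20), seed=99)
        # compare partitions, not label strings
        same = {frozenset(np.flatnonzero(a.labels == lab)) for lab in (0, 1)}
        other = {frozenset(np.flatnonzero(b.labels == lab)) for lab in (0, 1)}
        assert same == other

    def test_bayesian_gmm_marks_uncertain_points_ambiguous(self):
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.normal(-3, 0.2, (20, 1)), rng.normal(3, 0.2, (20, 1)),
                            [[0.0]]])  # midpoint has split responsibility
        bins = cluster(coords, 2, _fragment_set(41), method="bayesian_gmm", seed=0)
        assert bins.labels[-1] == -1
        assert (bins.labels[:40] >= 0).all()

    def test_more_bins_than_fragments_is_fatal(self):
        with pytest.raises(ValueError):
            cluster(np.zeros((3, 2)), 5, _fragment_set(3))


class TestBinningState:
    def test_bp_bookkeeping(self):
        fragments = _fragment_set(4, length=10)
        bins = BinningState(np.array([0, 1, 1, -1], dtype=np.int32), 2, fragments.lengths)
        assert bins.bin_bp.tolist() == [10, 20]
        assert bins.ambiguous_bp == 10
        assert bins.classified_fraction_bp == 0.75
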