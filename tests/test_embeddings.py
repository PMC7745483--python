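"""Graph-embedding methods: spectral oracles, corpus audits, training sanity."""

import numpy as np
import pytest
from scipy.linalg import eigh

from geel import assemble_hetnet, make_embedder, pair_feature
from geel.embeddings import (
    DeepWalkEmbedding,
    GAEEmbedding,
    GraRepEmbedding,
    HOPEEmbedding,
    LaplacianEigenmapsEmbedding,
)


def path_graph(n=3):
    H = np.zeros((n, n))
    for i in range(n - 1):
        H[i, i + 1] = H[i + 1, i] = 1.0
    return H


def eckart_young_error(X, rank):
    """Optimal rank-r Frobenius approximation error from the singular values."""
    s = np.linalg.svd(X, compute_uv=False)
    return np.sqrt((s[rank:] ** 2).sum())


class TestLaplacianEigenmaps:
    def test_path_graph_matches_dense_pencil_oracle(self):
        H = path_graph(3)
        D = np.diag(H.sum(1))
        L = D - H
        vals, vecs = eigh(L, D)
        nonzero = vals[vals > 1e-9]
        assert np.allclose(sorted(nonzero), [1.0, 2.0])
        est = LaplacianEigenmapsEmbedding(n_components=1).fit(H)
        v = est.embedding_[:, 0]
        assert np.isclose(est.eigenvalues_[0], 1.0)
        ref = vecs[:, np.argmin(np.abs(vals - 1.0))]
        assert np.isclose(abs(v @ D @ ref), 1.0, atol=1e-8)

    def test_columns_are_D_orthonormal_and_exclude_constant(self, small_graph):
        est = LaplacianEigenmapsEmbedding(n_components=3).fit(small_graph)
        D = np.diag(small_graph.sum(1))
        V = est.embedding_
        assert np.allclose(V.T @ D @ V, np.eye(3), atol=1e-6)
        assert np.allclose(V.T @ D @ np.ones(6), 0.0, atol=1e-6)

    def test_disconnected_graph_warns(self):
        H = np.zeros((4, 4))
        H[0, 1] = H[1, 0] = 1.0
        H[2, 3] = H[3, 2] = 1.0
        with pytest.warns(UserWarning, match="components"):
            LaplacianEigenmapsEmbedding(n_components=1).fit(H)

    def test_insufficient_rank_raises(self, small_graph):
        with pytest.raises(ValueError):
            LaplacianEigenmapsEmbedding(n_components=6).fit(small_graph)


class TestGraRep:
    def test_rank_truncation_is_svd_optimal(self, small_graph):
        est = GraRepEmbedding(n_components=3, k_step=1).fit(small_graph)
        X = est.targets_[0]
        recon = est.embedding_ @ est.context_[0].T
        achieved = np.linalg.norm(X - recon)
        assert achieved <= eckart_young_error(X, 3) + 1e-8

    def test_permutation_equivariance_of_gram(self, small_graph):
        est = GraRepEmbedding(n_components=2, k_step=1).fit(small_graph)
        perm = np.array([3, 1, 5, 0, 2, 4])
        P = np.eye(6)[perm]
        est_p = GraRepEmbedding(n_components=2, k_step=1).fit(P @ small_graph @ P.T)
        G = est.embedding_ @ est.embedding_.T
        G_p = est_p.embedding_ @ est_p.embedding_.T
        assert np.allclose(G_p, P @ G @ P.T, atol=1e-8)

    def test_zero_degree_node_rejected(self):
        H = np.zeros((3, 3))
        H[0, 1] = H[1, 0] = 1.0
        with pytest.raises(ValueError, match="zero-degree"):
            GraRepEmbedding(n_components=1).fit(H)

    def test_dimension_divisibility_enforced(self, small_graph):
        with pytest.raises(ValueError, match="divisible"):
            GraRepEmbedding(n_components=3, k_step=2).fit(small_graph)


class TestHOPE:
    def test_two_node_closed_form_katz(self):
        """Neumann-series oracle: single edge with decay b gives Katz
        off-diagonal b/(1-b^2) and diagonal b^2/(1-b^2)."""
        H = np.array([[0.0, 1.0], [1.0, 0.0]])
        b = 0.4
        est = HOPEEmbedding(n_components=2, katz_decay=b).fit(H)
        S = est.katz_matrix_
        assert np.isclose(S[0, 1], b / (1 - b**2), atol=1e-12)
        assert np.isclose(S[0, 0], b**2 / (1 - b**2), atol=1e-12)
        Es, Et = est.embedding_[:, :1], est.embedding_[:, 1:]
        achieved = np.linalg.norm(S - Es @ Et.T)
        assert achieved <= eckart_young_error(S, 1) + 1e-8

    def test_reconstruction_is_svd_optimal(self, small_graph):
        est = HOPEEmbedding(n_components=4).fit(small_graph)
        half = 2
        Es, Et = est.embedding_[:, :half], est.embedding_[:, half:]
        achieved = np.linalg.norm(est.katz_matrix_ - Es @ Et.T)
        assert achieved <= eckart_young_error(est.katz_matrix_, half) + 1e-8

    def test_zero_decay_gives_zero_embedding(self, small_graph):
        est = HOPEEmbedding(n_components=2, katz_decay=0.0).fit(small_graph)
        assert np.allclose(est.embedding_, 0.0)

    def test_divergent_decay_reports_spectral_bound(self, small_graph):
        rho = float(np.max(np.abs(np.linalg.eigvalsh(small_graph))))
        with pytest.raises(ValueError, match="spectral_radius"):
            HOPEEmbedding(n_components=2, katz_decay=2.0 / rho).fit(small_graph)


class TestDeepWalk:
    def test_corpus_size_and_edge_validity(self, small_graph):
        est = DeepWalkEmbedding(n_components=2, walk_length=12, walks_per_vertex=4, window=3, epochs=1)
        walks = est.generate_walks(small_graph, np.random.default_rng(0))
        n = small_graph.shape[0]
        assert walks.shape == (n * 4, 12)
        assert set(walks[:, 0]) == set(range(n))  # every node starts its walks
        for walk in walks:
            for a, b in zip(walk[:-1], walk[1:]):
                assert small_graph[a, b] > 0

    def test_isolated_node_walks_in_place(self):
        H = np.zeros((3, 3))
        H[0, 1] = H[1, 0] = 1.0
        est = DeepWalkEmbedding(n_components=1, walk_length=5, walks_per_vertex=1, window=2, epochs=1)
        walks = est.generate_walks(H, np.random.default_rng(0))
        iso = walks[walks[:, 0] == 2][0]
        assert (iso == 2).all()

    def test_clique_separation_across_seeds(self):
        n = 20
        H = np.zeros((n, n))
        H[:10, :10] = 1.0
        H[10:, 10:] = 1.0
        np.fill_diagonal(H, 0.0)
        wins = 0
        for seed in range(5):
            est = DeepWalkEmbedding(
                n_components=8, walk_length=30, walks_per_vertex=8, window=4, epochs=5, random_state=seed
            ).fit(H)
            E = est.embedding_
            En = E / np.linalg.norm(E, axis=1, keepdims=True)
            C = En @ En.T
            intra = ((C[:10, :10].sum() - 10) / 90 + (C[10:, 10:].sum() - 10) / 90) / 2
            wins += intra > C[:10, 10:].mean()
        assert wins == 5


class TestGAE:
    def test_training_reduces_reconstruction_loss(self, small_graph):
        est = GAEEmbedding(n_components=2, hidden_size=16, epochs=60, random_state=0).fit(small_graph)
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_decoder_separates_edges_from_nonedges(self, benchmark):
        from sklearn.metrics import roc_auc_score

        net = assemble_hetnet(benchmark["W_l"], benchmark["inter"], benchmark["W_m"])
        aucs = []
        for seed in range(5):
            est = GAEEmbedding(n_components=12, hidden_size=64, epochs=150, random_state=seed).fit(net.H)
            probs = est.decode()
            iu = np.triu_indices_from(net.H, k=1)
            aucs.append(roc_auc_score((net.H[iu] > 0).astype(int), probs[iu]))
        assert np.mean(aucs) > 0.8

    def test_nonvariational_mode_runs(self, small_graph):
        est = GAEEmbedding(n_components=2, hidden_size=8, variational=False, epochs=30).fit(small_graph)
        assert est.embedding_.shape == (6, 2)


class TestPairFeature:
    def test_concatenation_layout(self):
        E = np.array([[1.0, 2.0], [9.0, 9.0], [3.0, 4.0]])
        assert np.array_equal(pair_feature(E, 0, 0, r=2), [1, 2, 3, 4])

    def test_width_and_factorized_structure(self, small_graph):
        est = GraRepEmbedding(n_components=2, k_step=1).fit(small_graph)
        E = est.embedding_
        r = 3
        for i in range(r):
            for j in range(3):
                f = pair_feature(E, i, j, r)
                assert f.shape == (4,)
                assert np.array_equal(f[:2], pair_feature(E, i, (j + 1) % 3, r)[:2])

    def test_out_of_range_indices(self, small_graph):
        E = np.ones((6, 2))
        with pytest.raises(IndexError):
            pair_feature(E, 3, 0, r=3)
        with pytest.raises(IndexError):
            pair_feature(E, 0, 3, r=3)


def test_every_method_finite_on_benchmark(benchmark):
    from geel.evaluation import default_embed_config

    net = assemble_hetnet(benchmark["W_l"], benchmark["inter"], benchmark["W_m"])
    for name, kwargs in default_embed_config(seed=0).items():
        E = make_embedder(name, **kwargs).fit_transform(net.H)
        assert E.shape[0] == net.H.shape[0]
        assert np.isfinite(E).all()
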