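"""GEEL-FI: attention merge, DANN forward/backward, feature integration."""

import numpy as np
import pytest

from geel import DANN, GEELFIClassifier
from geel.geel_fi import attention_merge


def make_views(r, t, d, K, seed=0):
    rng = np.random.default_rng(seed)
    return (
        [rng.standard_normal((r, d)) for _ in range(K)],
        [rng.standard_normal((t, d)) for _ in range(K)],
    )


class TestAttentionMerge:
    def test_single_view_identity(self):
        v = np.arange(6.0).reshape(3, 2)
        assert np.allclose(attention_merge([v], np.array([2.7])), v)

    def test_equal_logits_give_uniform_combination(self):
        v1 = np.array([[2.0, 0.0]])
        v2 = np.array([[0.0, 2.0]])
        merged = attention_merge([v1, v2], np.zeros(2))
        assert np.allclose(merged, [[1.0, 1.0]])

    def test_merged_vector_in_convex_hull(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            views = [rng.standard_normal((4, 3)) for _ in range(3)]
            merged = attention_merge(views, rng.standard_normal(3))
            cap = np.max([np.abs(v).max() for v in views])
            assert np.abs(merged).max() <= cap + 1e-12

    def test_attention_off_is_unweighted_sum(self):
        rng = np.random.default_rng(7)
        views = [rng.standard_normal((4, 3)) for _ in range(3)]
        merged = attention_merge(views, rng.standard_normal(3), attention=False)
        assert np.allclose(merged, sum(views))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            attention_merge([np.ones((2, 2)), np.ones((2, 3))], np.zeros(2))


class TestDANNForward:
    def test_zero_parameters_score_half(self):
        net = DANN(view_dims=[3], pair_dim=6, hidden=(4,), random_state=0)
        for key in net.params:
            net.params[key][:] = 0.0
        F = np.ones((5, 6))
        assert np.allclose(net.forward(F), 0.5)

    def test_dead_relu_layer_passes_bias_chain(self):
        net = DANN(view_dims=[2], pair_dim=4, hidden=(3,), random_state=0)
        net.params["W1"][:] = -1.0  # all-negative pre-activations on positive F
        net.params["b1"][:] = 0.0
        net.params["W2"][:] = 1.0
        net.params["b2"][:] = 0.3
        F = np.ones((2, 4))
        from scipy.special import expit

        assert np.allclose(net.forward(F), expit(0.3))

    def test_matches_hand_rolled_algebra_oracle(self):
        net = DANN(view_dims=[2], pair_dim=4, hidden=(4,), random_state=3)
        F = np.random.default_rng(1).standard_normal((7, 4))
        W1, b1 = net.params["W1"], net.params["b1"]
        W2, b2 = net.params["W2"], net.params["b2"]
        z1 = np.maximum(F @ W1 + b1, 0.0)
        logits = z1 @ W2 + b2
        expected = 1.0 / (1.0 + np.exp(-logits.ravel()))
        assert np.abs(net.forward(F) - expected).max() < 1e-10


class TestDANNGradients:
    @pytest.mark.parametrize("pair_dim", [6, 8], ids=["identity", "projected"])
    def test_analytic_gradients_match_central_differences(self, pair_dim):
        rng = np.random.default_rng(0)
        r, t, d = 6, 4, 3
        views_l, views_m = make_views(r, t, d, K=2, seed=1)
        pairs = np.array([(i, j) for i in range(r) for j in range(t)])
        y = rng.integers(0, 2, len(pairs))
        net = DANN(view_dims=[d, d], pair_dim=pair_dim, hidden=(5, 3), random_state=2)
        _, grads = net.loss_and_grads(views_l, views_m, pairs, y)
        eps = 1e-6
        for key, P in net.params.items():
            num = np.zeros_like(P)
            it = np.nditer(P, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                P[idx] += eps
                lp, _ = net.loss_and_grads(views_l, views_m, pairs, y)
                P[idx] -= 2 * eps
                lm, _ = net.loss_and_grads(views_l, views_m, pairs, y)
                P[idx] += eps
                num[idx] = (lp - lm) / (2 * eps)
            denom = max(np.abs(num).max(), 1e-8)
            assert np.abs(grads[key] - num).max() / denom < 1e-5, key


class TestDANNTraining:
    def test_initial_loss_near_log2_on_balanced_labels(self):
        rng = np.random.default_rng(3)
        r, t, d = 10, 8, 4
        views_l, views_m = make_views(r, t, d, K=2, seed=4)
        pairs = np.array([(i, j) for i in range(r) for j in range(t)])
        y = np.tile([0, 1], len(pairs) // 2)
        net = DANN(view_dims=[d, d], pair_dim=2 * d, hidden=(6,), random_state=5)
        # shrink the random init so logits start near zero
        for key in net.params:
            if key.startswith("W") or key.startswith("b"):
                net.params[key] *= 0.01
        loss, _ = net.loss_and_grads(views_l, views_m, pairs, y)
        assert abs(loss - np.log(2)) < 0.05

    def test_training_decreases_loss(self):
        r, t, d = 8, 6, 3
        views_l, views_m = make_views(r, t, d, K=2, seed=6)
        pairs = np.array([(i, j) for i in range(r) for j in range(t)])
        y = ((pairs[:, 0] + pairs[:, 1]) % 2).astype(int)
        net = DANN(view_dims=[d, d], pair_dim=2 * d, hidden=(6,), epochs=100, random_state=7)
        net.fit(views_l, views_m, pairs, y)
        assert net.loss_history_[-1] < net.loss_history_[0]

    def test_attention_weights_normalized(self):
        r, t, d = 6, 4, 2
        views_l, views_m = make_views(r, t, d, K=3, seed=8)
        pairs = np.array([(i, j) for i in range(r) for j in range(t)])
        y = np.tile([0, 1], len(pairs) // 2)
        net = DANN(view_dims=[d] * 3, pair_dim=2 * d, hidden=(4,), epochs=30, random_state=9)
        net.fit(views_l, views_m, pairs, y)
        for w in net.attention_weights_.values():
            assert (w > 0).all()
            assert np.isclose(w.sum(), 1.0, atol=1e-8)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(10)
    r, t, d = 12, 8, 3
    block_l = (np.arange(r) % 2)[:, None].astype(float)
    block_m = (np.arange(t) % 2)[:, None].astype(float)
    signal = np.vstack(
        [np.hstack([block_l, 1 - block_l, block_l]), np.hstack([block_m, 1 - block_m, block_m])]
    )
    emb = {
        "GraRep": signal + 0.05 * rng.standard_normal(signal.shape),
        "LE": signal + 0.05 * rng.standard_normal(signal.shape),
    }
    pairs = np.array([(i, j) for i in range(r) for j in range(t)])
    y = ((pairs[:, 0] % 2) == (pairs[:, 1] % 2)).astype(int)
    return emb, pairs, y, r


class TestGEELFIClassifier:
    def test_scores_are_probabilities(self, toy):
        emb, pairs, y, r = toy
        model = GEELFIClassifier(n_estimators=40, epochs=50, random_state=0).fit(pairs, y, emb, r)
        s = model.decision_scores(pairs)
        assert ((s >= 0) & (s <= 1)).all()

    def test_pair_feature_width_is_pair_dim(self, toy):
        emb, pairs, y, r = toy
        model = GEELFIClassifier(pair_dim=8, n_estimators=20, epochs=30, random_state=0).fit(pairs, y, emb, r)
        F = model.extract_pair_features(pairs[:5])
        assert F.shape == (5, 8)

    def test_identical_entities_get_identical_features(self, toy):
        emb, pairs, y, r = toy
        emb = {k: v.copy() for k, v in emb.items()}
        for E in emb.values():
            E[1] = E[0]  # duplicate lncRNA 1 as a copy of 0
        model = GEELFIClassifier(n_estimators=20, epochs=30, random_state=0).fit(pairs, y, emb, r)
        F0 = model.extract_pair_features(np.array([(0, 2)]))
        F1 = model.extract_pair_features(np.array([(1, 2)]))
        assert np.allclose(F0, F1)

    def test_untrained_feature_extraction_rejected(self, toy):
        emb, pairs, y, r = toy
        model = GEELFIClassifier()
        with pytest.raises(RuntimeError, match="fit"):
            model.extract_pair_features(pairs)

    def test_hidden_presets_differ(self, toy):
        emb, pairs, y, r = toy
        m1 = GEELFIClassifier(hidden_preset="table", n_estimators=10, epochs=5, random_state=0).fit(
            pairs, y, emb, r
        )
        m2 = GEELFIClassifier(hidden_preset="text", n_estimators=10, epochs=5, random_state=0).fit(
            pairs, y, emb, r
        )
        assert m1.dann_.params["W1"].shape[1] == 240
        assert m2.dann_.params["W1"].shape[1] == 120

    def test_single_class_rejected(self, toy):
        emb, pairs, y, r = toy
        with pytest.raises(ValueError, match="both classes"):
            GEELFIClassifier().fit(pairs, np.ones_like(y), emb, r)
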