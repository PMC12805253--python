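import math

import numpy as np
import pytest

import cnattention as cn
from cnattention.mil import _sigmoid, _softmax


def scalar_gated_attention(V, U, w, H):
    """Independent scalar-by-scalar oracle for the gated attention weights."""
    K, M = H.shape
    L = len(w)
    scores = []
    for k in range(K):
        s = 0.0
        for l in range(L):
            t = g = 0.0
            for m in range(M):
                t += V[l][m] * H[k][m]
                g += U[l][m] * H[k][m]
            s += w[l] * math.tanh(t) * (1.0 / (1.0 + math.exp(-g)))
        scores.append(s)
    exps = [math.exp(s) for s in scores]
    total = sum(exps)
    return [e / total for e in exps]


class TestGatedAttention:
    def test_matches_scalar_oracle_on_hand_set_model(self):
        V = [[0.5, -1.0], [2.0, 0.3]]
        U = [[1.5, 0.7], [-0.2, 0.9]]
        w = [1.2, -0.8]
        H = np.array([[0.4, -0.6], [1.1, 0.2], [-0.5, 0.9]])
        params = cn.MILModelParams.initialize(D=2, M=2, L=2, C=2, seed=0)
        params.V = np.array(V)
        params.U = np.array(U)
        params.w = np.array(w)
        got = cn.gated_attention(params, H)
        expected = scalar_gated_attention(V, U, w, H)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_identical_embeddings_give_uniform_weights(self, tiny_params):
        H = np.tile(np.array([0.3, -0.2, 0.5, 0.1, 0.0]), (4, 1))
        a = cn.gated_attention(tiny_params, H)
        np.testing.assert_allclose(a, np.full(4, 0.25), atol=1e-12)

    def test_single_instance_gets_weight_one(self, tiny_params):
        a = cn.gated_attention(tiny_params, np.ones((1, 5)))
        np.testing.assert_allclose(a, [1.0])

    def test_weights_positive_and_normalized(self, tiny_params):
        rng = np.random.default_rng(5)
        for _ in range(20):
            H = rng.normal(size=(rng.integers(1, 8), 5)) * 3
            a = cn.gated_attention(tiny_params, H)
            assert (a > 0).all()
            assert np.isclose(a.sum(), 1.0, atol=1e-9)


class TestEmbedAndPool:
    def test_identical_instances_embed_identically(self, tiny_params):
        x = np.array([1.0, -2.0, 0.0, 1.0, 0.0, 2.0])
        H = cn.embed_instances(tiny_params, np.stack([x, x]))
        np.testing.assert_array_equal(H[0], H[1])

    def test_permuting_instances_permutes_embeddings(self, tiny_params):
        rng = np.random.default_rng(1)
        X = rng.integers(-2, 3, size=(5, 6)).astype(float)
        perm = rng.permutation(5)
        H = cn.embed_instances(tiny_params, X)
        np.testing.assert_allclose(cn.embed_instances(tiny_params, X[perm]), H[perm])

    def test_width_mismatch_errors(self, tiny_params):
        with pytest.raises(ValueError, match="width"):
            cn.embed_instances(tiny_params, np.zeros((2, 4)))

    def test_uniform_attention_pools_to_mean(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        z = cn.pool_bag(H, np.full(3, 1 / 3))
        np.testing.assert_allclose(z, H.mean(axis=0))

    def test_one_hot_attention_selects_an_instance(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(cn.pool_bag(H, [0.0, 1.0]), H[1])

    def test_joint_permutation_leaves_pool_unchanged(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(6, 3))
        a = rng.dirichlet(np.ones(6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(cn.pool_bag(H[perm], a[perm]), cn.pool_bag(H, a))


class TestClassifyBag:
    def test_zero_classifier_predicts_uniform(self):
        params = cn.MILModelParams.initialize(D=4, M=3, L=2, C=5, seed=7)
        bag = cn.Bag(np.random.default_rng(0).integers(-2, 3, (3, 4)), ["a", "b", "c"])
        out = cn.classify_bag(params, bag)
        np.testing.assert_allclose(out.bag_probs, np.full(5, 0.2), atol=1e-12)

    def test_permutation_invariance_over_random_bags(self, tiny_params):
        rng = np.random.default_rng(3)
        for _ in range(100):
            K = int(rng.integers(2, 12))
            X = rng.integers(-2, 3, size=(K, 6)).astype(float)
            bag = cn.Bag(X, [f"i{k}" for k in range(K)])
            perm = rng.permutation(K)
            shuffled = cn.Bag(X[perm], [f"i{k}" for k in perm])
            p1 = cn.classify_bag(tiny_params, bag).bag_probs
            p2 = cn.classify_bag(tiny_params, shuffled).bag_probs
            np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_duplicating_all_instances_preserves_probs(self, tiny_params):
        rng = np.random.default_rng(4)
        X = rng.integers(-2, 3, size=(4, 6)).astype(float)
        bag = cn.Bag(X, list("abcd"))
        doubled = cn.Bag(np.vstack([X, X]), list("abcdefgh"))
        p1 = cn.classify_bag(tiny_params, bag).bag_probs
        p2 = cn.classify_bag(tiny_params, doubled).bag_probs
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestBagNLL:
    def test_perfect_prediction_costs_zero(self):
        assert cn.bag_nll(np.array([0.0, 1.0, 0.0]), 1) == 0.0

    def test_uniform_over_four_classes_is_log4(self):
        assert cn.bag_nll(np.full(4, 0.25), 2) == pytest.approx(math.log(4))

    def test_zero_probability_is_clamped(self):
        val = cn.bag_nll(np.array([1.0, 0.0]), 1)
        assert np.isfinite(val) and val > 20

    def test_binary_case_matches_cross_entropy(self):
        for p in (0.1, 0.5, 0.93):
            probs = np.array([1 - p, p])
            assert cn.bag_nll(probs, 1) == pytest.approx(-math.log(p))
            assert cn.bag_nll(probs, 0) == pytest.approx(-math.log(1 - p))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, tiny_params):
        params = tiny_params.copy()
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4, 6))
        label = 2
        _, grads = cn.forward_backward(params, X, label)
        eps = 1e-6
        for name, g in grads.items():
            arr = getattr(params, name)
            flat = arr.reshape(-1)
            idxs = rng.choice(flat.size, size=min(flat.size, 12), replace=False)
            for i in idxs:
                old = flat[i]
                flat[i] = old + eps
                lp, _ = cn.forward_backward(params, X, label)
                flat[i] = old - eps
                lm, _ = cn.forward_backward(params, X, label)
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(g.reshape(-1)[i]), 1e-8)
                assert abs(fd - g.reshape(-1)[i]) / denom < 1e-4, name

    def test_loss_matches_forward_pass(self, tiny_params):
        rng = np.random.default_rng(9)
        X = rng.integers(-2, 3, size=(3, 6)).astype(float)
        loss, _ = cn.forward_backward(tiny_params, X, 0)
        out = cn.classify_bag(tiny_params, cn.Bag(X, list("abc")))
        assert loss == pytest.approx(cn.bag_nll(out.bag_probs, 0))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_params):
        params = tiny_params.copy()
        params.gene_ids = [f"g{i}" for i in range(6)]
        params.class_names = ["a", "b", "c"]
        path = tmp_path / "model.json"
        params.save(path)
        back = cn.MILModelParams.load(path)
        for k, v in params.arrays().items():
            np.testing.assert_allclose(getattr(back, k), v)
        assert back.gene_ids == params.gene_ids
        assert back.class_names == params.class_names


def test_softmax_and_sigmoid_are_stable_at_extremes():
    assert np.isclose(_softmax(np.array([1000.0, 1000.0]))[0], 0.5)
    assert _sigmoid(np.array([-800.0]))[0] == pytest.approx(0.0, abs=1e-12)
    assert _sigmoid(np.array([800.0]))[0] == pytest.approx(1.0)
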