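import numpy as np
import pandas as pd
import pytest

import cnattention as cn


class TestInstancePredictions:
    def test_identical_instances_share_all_quantities(self, tiny_params):
        x = np.array([1.0, 0.0, -2.0, 1.0, 0.0, 2.0])
        bag = cn.Bag(np.stack([x, x, x]), ["a", "b", "c"])
        preds = cn.instance_predictions(tiny_params, [bag])
        for p in preds[1:]:
            assert p.attention == pytest.approx(preds[0].attention)
            np.testing.assert_allclose(p.probs, preds[0].probs)
            np.testing.assert_allclose(p.weighted_scores, preds[0].weighted_scores)

    def test_singleton_bag_has_unit_weight(self, tiny_params):
        x = np.array([[0.0, 1.0, -1.0, 2.0, 0.0, -2.0]])
        preds = cn.instance_predictions(tiny_params, [cn.Bag(x, ["only"])])
        assert preds[0].attention == pytest.approx(1.0)
        np.testing.assert_allclose(preds[0].weighted_scores, preds[0].probs)

    def test_predicted_class_matches_unweighted_argmax(self, tiny_params):
        rng = np.random.default_rng(6)
        bag = cn.Bag(rng.integers(-2, 3, (5, 6)).astype(float), list("abcde"))
        for p in cn.instance_predictions(tiny_params, [bag]):
            assert p.predicted_class == int(np.argmax(p.probs))

    def test_weighted_scores_sum_to_one_per_bag(self, tiny_params):
        rng = np.random.default_rng(7)
        for _ in range(10):
            K = int(rng.integers(1, 9))
            bag = cn.Bag(rng.integers(-2, 3, (K, 6)).astype(float),
                         [f"i{k}" for k in range(K)])
            preds = cn.instance_predictions(tiny_params, [bag])
            total = sum(p.weighted_scores.sum() for p in preds)
            assert total == pytest.approx(1.0, abs=1e-6)


class TestInstanceAccuracy:
    def _pred(self, sid, cls):
        probs = np.zeros(3)
        probs[cls] = 1.0
        return cn.InstancePrediction(sid, 0, 1.0, probs, probs, cls)

    def test_all_correct(self):
        preds = [self._pred(f"s{i}", i % 3) for i in range(6)]
        labels = {f"s{i}": i % 3 for i in range(6)}
        assert cn.instance_accuracy(preds, labels) == 1.0

    def test_three_of_four(self):
        preds = [self._pred("a", 0), self._pred("b", 1),
                 self._pred("c", 2), self._pred("d", 0)]
        labels = {"a": 0, "b": 1, "c": 2, "d": 1}
        assert cn.instance_accuracy(preds, labels) == 0.75

    def test_order_invariance_and_empty_error(self):
        preds = [self._pred("a", 0), self._pred("b", 2)]
        labels = {"a": 0, "b": 1}
        assert cn.instance_accuracy(preds, labels) == \
            cn.instance_accuracy(preds[::-1], labels)
        with pytest.raises(ValueError):
            cn.instance_accuracy([], {})


class TestProjection:
    def test_hand_computed_single_instance_projection(self):
        """One instance predicted for class 0 with weighted score 0.5 and calls
        (+2, -1, 0): raw scores (1.0, -0.5, 0), max-normalized (1.0, -0.5, 0)."""
        matrix = cn.CNAMatrix(["s1"], ["gA", "gB", "gC"], np.array([[2, -1, 0]]))
        probs = np.array([0.9, 0.1])
        weighted = np.array([0.5, 0.0555])
        pred = cn.InstancePrediction("s1", 0, 1.0, probs, weighted, 0)
        s = cn.project_to_features([pred], matrix, 0, "per_class_max")
        np.testing.assert_allclose(s, [1.0, -0.5, 0.0])

    def test_diploid_gene_scores_zero(self, tiny_params):
        rng = np.random.default_rng(8)
        X = rng.integers(-2, 3, (6, 6))
        X[:, 2] = 0
        matrix = cn.CNAMatrix([f"s{i}" for i in range(6)],
                              [f"g{j}" for j in range(6)], X)
        bag = cn.Bag(X.astype(float), matrix.sample_ids)
        preds = cn.instance_predictions(tiny_params, [bag])
        for k in range(3):
            s = cn.project_to_features(preds, matrix, k)
            assert s[2] == 0.0

    def test_no_assigned_instance_gives_zero_vector(self):
        matrix = cn.CNAMatrix(["s1"], ["gA"], np.array([[1]]))
        pred = cn.InstancePrediction("s1", 0, 1.0, np.array([1.0, 0.0]),
                                     np.array([1.0, 0.0]), 0)
        s = cn.project_to_features([pred], matrix, 1)
        np.testing.assert_array_equal(s, [0.0])

    def test_l1_normalization_sums_to_one(self):
        matrix = cn.CNAMatrix(["s1"], ["gA", "gB"], np.array([[2, -2]]))
        pred = cn.InstancePrediction("s1", 0, 1.0, np.array([1.0]),
                                     np.array([0.7]), 0)
        s = cn.project_to_features([pred], matrix, 0, "l1")
        assert np.abs(s).sum() == pytest.approx(1.0)

    def test_gradient_projection_has_same_contract(self, tiny_params):
        rng = np.random.default_rng(9)
        X = rng.integers(-2, 3, (4, 6))
        matrix = cn.CNAMatrix([f"s{i}" for i in range(4)],
                              [f"g{j}" for j in range(6)], X)
        bag = cn.Bag(X.astype(float), matrix.sample_ids)
        preds = cn.instance_predictions(tiny_params, [bag])
        k = preds[0].predicted_class
        s = cn.project_to_features(preds, matrix, k, method="grad_x_input",
                                   params=tiny_params)
        assert s.shape == (6,)
        assert np.abs(s).max() <= 1.0 + 1e-12


class TestExtractSignature:
    def test_top_n_ordering_and_directions(self):
        scores = pd.DataFrame({"k": [0.9, -0.9, 0.1]}, index=["A", "B", "C"])
        sig = cn.extract_signature(scores, 2)
        assert sig.top_genes["k"] == [("A", 0.9, "dup"), ("B", -0.9, "del")]

    def test_n_equal_to_gene_count_keeps_all(self):
        scores = pd.DataFrame({"k": [0.5, -0.2]}, index=["A", "B"])
        sig = cn.extract_signature(scores, 2)
        assert sig.genes_of("k") == {"A", "B"}

    def test_n_above_gene_count_keeps_all_with_warning(self):
        scores = pd.DataFrame({"k": [0.5]}, index=["A"])
        sig = cn.extract_signature(scores, 10)
        assert sig.genes_of("k") == {"A"}

    def test_deterministic_and_idempotent(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"),
                              index=[f"g{i}" for i in range(20)])
        s1 = cn.extract_signature(scores, 5)
        s2 = cn.extract_signature(scores, 5)
        assert s1.top_genes == s2.top_genes

    def test_tsv_round_trip(self, tmp_path):
        scores = pd.DataFrame({"k1": [0.9, -0.3], "k2": [-0.1, 0.8]},
                              index=["A", "B"])
        sig = cn.extract_signature(scores, 2)
        path = tmp_path / "sig.tsv"
        sig.save(path)
        from cnattention.signatures import read_signature_table
        back = read_signature_table(path)
        assert set(back["gene"]) == {"A", "B"}
        assert set(back["class"]) == {"k1", "k2"}
        assert set(back["direction"]) <= {"dup", "del"}


class TestEndToEndRecovery:
    def test_planted_block_genes_dominate_signature_scores(self, trained):
        results, _, truth = trained
        sigs = results.signatures(n_per_class=10, seed=0)
        for cls, planted in truth.blocks.items():
            scores = sigs.scores[cls]
            on = np.abs(scores.loc[list(planted)])
            off = np.abs(scores.drop(list(planted)))
            assert on.min() > off.max() or on.median() > off.quantile(0.999)

    def test_per_class_signature_gene_sets_disjoint_and_match_truth(self, trained):
        results, _, truth = trained
        sigs = results.signatures(n_per_class=20, seed=0)
        sets = {cls: sigs.genes_of(cls) for cls in truth.blocks}
        classes = list(sets)
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                assert not sets[a] & sets[b]
        for cls, planted in truth.blocks.items():
            assert cn.signature_jaccard(sets[cls], set(planted)) >= 0.8

    def test_signature_directions_match_planted_signs(self, trained):
        results, _, truth = trained
        sigs = results.signatures(n_per_class=20, seed=0)
        for cls, planted in truth.blocks.items():
            for gene, score, direction in sigs.top_genes[cls]:
                if gene in planted:
                    expected = "dup" if planted[gene] > 0 else "del"
                    assert direction == expected
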