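import numpy as np
import pytest

import pathact.classifier as clf
from pathact.classifier import (
    TrainingConfig,
    apply_scaler,
    evaluate,
    fit_scaler,
    split_data,
    train_model,
)
from pathact.pathway_scoring import PathwayScoreMatrix

from conftest import make_labels


def score_matrix(rows, barcodes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    barcodes = barcodes or [f"C{i}" for i in range(rows.shape[1])]
    return PathwayScoreMatrix(
        pathway_names=[f"P{i}" for i in range(rows.shape[0])],
        barcodes=barcodes,
        scores=rows,
        n_genes_used=np.full(rows.shape[0], 5),
    )


def separable_toy(n_per_class=100, n_pathways=5, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_pathways, 2 * n_per_class))
    x[:, :n_per_class] += shift
    sm = score_matrix(x)
    labels = make_labels(sm.barcodes, [1] * n_per_class + [0] * n_per_class)
    return sm, labels


class TestSplitData:
    def test_stratified_counts(self):
        sm = score_matrix(np.zeros((2, 200)))
        labels = make_labels(sm.barcodes, [1] * 100 + [0] * 100)
        train, test = split_data(sm, labels, 0.8, seed=1)
        y = labels.labels
        assert len(train) == 160 and len(test) == 40
        assert y[train].sum() == 80 and y[test].sum() == 20

    def test_partition_and_determinism(self):
        sm = score_matrix(np.zeros((2, 57)))
        labels = make_labels(sm.barcodes, [1] * 23 + [0] * 34)
        a_train, a_test = split_data(sm, labels, 0.8, seed=5)
        b_train, b_test = split_data(sm, labels, 0.8, seed=5)
        assert (a_train == b_train).all() and (a_test == b_test).all()
        assert set(a_train) & set(a_test) == set()
        assert len(set(a_train) | set(a_test)) == 57
        c_train, _ = split_data(sm, labels, 0.8, seed=6)
        assert not np.array_equal(a_train, c_train)

    def test_tiny_class_rejected(self):
        sm = score_matrix(np.zeros((1, 5)))
        labels = make_labels(sm.barcodes, [1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            split_data(sm, labels, 0.8, seed=0)


class TestScaler:
    def test_population_sd_convention(self):
        means, scales = fit_scaler(np.array([[1.0, 2.0, 3.0]]))
        standardized = apply_scaler(np.array([[1.0, 2.0, 3.0]]), means, scales)
        assert standardized.ravel() == pytest.approx(
            [-1.2247448, 0.0, 1.2247448]
        )

    def test_constant_pathway_gets_scale_one(self):
        means, scales = fit_scaler(np.array([[5.0, 5.0, 5.0]]))
        assert scales[0] == 1.0
        out = apply_scaler(np.array([[5.0, 5.0, 5.0]]), means, scales)
        assert (out == 0).all()

    def test_train_matrix_standardizes_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2, 2, size=(4, 50))
        means, scales = fit_scaler(x)
        z = apply_scaler(x, means, scales)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)


class TestTrainModel:
    def test_linearly_separable_toy_reaches_perfect_f1(self):
        sm, labels = separable_toy()
        # sanity oracle: a linear model must separate this perfectly
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression().fit(sm.scores.T, labels.labels)
        assert lr.score(sm.scores.T, labels.labels) == 1.0

        model = train_model(sm, labels, config=TrainingConfig(seed=0,
                                                              max_epochs=60))
        _, calls = model.predict(sm)
        report = evaluate(calls, labels.labels)
        assert report.f1 == 1.0

    def test_shuffled_labels_give_chance_level_f1(self):
        sm, labels = separable_toy(n_per_class=150)
        rng = np.random.default_rng(11)
        shuffled = make_labels(sm.barcodes, rng.permutation(labels.labels))
        train, test = split_data(sm, shuffled, 0.8, seed=11)
        model = train_model(sm.subset_cells(train), shuffled,
                            config=TrainingConfig(seed=11, max_epochs=40))
        _, calls = model.predict(sm.subset_cells(test))
        report = evaluate(calls, shuffled.aligned_to(
            [sm.barcodes[i] for i in test]))
        assert 0.25 <= report.f1 <= 0.75

    def test_same_seed_reproduces_identical_weights(self):
        sm, labels = separable_toy(n_per_class=40)
        cfg = TrainingConfig(seed=3, max_epochs=15)
        m1 = train_model(sm, labels, config=cfg)
        m2 = train_model(sm, labels, config=cfg)
        for w1, w2 in zip(m1.layer_weights, m2.layer_weights):
            assert (w1 == w2).all()
        for b1, b2 in zip(m1.layer_biases, m2.layer_biases):
            assert (b1 == b2).all()

    def test_single_class_training_rejected(self):
        sm = score_matrix(np.random.default_rng(0).normal(size=(2, 20)))
        with pytest.raises(ValueError):
            train_model(sm, make_labels(sm.barcodes, [1] * 20))


class TestPredict:
    def test_threshold_boundary_calls_tumor(self, small_model):
        model = small_model["model"]
        # force the boundary by querying the call rule directly
        prob = np.array([0.5 - 1e-9, 0.5, 0.5 + 1e-9])
        calls = (prob >= model.threshold).astype(int)
        assert calls.tolist() == [0, 1, 1]

    def test_missing_pathway_error_names_it(self, small_model):
        model, test_sc = small_model["model"], small_model["test_sc"]
        reduced = test_sc.subset_pathways(model.pathway_names[1:])
        with pytest.raises(ValueError, match=model.pathway_names[0]):
            model.predict(reduced)

    def test_column_permutation_permutes_outputs(self, small_model):
        model, test_sc = small_model["model"], small_model["test_sc"]
        prob, _ = model.predict(test_sc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(test_sc.barcodes))
        prob_perm, _ = model.predict(test_sc.subset_cells(perm))
        assert (prob_perm == prob[perm]).all()


class TestEvaluate:
    def test_hand_computed_confusion(self):
        truth = np.array([1] * 10 + [0] * 10)
        calls = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        rep = evaluate(calls, truth)
        assert rep.confusion == (8, 2, 8, 2)
        assert (rep.precision, rep.recall, rep.f1, rep.accuracy) == \
            (0.8, 0.8, pytest.approx(0.8), 0.8)

    def test_perfect_prediction(self):
        rep = evaluate(np.array([1, 0, 1]), np.array([1, 0, 1]))
        assert (rep.f1, rep.accuracy, rep.precision, rep.recall) == (1, 1, 1, 1)

    def test_degenerate_all_negative_convention(self):
        rep = evaluate(np.zeros(4, dtype=int), np.zeros(4, dtype=int))
        assert (rep.precision, rep.recall, rep.f1) == (0, 0, 0)
        assert rep.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1, 0]), np.array([1]))

    def test_agrees_with_sklearn_on_random_vectors(self):
        from sklearn.metrics import (accuracy_score, f1_score,
                                     precision_score, recall_score)

        rng = np.random.default_rng(9)
        for _ in range(20):
            truth = rng.integers(0, 2, size=50)
            calls = rng.integers(0, 2, size=50)
            if truth.sum() == 0 or calls.sum() == 0:
                continue
            rep = evaluate(calls, truth)
            assert rep.f1 == pytest.approx(f1_score(truth, calls))
            assert rep.accuracy == pytest.approx(accuracy_score(truth, calls))
            assert rep.precision == pytest.approx(
                precision_score(truth, calls))
            assert rep.recall == pytest.approx(recall_score(truth, calls))

    def test_imbalanced_minority_positive_matches_hand_arithmetic(self):
        truth = np.array([1] * 10 + [0] * 90)
        calls = np.array([1] * 7 + [0] * 3 + [1] * 5 + [0] * 85)
        rep = evaluate(calls, truth)
        assert rep.confusion == (7, 5, 85, 3)
        assert rep.precision == pytest.approx(7 / 12)
        assert rep.recall == pytest.approx(7 / 10)
        assert rep.f1 == pytest.approx(2 * (7 / 12) * 0.7 / ((7 / 12) + 0.7))
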