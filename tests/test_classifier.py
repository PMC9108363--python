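import numpy as np
import pandas as pd
import pytest

from scmod.classifier import (
    ClassifierConfig,
    SubtypeClassifier,
    cross_entropy,
    evaluate,
    mean_report,
    predict_samples,
    predict_vote,
    train,
)


def blob_features(n_per_class=40, dim=6, gap=4.0, seed=0):
    """Linearly separable two-class blobs as a labeled feature frame."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, dim))
    b = rng.normal(gap, 1.0, (n_per_class, dim))
    X = np.vstack([a, b])
    idx = pd.MultiIndex.from_tuples(
        [(f"s{i}", 0) for i in range(2 * n_per_class)],
        names=["sample_id", "set_id"],
    )
    df = pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(dim)])
    df["label"] = ["a"] * n_per_class + ["b"] * n_per_class
    return df


class StubModel:
    """Duck-typed model emitting fixed probabilities, for vote tests."""

    def __init__(self, proba, classes):
        self._proba = np.asarray(proba, float)
        self.classes_ = classes

    def predict_proba(self, X):
        return self._proba[: len(np.atleast_2d(X))]


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        proba = np.eye(4)
        assert cross_entropy(proba, np.eye(4)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_log_t(self):
        proba = np.full((3, 4), 0.25)
        y = np.zeros((3, 4))
        y[:, 1] = 1
        assert cross_entropy(proba, y) == pytest.approx(np.log(4), abs=1e-12)


class TestTrain:
    def test_separable_blobs_learned(self):
        df = blob_features(n_per_class=150)
        cfg = ClassifierConfig(hidden_sizes=(8,), n_members=5, seed=0,
                               early_stop_patience=60)
        model = train(df, cfg)
        X = df.drop(columns="label").to_numpy()
        assert (model.predict(X) == df["label"].to_numpy()).mean() == 1.0

    def test_softmax_rows_sum_to_one(self):
        df = blob_features()
        model = train(df, ClassifierConfig(hidden_sizes=(8,), n_members=2, seed=1))
        proba = model.predict_proba(df.drop(columns="label").to_numpy())
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_errors(self):
        df = blob_features(n_per_class=10)
        df["label"] = "a"
        with pytest.raises(ValueError, match="single class"):
            train(df, ClassifierConfig(n_members=1))

    def test_deterministic_given_seed(self):
        df = blob_features()
        cfg = ClassifierConfig(hidden_sizes=(8,), n_members=2, seed=7)
        m1, m2 = train(df, cfg), train(df, cfg)
        X = df.drop(columns="label").to_numpy()
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_json_round_trip_exact(self, tmp_path):
        df = blob_features()
        model = train(df, ClassifierConfig(hidden_sizes=(8,), n_members=2, seed=3))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = SubtypeClassifier.from_json(path)
        X = df.drop(columns="label").to_numpy()
        assert np.array_equal(model.predict_proba(X), loaded.predict_proba(X))
        assert loaded.classes_ == model.classes_


class TestPredictVote:
    def test_majority_wins(self):
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.6, 0.4],
                          [0.2, 0.8]])
        label, votes = predict_vote(StubModel(proba, ["A", "B"]), np.zeros((5, 2)))
        assert label == "A" and votes == 3

    def test_single_vector_argmax(self):
        label, votes = predict_vote(
            StubModel([[0.1, 0.9]], ["A", "B"]), np.zeros((1, 2))
        )
        assert label == "B" and votes == 1

    def test_tie_broken_by_mean_probability(self):
        proba = np.array([[0.61, 0.39], [0.61, 0.39], [0.45, 0.55], [0.45, 0.55]])
        label, _ = predict_vote(StubModel(proba, ["A", "B"]), np.zeros((4, 2)))
        assert label == "A"  # mean 0.53 vs 0.47


class TestEvaluate:
    def test_toy_confusion_oracle(self):
        """2 classes, TP = (9, 8) of 10 each: accuracy and macro-R by hand."""
        y_true = ["a"] * 10 + ["b"] * 10
        y_pred = ["a"] * 9 + ["b"] + ["b"] * 8 + ["a"] * 2
        rep = evaluate(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.85, abs=1e-12)
        assert rep.macro_recall == pytest.approx((0.9 + 0.8) / 2, abs=1e-12)

    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        rep = evaluate(y, list(y))
        assert rep.accuracy == rep.macro_precision == rep.macro_recall == 1.0
        assert rep.macro_f1 == 1.0

    def test_never_predicted_class_zero_precision(self, caplog):
        with caplog.at_level("WARNING", logger="scmod.classifier"):
            rep = evaluate(["a", "b"], ["a", "a"], classes=["a", "b"])
        assert "never predicted" in caplog.text
        assert rep.macro_precision == pytest.approx((0.5 + 0.0) / 2)

    def test_macro_f1_is_harmonic_mean_of_macro_averages(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, 200).tolist()
        y_pred = rng.choice(classes, 200).tolist()
        rep = evaluate(y_true, y_pred, classes=classes)
        # independent recomputation from the confusion matrix
        cm = rep.confusion
        tp = np.diag(cm)
        p = np.mean([tp[i] / cm[:, i].sum() if cm[:, i].sum() else 0.0
                     for i in range(3)])
        r = np.mean([tp[i] / cm[i].sum() if cm[i].sum() else 0.0
                     for i in range(3)])
        expected = 2 * p * r / (p + r)
        assert rep.macro_f1 == pytest.approx(expected, abs=1e-12)

    def test_confusion_conservation(self):
        y_true = ["a"] * 7 + ["b"] * 5
        y_pred = ["b"] * 3 + ["a"] * 9
        rep = evaluate(y_true, y_pred)
        assert rep.confusion.sum() == 12


def test_predict_samples_groups_by_sample():
    proba = np.array([[0.9, 0.1], [0.8, 0.2]])
    model = StubModel(proba, ["A", "B"])
    idx = pd.MultiIndex.from_tuples([("s1", 0), ("s1", 1)],
                                    names=["sample_id", "set_id"])
    feats = pd.DataFrame(np.zeros((2, 2)), index=idx, columns=["f0", "f1"])
    preds = predict_samples(model, feats)
    assert preds.loc["s1", "predicted"] == "A"
    assert preds.loc["s1", "n_votes_for_winner"] == 2


def test_mean_report_is_arithmetic_mean():
    r1 = evaluate(["a", "b"], ["a", "b"])
    r2 = evaluate(["a", "b"], ["b", "a"])
    mean = mean_report([r1, r2])
    assert mean["accuracy"] == pytest.approx((1.0 + 0.0) / 2)


@pytest.fixture(scope="module")
def cv_world():
    from scmod.simulate import SimulationSpec, simulate
    from scmod.specificity import SpecificEdgeSet

    ds, truth = simulate(
        SimulationSpec(T=2, sizes=(15, 21), n_genes=60, module_size=10,
                       n_shared_modules=0, shared_size=0, seed=8)
    )
    edge_sets = {}
    for s in ds.subtypes:
        genes = sorted(truth.specific[s])
        pairs = [(genes[i], genes[j]) for i in range(len(genes))
                 for j in range(i + 1, len(genes))][:10]
        edge_sets[s] = SpecificEdgeSet(
            subtype=s, module=1, module_genes=set(genes),
            edges=pd.DataFrame({"gene_a": [a for a, _ in pairs],
                                "gene_b": [b for _, b in pairs],
                                "delta": 0.5}),
        )
    return ds, edge_sets


class TestCrossValidate:
    def test_folds_partition_samples(self, cv_world):
        from scmod.classifier import cross_validate

        ds, edge_sets = cv_world
        cfg = ClassifierConfig(hidden_sizes=(10,), n_members=1,
                               max_epochs=150, seed=0)
        reports, mean = cross_validate(
            ds, edge_sets, k=3, P=8, n_sets=2, cfg=cfg, seed=0
        )
        assert len(reports) == 3
        assert sum(r.confusion.sum() for r in reports) == ds.n_samples
        for key, value in mean.items():
            assert value == pytest.approx(
                np.mean([r.metrics()[key] for r in reports])
            )

    def test_subtype_smaller_than_k_errors(self, cv_world):
        from scmod.classifier import cross_validate

        ds, edge_sets = cv_world
        with pytest.raises(ValueError, match="at least k"):
            cross_validate(ds, edge_sets, k=16)
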