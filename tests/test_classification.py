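import numpy as np
import pytest

from alscape.classification import (
    CNNConfig,
    RFConfig,
    SVMConfig,
    predict,
    split_classes,
    train_cnn,
    train_rf,
    train_svm,
)


@pytest.fixture(scope="module")
def toy_features():
    """Linearly separable 3-class feature clouds."""
    rng = np.random.default_rng(0)
    centers = {"heterogeneous": (0, 0), "rugged": (6, 0), "smooth": (0, 6)}
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(loc=c, scale=0.3, size=(20, 2)))
        y += [label] * 20
    return np.concatenate(X), np.array(y)


class TestSplit:
    def test_38_classes_split_19_19(self):
        names = [f"c{i}" for i in range(38)]
        split = split_classes(names, seed=0)
        assert len(split.train_classes) == len(split.test_classes) == 19
        assert not set(split.train_classes) & set(split.test_classes)
        assert set(split.train_classes) | set(split.test_classes) == set(names)

    def test_deterministic_given_seed(self):
        names = [f"c{i}" for i in range(12)]
        assert split_classes(names, 5) == split_classes(names, 5)
        assert split_classes(names, 5) != split_classes(names, 6)

    def test_odd_count_requires_explicit_fraction(self):
        names = [f"c{i}" for i in range(7)]
        with pytest.raises(ValueError, match="odd"):
            split_classes(names, 0)
        split = split_classes(names, 0, train_fraction=0.6)
        assert len(split.train_classes) == 4


class TestSVM:
    def test_one_against_one_model_count(self, toy_features):
        X, y = toy_features
        clf = train_svm(X, y, SVMConfig(costs=(1.0,), kernels=("linear",)), seed=0)
        svc = clf.model.named_steps["svc"]
        # 3 labels → k(k−1)/2 = 3 binary one-vs-one machines
        assert svc.decision_function(X[:2]).shape == (2, 3)

    def test_separable_training_accuracy_is_one(self, toy_features):
        X, y = toy_features
        clf = train_svm(X, y, SVMConfig(costs=(1.0,), kernels=("linear",)), seed=0)
        _, hard = predict(clf, X)
        assert (hard == y).mean() == 1.0

    def test_selection_matches_exhaustive_cv_oracle(self, toy_features):
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X, y = toy_features
        config = SVMConfig(costs=(0.01, 1.0), kernels=("linear", "rbf"), n_folds=3)
        clf = train_svm(X, y, config, seed=0)
        scores = {}
        for C in config.costs:
            for kernel in config.kernels:
                pipe = Pipeline([("scale", StandardScaler()),
                                 ("svc", SVC(C=C, kernel=kernel, random_state=0))])
                cv = StratifiedKFold(3, shuffle=True, random_state=0)
                scores[(C, kernel)] = cross_val_score(pipe, X, y, cv=cv).mean()
        best = max(scores, key=scores.get)
        assert (clf.hyperparameters["C"], clf.hyperparameters["kernel"]) == best

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((10, 2)), ["smooth"] * 10)


class TestRF:
    def test_grid_has_eight_points(self, toy_features):
        X, y = toy_features
        clf = train_rf(X, y, RFConfig(n_folds=3), seed=0)
        assert len(clf.log["cv_results"]["params"]) == 8

    def test_seeded_determinism(self, toy_features):
        X, y = toy_features
        a = train_rf(X, y, RFConfig(n_trees=(50,), n_folds=3), seed=4)
        b = train_rf(X, y, RFConfig(n_trees=(50,), n_folds=3), seed=4)
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_separable_heldout_accuracy(self, toy_features):
        X, y = toy_features
        idx = np.arange(len(y))
        rng = np.random.default_rng(1)
        rng.shuffle(idx)
        tr, te = idx[:45], idx[45:]
        clf = train_rf(X[tr], y[tr], RFConfig(n_folds=3), seed=0)
        _, hard = predict(clf, X[te])
        assert (hard == y[te]).mean() >= 0.95

    def test_probability_is_tree_vote_fraction(self):
        # 2-tree toy ensemble with pure leaves: probabilities are vote counts / 2
        from sklearn.ensemble import RandomForestClassifier

        X = np.array([[0.0], [0.1], [1.0], [1.1], [2.0], [2.1]])
        y = np.array([0, 0, 1, 1, 2, 2])
        rf = RandomForestClassifier(n_estimators=2, bootstrap=False, random_state=0).fit(X, y)
        probs = rf.predict_proba(X)
        votes = np.stack([t.predict(X) for t in rf.estimators_])
        manual = np.stack([(votes == k).mean(axis=0) for k in (0, 1, 2)], axis=1)
        assert np.allclose(probs, manual)


class TestCNNTraining:
    @pytest.fixture(scope="class")
    def toy_images(self):
        rng = np.random.default_rng(0)
        x, y = [], []
        for label, level in [("heterogeneous", 0.1), ("rugged", 0.5), ("smooth", 0.9)]:
            x.append(np.clip(rng.normal(level, 0.02, size=(12, 16, 16)), 0, 1))
            y += [label] * 12
        return np.concatenate(x), np.array(y)

    def test_separable_images_high_heldout_accuracy(self, toy_images):
        x, y = toy_images
        idx = np.random.default_rng(1).permutation(len(y))
        tr, te = idx[:27], idx[27:]
        config = CNNConfig(conv_channels=(4, 8, 8), alphas=(0.1,), dropouts=(0.0,),
                           dense_sizes=(16, 8), learning_rates=(0.01,), epochs=30,
                           batch_size=8, max_grid_points=1)
        clf = train_cnn(x[tr], y[tr], config, seed=0)
        probs, hard = predict(clf, x[te])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (hard == y[te]).mean() >= 0.95

    def test_divergent_grid_points_are_skipped(self, toy_images, monkeypatch):
        from alscape import _cnn

        x, y = toy_images
        original_fit = _cnn.TinyCNN.fit

        def failing_fit(self, *args, lr=1e-3, **kwargs):
            if lr == 100.0:
                raise _cnn.DivergenceError("simulated divergence")
            return original_fit(self, *args, lr=lr, **kwargs)

        monkeypatch.setattr(_cnn.TinyCNN, "fit", failing_fit)
        config = CNNConfig(conv_channels=(2, 2, 2), alphas=(0.1,), dropouts=(0.0,),
                           dense_sizes=(8, 8), learning_rates=(100.0, 0.01),
                           epochs=5, batch_size=8, max_grid_points=4)
        clf = train_cnn(x, y, config, seed=0)
        assert clf.hyperparameters["lr"] == 0.01
        failed = [r for r in clf.log["grid"] if r["val_accuracy"] < 0]
        assert failed and all(r["lr"] == 100.0 for r in failed)

    def test_encoding_mismatch_rejected(self, toy_images):
        x, y = toy_images
        config = CNNConfig(conv_channels=(2, 2, 2), alphas=(0.1,), dropouts=(0.0,),
                           dense_sizes=(8, 8), learning_rates=(0.01,), epochs=2,
                           batch_size=8, max_grid_points=1)
        clf = train_cnn(x, y, config, seed=0)
        with pytest.raises(ValueError, match="encoding"):
            clf.predict_proba(np.zeros((2, 8, 8, 1)))


class TestPredict:
    def test_hard_label_is_argmax_with_label_order_tiebreak(self, toy_features):
        X, y = toy_features
        clf = train_svm(X, y, SVMConfig(costs=(1.0,), kernels=("linear",)), seed=0)
        probs, hard = predict(clf, X)
        for p, h in zip(probs, hard):
            assert h == clf.labels[int(np.argmax(p))]
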