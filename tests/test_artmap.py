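"""Fuzzy ARTMAP: coding, choice/match/learn arithmetic, training dynamics."""

import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from rosenose.artmap import (
    FuzzyArtmapClassifier,
    choice,
    complement_code,
    learn,
    load_model,
    match,
    save_model,
)


def _random_patterns(rng, n=150, m=10, classes=3):
    X = rng.uniform(0, 1, size=(n, m))
    y = np.array([f"C{1 + i % classes}" for i in range(n)])
    return X, y


class TestPrimitives:
    def test_complement_coding(self):
        np.testing.assert_allclose(
            complement_code(np.array([0.3, 0.7])), [0.3, 0.7, 0.7, 0.3]
        )
        zeros = complement_code(np.zeros(5))
        np.testing.assert_allclose(zeros, np.r_[np.zeros(5), np.ones(5)])

    @pytest.mark.parametrize("seed", range(5))
    def test_coded_norm_equals_input_dim(self, seed):
        a = np.random.default_rng(seed).uniform(0, 1, 12)
        assert complement_code(a).sum() == pytest.approx(12.0)

    def test_out_of_range_rejected_with_position(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            complement_code(np.array([0.1, 0.5, 1.2]))

    def test_choice_values(self):
        I = complement_code(np.array([0.4, 0.6]))  # |I| = 2
        uncommitted = np.ones(4)
        assert choice(I, uncommitted, 0.001) == pytest.approx(2 / 4.001, rel=1e-12)
        assert choice(I, I, 0.001) == pytest.approx(2 / 2.001, rel=1e-12)
        disjoint = np.array([0.0, 0.0, 0.0, 0.0])
        assert choice(I, disjoint, 0.001) == 0.0

    def test_match_values(self):
        I = complement_code(np.array([0.2, 0.9]))
        assert match(I, I) == 1.0
        assert match(I, np.ones(4)) == 1.0  # uncommitted node always resonates

    def test_learn_fast_and_slow(self):
        I = np.array([0.4, 0.8])
        assert np.array_equal(learn(np.ones(2), I, beta=1.0), I)
        assert np.array_equal(learn(I, I, beta=1.0), I)  # idempotent
        np.testing.assert_allclose(learn(np.ones(2), I, beta=0.5), [0.7, 0.9])

    @pytest.mark.parametrize("seed", range(5))
    def test_learned_weights_never_increase(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, 8)
        I = rng.uniform(0, 1, 8)
        assert np.all(learn(w, I, beta=rng.uniform(0.1, 1.0)) <= w + 1e-15)


class TestTraining:
    def test_two_patterns_two_categories(self):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        y = np.array(["a", "b"])
        m = FuzzyArtmapClassifier().fit(X, y)
        assert m.n_categories_ == 2
        assert list(m.predict(X)) == ["a", "b"]

    def test_full_training_recall(self, rng):
        """Fast learning with rho_a=0 reproduces 100% of any consistent,
        duplicate-free training set."""
        X, y = _random_patterns(rng)
        m = FuzzyArtmapClassifier().fit(X, y)
        assert (m.predict(X) == y).all()

    def test_deterministic_given_order(self, rng):
        X, y = _random_patterns(rng, n=60)
        m1 = FuzzyArtmapClassifier().fit(X, y)
        m2 = FuzzyArtmapClassifier().fit(X, y)
        np.testing.assert_array_equal(m1.weights_, m2.weights_)
        np.testing.assert_array_equal(m1.category_class_, m2.category_class_)

    def test_weights_monotone_over_additional_training(self, rng):
        X, y = _random_patterns(rng, n=40)
        m = FuzzyArtmapClassifier().fit(X[:20], y[:20])
        before = m.weights_.copy()
        m.partial_fit(X[20:], y[20:])
        after = m.weights_[: len(before)]
        assert np.all(after <= before + 1e-15)

    def test_stability_after_convergence(self, rng):
        """Re-presenting the training set changes no weights."""
        X, y = _random_patterns(rng, n=80)
        m = FuzzyArtmapClassifier().fit(X, y)
        before = m.weights_.copy()
        n_before = m.n_categories_
        m.partial_fit(X, y)
        assert m.n_categories_ == n_before
        np.testing.assert_array_equal(m.weights_[:n_before], before)

    def test_online_equals_batch_category_count(self, rng):
        """Feeding the same single-epoch stream incrementally gives the same
        categories as one batch pass."""
        X, y = _random_patterns(rng, n=60)
        batch = FuzzyArtmapClassifier(max_epochs=1).fit(X, y)
        online = FuzzyArtmapClassifier(max_epochs=1)
        online.partial_fit(X[:20], y[:20], classes=np.unique(y))
        online.partial_fit(X[20:40], y[20:40])
        online.partial_fit(X[40:], y[40:])
        assert online.n_categories_ == batch.n_categories_
        np.testing.assert_array_equal(online.weights_, batch.weights_)

    def test_category_count_bounded_by_patterns(self, rng):
        X, y = _random_patterns(rng, n=50)
        m = FuzzyArtmapClassifier().fit(X, y)
        assert m.n_categories_ <= 50

    def test_clustered_data_commits_few_categories(self, rng):
        centers = np.array([[0.2, 0.2], [0.8, 0.8], [0.2, 0.8]])
        X = np.vstack([c + rng.normal(0, 0.01, size=(30, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 30)
        m = FuzzyArtmapClassifier().fit(np.clip(X, 0, 1), y)
        assert m.n_categories_ <= 6  # far fewer than 90 patterns

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            FuzzyArtmapClassifier().fit(np.array([[0.5, 1.5]]), ["a"])

    @pytest.mark.parametrize("params", [
        dict(rho_a_baseline=1.5), dict(rho_ab=0.0), dict(alpha=0.0),
        dict(beta=0.0), dict(epsilon=-1.0),
    ])
    def test_invalid_hyperparams_rejected(self, params):
        with pytest.raises(ValueError):
            FuzzyArtmapClassifier(**params).fit(np.array([[0.1], [0.9]]), ["a", "b"])


class TestPrediction:
    def test_single_category_predicts_its_class_everywhere(self, rng):
        m = FuzzyArtmapClassifier().fit(np.array([[0.3, 0.6]]), ["only"])
        X = rng.uniform(0, 1, size=(20, 2))
        assert (m.predict(X) == "only").all()

    def test_tie_broken_to_lowest_category_index(self):
        """Duplicating a committed weight vector at a higher index with a
        different class cannot change predictions."""
        m = FuzzyArtmapClassifier().fit(np.array([[0.2, 0.2], [0.8, 0.8]]),
                                        ["a", "b"])
        m.weights_ = np.vstack([m.weights_, m.weights_[0]])
        m.category_class_ = np.r_[m.category_class_, 1 - m.category_class_[0]]
        assert m.predict(np.array([[0.2, 0.2]]))[0] == "a"

    def test_unfitted_model_rejected(self):
        with pytest.raises(NotFittedError):
            FuzzyArtmapClassifier().predict(np.array([[0.1]]))

    def test_json_round_trip(self, rng, tmp_path):
        X, y = _random_patterns(rng, n=40)
        m = FuzzyArtmapClassifier().fit(X, y)
        path = tmp_path / "model.json"
        save_model(m, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict(X), m.predict(X))

    def test_loaded_model_supports_incremental_updates(self, rng, tmp_path):
        X, y = _random_patterns(rng, n=40)
        m = FuzzyArtmapClassifier().fit(X[:30], y[:30])
        path = tmp_path / "model.json"
        save_model(m, path)
        loaded = load_model(path)
        loaded.partial_fit(X[30:], y[30:])
        assert (loaded.predict(X[30:]) == y[30:]).all()
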