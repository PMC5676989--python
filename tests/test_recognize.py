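"""Enrolment models, score contracts, past-score weighting, thresholds."""

import numpy as np
import pytest

from wheelbeat.recognize import (
    DecisionState,
    ThresholdProfile,
    authenticate,
    identify,
    score,
    score_matrix,
    train,
    tune_thresholds,
    weight_scores,
)


@pytest.fixture(scope="module")
def toy_data():
    """Two well-separated identities in 4-D, 20 samples each."""
    rng = np.random.default_rng(123)
    a = rng.normal([0, 0, 0, 0], 0.3, size=(20, 4))
    b = rng.normal([3, 3, 0, 0], 0.3, size=(20, 4))
    X = np.vstack([a, b])
    y = np.array(["A"] * 20 + ["B"] * 20)
    return X, y


class TestTrainAndScore:
    @pytest.mark.parametrize("kind", ["svm", "knn", "mlp", "gmmubm"])
    def test_scores_are_a_distribution(self, toy_data, kind):
        X, y = toy_data
        model = train(X, y, kind=kind, seed=0)
        s = score_matrix(model, X)
        assert s.shape == (40, 2)
        assert np.all(s >= 0) and np.all(s <= 1)
        assert np.allclose(s.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("kind", ["svm", "knn", "mlp", "gmmubm"])
    def test_separable_identities_recovered(self, toy_data, kind):
        X, y = toy_data
        # a UBM needs fewer components than identity clusters, otherwise the
        # background explains each subject exactly and the LLR flattens;
        # with one cluster per subject that means a single shared component
        cfg = {"n_components": 1} if kind == "gmmubm" else None
        model = train(X, y, kind=kind, config=cfg, seed=0)
        preds = [identify(model, x) for x in X]
        assert np.mean(np.asarray(preds) == y) >= 0.95

    def test_knn_k1_training_sample_identity(self, toy_data):
        X, y = toy_data
        model = train(X, y, kind="knn", config={"k": 1}, seed=0)
        s = score(model, X[0])
        assert model.classes[np.argmax(s)] == "A"
        assert s[0] == 1.0

    def test_symmetric_query_scores_half(self):
        rng = np.random.default_rng(5)
        jitter = rng.normal(0, 0.05, size=(10, 2))
        a = np.array([[-1.0, 0.0]] * 10) + jitter
        b = np.array([[1.0, 0.0]] * 10) - jitter  # mirrored training sets
        X = np.vstack([a, b])
        y = np.array(["A"] * 10 + ["B"] * 10)
        model = train(X, y, kind="knn", config={"k": 4}, seed=0)
        s = score(model, np.array([0.0, 0.0]))
        assert s[0] == pytest.approx(0.5, abs=0.26)
        assert abs(s.sum() - 1.0) < 1e-12

    def test_gmm_ubm_llr_favours_own_subject(self):
        # known generative mixtures, speaker-verification style: both
        # subjects share the same two broad modes, each subject offsetting
        # them slightly; MAP adaptation must pull the background means
        # toward each subject's side so their own samples score above the UBM
        rng = np.random.default_rng(77)

        def draw(offset, n):
            comps = rng.choice([-2.0, 2.0], size=(n, 1))
            return comps + offset + rng.normal(0, 0.4, size=(n, 3))

        X = np.vstack([draw(-0.5, 60), draw(+0.5, 60)])
        y = np.array(["A"] * 60 + ["B"] * 60)
        model = train(X, y, kind="gmmubm",
                      config={"n_components": 2}, seed=1)
        fresh_a = draw(-0.5, 30)
        Xs = model.scaler.transform(fresh_a)
        llr = model.estimator.llr(Xs)
        assert llr[:, 0].mean() > 0          # A above UBM on average
        assert llr[:, 0].mean() > llr[:, 1].mean()

    def test_deterministic_for_fixed_seed(self, toy_data):
        X, y = toy_data
        q = np.array([1.5, 1.5, 0.0, 0.0])
        s1 = score(train(X, y, kind="mlp", seed=3), q)
        s2 = score(train(X, y, kind="mlp", seed=3), q)
        assert np.array_equal(s1, s2)

    def test_single_identity_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((4, 2)), ["A"] * 4)


class TestWeightScores:
    def test_empty_history_passthrough(self):
        state = DecisionState()
        cur = np.array([0.2, 0.8])
        assert np.array_equal(weight_scores(state, cur, t_now=10.0), cur)

    def test_constant_history_fixed_point(self):
        state = DecisionState(n_history=4, sigma_s=2.0)
        v = np.array([0.25, 0.75])
        for t in range(4):
            state.push(float(t), v)
        assert np.allclose(weight_scores(state, v, t_now=4.0), v, atol=1e-15)

    def test_half_gaussian_ratio(self):
        # one past vector sigma seconds ago: weights 1 and e^{-1/2}
        sigma = 2.0
        state = DecisionState(n_history=4, sigma_s=sigma)
        state.push(0.0, np.array([1.0, 0.0]))
        out = weight_scores(state, np.array([0.0, 1.0]), t_now=sigma)
        w1 = np.exp(-0.5)
        expected = np.array([w1, 1.0]) / (1.0 + w1)
        assert np.allclose(out, expected, atol=1e-12)

    def test_convex_combination_invariants(self, rng):
        state = DecisionState(n_history=4, sigma_s=2.0)
        for t in range(4):
            p = rng.dirichlet(np.ones(5))
            state.push(float(t), p)
        cur = rng.dirichlet(np.ones(5))
        out = weight_scores(state, cur, t_now=4.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0) and np.all(out <= 1)

    def test_weights_nonincreasing_with_age(self):
        sigma = 2.0
        ages = np.array([0.0, 1.0, 2.0, 5.0])
        w = np.exp(-(ages**2) / (2 * sigma**2))
        assert np.all(np.diff(w) < 0)

    def test_buffer_caps_history(self):
        state = DecisionState(n_history=2)
        for t in range(5):
            state.push(float(t), np.array([1.0, 0.0]))
        assert len(state.history()) == 2
        assert state.history()[0][0] == 3.0

    def test_timestamps_must_increase(self):
        state = DecisionState()
        state.push(1.0, np.array([1.0]))
        with pytest.raises(ValueError):
            state.push(1.0, np.array([1.0]))


class TestAuthentication:
    def test_threshold_decision(self, toy_data):
        X, y = toy_data
        model = train(X, y, kind="knn", seed=0)
        profile = ThresholdProfile({"A": 0.6, "B": 0.6})
        assert authenticate(model, X[0], "A", profile)
        assert not authenticate(model, X[0], "B", profile)

    def test_unknown_identity_rejected(self, toy_data):
        X, y = toy_data
        model = train(X, y, kind="knn", seed=0)
        with pytest.raises(ValueError):
            authenticate(model, X[0], "C", ThresholdProfile({"C": 0.5}))

    def test_tuned_thresholds_separate_genuine_from_impostor(self, toy_data):
        X, y = toy_data
        model = train(X, y, kind="svm", seed=0)
        profile = tune_thresholds(model, X, y)
        assert set(profile.thresholds) == {"A", "B"}
        accepts_genuine = np.mean([authenticate(model, x, t, profile)
                                   for x, t in zip(X, y)])
        accepts_impostor = np.mean([authenticate(model, x, "A" if t == "B" else "B",
                                                 profile)
                                    for x, t in zip(X, y)])
        assert accepts_genuine > 0.9
        assert accepts_impostor < 0.1
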