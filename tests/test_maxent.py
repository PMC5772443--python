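import numpy as np
import pytest
from scipy import stats

from sdmcontrast.maxent import (LinearQuadraticFeatures, MaxentLQ,
                                sample_background, threshold_10pct,
                                training_auc)


class TestFeatures:
    def test_twelve_features_scaled_to_unit_interval(self, rng):
        X = rng.uniform(10, 30, size=(100, 6))
        f = LinearQuadraticFeatures().fit(X)
        F = f.transform(X)
        assert F.shape == (100, 12)
        assert np.allclose(F.min(axis=0), 0)
        assert np.allclose(F.max(axis=0), 1)

    def test_constant_variable_dropped_with_warning(self, rng):
        X = rng.uniform(size=(50, 6))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            f = LinearQuadraticFeatures().fit(X)
        assert f.n_features_out_ == 10

    def test_quadratic_is_square_before_scaling(self, rng):
        X = rng.uniform(1, 2, size=(40, 1))
        f = LinearQuadraticFeatures().fit(X)
        F = f.transform(X)
        # unscale the quadratic column and compare with the raw square
        raw_sq = F[:, 1] * f.scale_[1] + f.min_[1]
        assert np.allclose(raw_sq, X[:, 0] ** 2)

    def test_presences_use_background_scaling(self, rng):
        Xb = rng.uniform(0, 1, size=(60, 2))
        f = LinearQuadraticFeatures().fit(Xb)
        Xp = np.array([[2.0, 2.0]])  # outside background range
        assert (f.transform(Xp) > 1).all()


class TestSampleBackground:
    def test_all_cells_used_when_fewer_than_requested(self, rng):
        bias = np.zeros(1000)
        bias[rng.choice(1000, 300, replace=False)] = 1
        idx = sample_background(bias, 10_000, rng)
        assert idx.size == 300
        assert (bias[idx] == 1).all()

    def test_deterministic_under_seed(self):
        bias = np.ones(5000)
        a = sample_background(bias, 100, 7)
        b = sample_background(bias, 100, 7)
        assert np.array_equal(a, b)

    def test_sample_respects_bias(self, rng):
        bias = np.zeros(500)
        bias[::3] = 1
        idx = sample_background(bias, 50, rng)
        assert idx.size == 50
        assert (bias[idx] == 1).all()

    def test_empty_bias_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_background(np.zeros(10), 5, rng)


class TestMaxentFit:
    def test_infinite_regularization_gives_uniform(self, rng):
        X = rng.uniform(size=(120, 3))
        y = np.zeros(120)
        y[:10] = 1
        F = LinearQuadraticFeatures().fit(X[y == 0]).transform(X)
        model = MaxentLQ(reg_multiplier=1e9).fit(F, y)
        B = (y == 0).sum()
        assert np.allclose(model.lambda_, 0)
        assert np.allclose(model.q_, 1.0 / B)
        assert model.entropy_ == pytest.approx(np.log(B))

    def test_two_state_closed_form(self):
        """One binary feature, two background states, presence mean 0.8.

        The unregularized Gibbs solution puts q(1) = 0.8, q(0) = 0.2,
        i.e. lambda = log(4) up to the free normalization.
        """
        bg = np.array([[0.0], [1.0]])
        pres = np.array([[1.0]] * 8 + [[0.0]] * 2)  # mean 0.8
        X = np.vstack([bg, pres])
        y = np.concatenate([np.zeros(2), np.ones(10)])
        model = MaxentLQ(reg_multiplier=0.0, tol=1e-14,
                         min_presences=5).fit(X, y)
        assert model.q_[1] == pytest.approx(0.8, abs=1e-6)
        assert model.q_[0] == pytest.approx(0.2, abs=1e-6)
        assert model.lambda_[0] == pytest.approx(np.log(4), abs=1e-5)

    def test_unregularized_constraints_satisfied(self, rng):
        """E_q[f] equals the presence mean feature-wise without penalty."""
        Xb = rng.uniform(size=(80, 4))
        Xp = Xb[rng.choice(80, 20, replace=False)] + rng.normal(
            0, 0.01, size=(20, 4))
        X = np.vstack([Xb, Xp])
        y = np.concatenate([np.zeros(80), np.ones(20)])
        model = MaxentLQ(reg_multiplier=0.0, tol=1e-14, max_iter=2000).fit(
            X, y)
        eq = model.q_ @ Xb
        assert np.allclose(eq, Xp.mean(axis=0), atol=1e-4)

    def test_q_normalizes_and_entropy_bounded(self, rng):
        X = rng.uniform(size=(100, 3))
        y = np.zeros(100)
        y[rng.choice(100, 15, replace=False)] = 1
        F = LinearQuadraticFeatures().fit(X[y == 0]).transform(X)
        model = MaxentLQ().fit(F, y)
        assert model.q_.sum() == pytest.approx(1.0)
        assert 0 <= model.entropy_ <= np.log((y == 0).sum()) + 1e-12

    def test_objective_trace_monotone(self, rng):
        X = rng.uniform(size=(150, 5))
        y = np.zeros(150)
        y[rng.choice(150, 25, replace=False)] = 1
        F = LinearQuadraticFeatures().fit(X[y == 0]).transform(X)
        model = MaxentLQ().fit(F, y)
        diffs = np.diff(model.objective_trace_)
        assert (diffs >= -1e-9).all()

    def test_too_few_presences_rejected(self, rng):
        X = rng.uniform(size=(20, 2))
        y = np.zeros(20)
        y[:3] = 1
        with pytest.raises(ValueError, match="insufficient"):
            MaxentLQ().fit(X, y)

    def test_fit_deterministic(self, rng):
        X = rng.uniform(size=(90, 4))
        y = np.zeros(90)
        y[:12] = 1
        m1 = MaxentLQ().fit(X, y)
        m2 = MaxentLQ().fit(X, y)
        assert np.array_equal(m1.lambda_, m2.lambda_)

    def test_gaussian_niche_recovery(self, world):
        """Logistic output tracks the true suitability of a niche species.

        Presences are an (approximate) sample from the suitability
        distribution itself — the model's generative assumption — drawn
        without replacement over forest cells.
        """
        sp = world.species[0]  # narrow Gaussian-niche species
        forest = world.forest_mask
        env = np.column_stack([world.env[n].values[forest]
                               for n in world.env])
        suit_true = sp.true_suitability.values[forest]
        rng2 = np.random.default_rng(0)
        pres = rng2.choice(len(suit_true), size=200, replace=False,
                           p=suit_true / suit_true.sum())
        F = LinearQuadraticFeatures().fit(env).transform(env)
        X = np.vstack([F, F[pres]])
        y = np.concatenate([np.zeros(len(F)), np.ones(len(pres))])
        model = MaxentLQ().fit(X, y)
        rho = stats.spearmanr(model.predict_logistic(F), suit_true).statistic
        assert rho >= 0.8


class TestLogisticOutput:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.uniform(size=(100, 3))
        y = np.zeros(100)
        y[rng.choice(100, 20, replace=False)] = 1
        F = LinearQuadraticFeatures().fit(X[y == 0]).transform(X)
        return MaxentLQ().fit(F, y), F

    def test_typical_cell_maps_to_half(self, fitted):
        model, F = fitted
        # a cell with q~ = e^-H has logistic output exactly 0.5; invert the
        # fitted scores to find the feature-space score that achieves it
        t = model.log_z_ - model.entropy_  # lambda.f making e^H q~ = 1
        # construct synthetic feature row via scaling of an existing row
        lam = model.lambda_
        if np.allclose(lam, 0):
            pytest.skip("degenerate fit")
        x0 = F[0] * (t / (F[0] @ lam)) if F[0] @ lam != 0 else F[0]
        val = model.predict_logistic(x0[None, :])[0]
        assert val == pytest.approx(0.5, abs=1e-9)

    def test_zero_weights_constant_output(self, rng):
        X = rng.uniform(size=(50, 2))
        y = np.zeros(50)
        y[:10] = 1
        model = MaxentLQ(reg_multiplier=1e9).fit(X, y)
        out = model.predict_logistic(X)
        assert np.allclose(out, out[0])

    def test_order_preserved(self, fitted):
        model, F = fitted
        scores = model.decision_function(F)
        logi = model.predict_logistic(F)
        order = np.argsort(scores, kind="stable")
        assert np.all(np.diff(logi[order]) >= -1e-15)


def brute_force_auc(pres, bg):
    wins = 0.0
    for p in pres:
        for b in bg:
            wins += 1.0 if p > b else (0.5 if p == b else 0.0)
    return wins / (len(pres) * len(bg))


class TestTrainingAuc:
    @pytest.mark.parametrize("pres, bg, expected", [
        ([0.8, 0.9], [0.1, 0.2], 1.0),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
        ([0.9, 0.4], [0.5, 0.1], 0.75),
    ])
    def test_examples(self, pres, bg, expected):
        assert training_auc(pres, bg) == pytest.approx(expected)

    def test_matches_pairwise_oracle(self, rng):
        """200 random instances equal the brute-force win probability."""
        for _ in range(200):
            n1 = int(rng.integers(1, 20))
            n0 = int(rng.integers(1, 20))
            # discretized scores force plenty of ties
            pres = rng.integers(0, 5, size=n1) / 4
            bg = rng.integers(0, 5, size=n0) / 4
            assert training_auc(pres, bg) == pytest.approx(
                brute_force_auc(pres, bg), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        pres = rng.normal(size=25)
        bg = rng.normal(size=40)
        a1 = training_auc(pres, bg)
        a2 = training_auc(np.exp(pres), np.exp(bg))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestThreshold:
    def test_ten_presences_example(self):
        scores = np.arange(1, 11) / 10  # 0.1 .. 1.0
        t = threshold_10pct(scores)
        assert t == pytest.approx(0.2)
        assert (scores >= t).mean() == 0.9

    def test_all_equal(self):
        assert threshold_10pct([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_single_presence(self):
        assert threshold_10pct([0.73]) == pytest.approx(0.73)

    def test_at_least_ninety_percent_retained(self, rng):
        for _ in range(20):
            scores = rng.uniform(size=int(rng.integers(1, 60)))
            t = threshold_10pct(scores)
            assert (scores >= t).mean() >= 0.9 - 1e-12
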