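import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from zostera import (
    DepthGrid,
    auc_interpretation,
    balance_prevalence,
    crossvalidate_auc,
    fit_gam,
    predict_probability,
    predictor_contributions,
    response_curve,
    roc_auc,
)


def _table(y, **predictors):
    return pd.DataFrame({"presence": y, **predictors})


def _logistic_sample(n, seed, slope_a=1.2, slope_b=1.2):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n)
    p = expit(slope_a * a + slope_b * b)
    y = (rng.uniform(size=n) < p).astype(int)
    return _table(y, a=a, b=b)


class TestBalancePrevalence:
    def test_majority_subsampled_to_minority_size(self):
        y = np.r_[np.ones(100), np.zeros(300)]
        table = _table(y, x=np.arange(400.0))
        sample = balance_prevalence(table, seed=0)
        assert sample.n == 200
        assert sample.prevalence == 0.5

    def test_already_balanced_input_kept_complete(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        sample = balance_prevalence(_table(y, x=np.arange(100.0)), seed=0)
        assert sample.n == 100

    def test_deterministic_per_seed(self):
        y = np.r_[np.ones(100), np.zeros(300)]
        table = _table(y, x=np.arange(400.0))
        a = balance_prevalence(table, seed=3)
        b = balance_prevalence(table, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_prevalence(_table(np.ones(10), x=np.arange(10.0)), seed=0)


class TestFitGam:
    def test_separable_sample_reaches_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        mov = rng.uniform(0, 1, 400)
        pfd = rng.uniform(0, 500, 400)
        sample = balance_prevalence(
            _table((mov < 0.4).astype(int), pfd=pfd, mov=mov), seed=0
        )
        model = fit_gam(sample)
        scores = model.predict({n: sample.data[n].to_numpy() for n in ("pfd", "mov")})
        assert roc_auc(scores, sample.presence) == 1.0

    def test_uninformative_predictors_explain_almost_nothing(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 2000)
        sample = balance_prevalence(
            _table(y, a=rng.normal(0, 1, 2000), b=rng.normal(0, 1, 2000)), seed=0
        )
        model = fit_gam(sample)
        assert model.explained_deviance < 0.02

    def test_matches_unpenalized_glm_on_same_design(self):
        sample = balance_prevalence(_logistic_sample(1200, seed=2), seed=1)
        model = fit_gam(sample, ridge=1e-9, tol=1e-12)
        X = model.design_matrix({n: sample.data[n].to_numpy() for n in ("a", "b")})
        glm = smapi.GLM(sample.presence, X, family=smapi.families.Binomial()).fit()
        mine = model.predict({n: sample.data[n].to_numpy() for n in ("a", "b")})
        np.testing.assert_allclose(mine, glm.fittedvalues, atol=1e-6)

    def test_mean_fitted_probability_matches_training_prevalence(self):
        sample = balance_prevalence(_logistic_sample(1000, seed=3), seed=0)
        model = fit_gam(sample)
        p = model.predict({n: sample.data[n].to_numpy() for n in ("a", "b")})
        assert abs(p.mean() - sample.prevalence) < 0.02

    def test_constant_predictor_rejected(self):
        y = np.r_[np.ones(60), np.zeros(60)]
        table = _table(y, a=np.ones(120), b=np.arange(120.0))
        with pytest.raises(ValueError, match="constant"):
            fit_gam(balance_prevalence(table, seed=0))

    def test_small_classes_rejected(self):
        table = _logistic_sample(40, seed=0)
        with pytest.raises(ValueError, match="at least"):
            fit_gam(balance_prevalence(table, seed=0))

    def test_serialization_round_trip_preserves_predictions(self, tmp_path):
        from zostera.sdm import FittedSDM

        sample = balance_prevalence(_logistic_sample(800, seed=4), seed=0)
        model = fit_gam(sample)
        model.to_json(tmp_path / "model.json")
        back = FittedSDM.from_json(tmp_path / "model.json")
        grid_vals = {"a": np.linspace(-2, 2, 50), "b": np.zeros(50)}
        np.testing.assert_allclose(back.predict(grid_vals), model.predict(grid_vals))


class TestPredictProbability:
    def test_constant_fields_reproduce_pointwise_value(self):
        sample = balance_prevalence(_logistic_sample(800, seed=5), seed=0)
        model = fit_gam(sample)
        grid = DepthGrid(depth=np.full((4, 5), 5.0))
        a0, b0 = sample.data["a"].iloc[0], sample.data["b"].iloc[0]
        out = predict_probability(
            model, grid, {"a": np.full(grid.shape, a0), "b": np.full(grid.shape, b0)}
        )
        expected = model.predict({"a": np.array([a0]), "b": np.array([b0])})[0]
        np.testing.assert_allclose(out, expected)

    def test_out_of_scope_cells_emit_nan(self):
        sample = balance_prevalence(_logistic_sample(800, seed=5), seed=0)
        model = fit_gam(sample)
        grid = DepthGrid(depth=np.array([[5.0, -1.0], [13.0, 2.0]]))
        out = predict_probability(
            model, grid, {"a": np.zeros((2, 2)), "b": np.zeros((2, 2))}
        )
        assert np.isnan(out[0, 1]) and np.isnan(out[1, 0])
        assert np.isfinite(out[0, 0]) and np.isfinite(out[1, 1])

    def test_monotone_truth_means_raising_predictor_raises_probability(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(0, 1, 2000)
        y = (rng.uniform(size=2000) < expit(2.0 * a)).astype(int)
        sample = balance_prevalence(_table(y, a=a, b=b), seed=0)
        model = fit_gam(sample)
        grid = DepthGrid(depth=np.full((3, 3), 5.0))
        lo = predict_probability(
            model, grid, {"a": np.full((3, 3), -0.5), "b": np.zeros((3, 3))}
        )
        hi = predict_probability(
            model, grid, {"a": np.full((3, 3), 0.5), "b": np.zeros((3, 3))}
        )
        assert (hi > lo).all()

    def test_extrapolation_warns_but_predicts(self):
        sample = balance_prevalence(_logistic_sample(800, seed=7), seed=0)
        model = fit_gam(sample)
        with pytest.warns(UserWarning, match="training range"):
            p = model.predict({"a": np.array([99.0]), "b": np.array([0.0])})
        assert 0.0 <= p[0] <= 1.0


class TestResponseCurve:
    @pytest.fixture(scope="class")
    def fitted(self):
        sample = balance_prevalence(_logistic_sample(3000, seed=8), seed=0)
        return sample, fit_gam(sample)

    def test_bands_bracket_the_curve(self, fitted):
        sample, model = fitted
        vals = np.linspace(-2, 2, 100)
        rc = response_curve(model, "a", vals)
        assert (rc.lower <= rc.effect).all() and (rc.effect <= rc.upper).all()

    def test_bands_widen_at_data_sparse_extremes(self, fitted):
        sample, model = fitted
        x = sample.data["a"].to_numpy()
        vals = np.array([x.min(), np.median(x), x.max()])
        rc = response_curve(model, "a", vals)
        width = rc.upper - rc.lower
        assert width[0] > width[1] and width[2] > width[1]

    def test_effect_near_zero_at_training_mean(self, fitted):
        sample, model = fitted
        rc = response_curve(model, "a", np.array([sample.data["a"].mean()]))
        assert abs(rc.effect[0]) < 0.25

    def test_monotone_truth_recovered_over_central_range(self, fitted):
        sample, model = fitted
        x = sample.data["a"].to_numpy()
        lo, hi = np.percentile(x, [5, 95])
        rc = response_curve(model, "a", np.linspace(lo, hi, 100))
        assert (np.diff(rc.effect) > 0).all()

    def test_unknown_predictor_rejected(self, fitted):
        _, model = fitted
        with pytest.raises(KeyError):
            response_curve(model, "salinity", np.linspace(0, 1, 5))


class TestPredictorContributions:
    def test_informative_predictor_dominates_noise(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 3000)
        y = (rng.uniform(size=3000) < expit(2.4 * x)).astype(int)
        sample = balance_prevalence(
            _table(y, signal=x, noise=rng.normal(0, 1, 3000)), seed=0
        )
        contrib = predictor_contributions(sample)
        assert contrib["signal"] > 90.0

    def test_exchangeable_predictors_split_evenly(self):
        sample = balance_prevalence(_logistic_sample(3000, seed=0), seed=0)
        contrib = predictor_contributions(sample)
        assert contrib["a"] == pytest.approx(50.0, abs=5.0)
        assert contrib["b"] == pytest.approx(50.0, abs=5.0)

    def test_shares_sum_to_hundred(self):
        sample = balance_prevalence(_logistic_sample(1000, seed=1), seed=0)
        assert predictor_contributions(sample).sum() == pytest.approx(100.0)


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_pairs(self):
        # pairs: (.9 vs .8) win, (.9 vs .2) win, (.4 vs .8) loss, (.4 vs .2) win
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = rng.integers(4, 30)
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(brute)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    @pytest.mark.parametrize(
        "auc,label",
        [(0.5, "none"), (0.65, "low"), (0.77, "acceptable"), (0.85, "excellent")],
    )
    def test_interpretation_bands(self, auc, label):
        assert auc_interpretation(auc) == label


class TestCrossValidation:
    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(11)
        mov = rng.uniform(0, 1, 900)
        margin = (mov < 0.45) | (mov > 0.55)  # wide-margin separation
        mov = mov[margin]
        sample = balance_prevalence(
            _table((mov < 0.5).astype(int), mov=mov, other=rng.uniform(0, 1, mov.size)),
            seed=0,
        )
        cv = crossvalidate_auc(sample, k=5, seed=0)
        assert cv.mean == 1.0 and cv.sd == 0.0

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 2000)
        sample = balance_prevalence(
            _table(y, a=rng.normal(0, 1, 2000), b=rng.normal(0, 1, 2000)), seed=0
        )
        cv = crossvalidate_auc(sample, k=5, seed=0)
        assert cv.mean == pytest.approx(0.5, abs=0.05)

    def test_deterministic_per_seed(self):
        sample = balance_prevalence(_logistic_sample(800, seed=13), seed=0)
        a = crossvalidate_auc(sample, seed=4)
        b = crossvalidate_auc(sample, seed=4)
        assert a.aucs == b.aucs
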