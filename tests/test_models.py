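"""Model fitting, prediction, cross-validation and stepwise selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phenorosette import models, synthetic
from phenorosette.models import (
    CVConfig,
    TraitModel,
    cross_validate,
    fit,
    predict,
    reference_dry_mass_model,
    reference_fruit_model,
    stepwise_select,
)


def _lasso_cd_oracle(X, y, penalty, n_iter=2000):
    """Tiny coordinate-descent lasso on standardized predictors, returning
    slopes on the original scale (independent of scikit-learn)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    mu, sd = X.mean(0), X.std(0)
    Z = (X - mu) / sd
    n, p = Z.shape
    yc = y - y.mean()
    beta = np.zeros(p)
    for _ in range(n_iter):
        for j in range(p):
            r = yc - Z @ beta + Z[:, j] * beta[j]
            rho = Z[:, j] @ r / n
            beta[j] = np.sign(rho) * max(abs(rho) - penalty, 0.0)
    return beta / sd


class TestFit:
    def test_exact_linear_relation_recovered(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"x": x})
        m = fit(X, 2 * x + 1, family="linear")
        assert m.intercept == pytest.approx(1.0)
        assert m.coefficients["x"] == pytest.approx(2.0)

    def test_quadratic_family_recovers_parabola(self):
        x = np.linspace(-3, 3, 40)
        X = pd.DataFrame({"x": x})
        m = fit(X, 1 + 2 * x - 0.5 * x**2, family="quadratic")
        assert m.coefficients["x"] == pytest.approx(2.0)
        assert m.coefficients["x^2"] == pytest.approx(-0.5)

    def test_ridge_shrinks_to_zero_at_huge_penalty(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = 3 * X.a + 2 * X.b
        m = fit(X, y, family="ridge", penalty=1e12)
        assert all(abs(v) < 1e-6 for v in m.coefficients.values())

    def test_lasso_zeroes_irrelevant_predictor(self):
        rng = np.random.default_rng(1)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 3 * x1 + rng.normal(scale=0.3, size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        penalty = 0.5
        m = fit(X, y, family="lasso", penalty=penalty)
        oracle = _lasso_cd_oracle(X.to_numpy(), y, penalty)
        assert m.coefficients["x2"] == 0.0 == pytest.approx(oracle[1])
        assert m.coefficients["x1"] == pytest.approx(oracle[0], rel=1e-3)

    @pytest.mark.parametrize("family", ["ridge", "lasso"])
    def test_zero_penalty_equals_least_squares(self, family):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(scale=0.1, size=60)
        lin = fit(X, y, family="linear")
        pen = fit(X, y, family=family, penalty=0.0)
        for k in "abc":
            assert pen.coefficients[k] == pytest.approx(
                lin.coefficients[k], abs=1e-6
            )

    def test_collinear_columns_raise_with_names(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": np.random.default_rng(0).normal(size=10)})
        with pytest.raises(ValueError, match="b"):
            fit(X, x, family="linear")

    def test_collinear_columns_dropped_on_request(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        m = fit(X, 3 * x, family="linear", on_collinear="drop")
        assert m.coefficients["b"] == 0.0
        assert m.coefficients["a"] == pytest.approx(3.0)
        assert predict(m, X) == pytest.approx(3 * x)

    def test_json_round_trip(self, tmp_path):
        m = reference_dry_mass_model()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = TraitModel.from_json(path)
        assert back == m


class TestPredict:
    def test_reference_dry_mass_values(self):
        m = reference_dry_mass_model()
        X = pd.DataFrame({"RA": [0.0, 1.0], "Circ": [0.0, 1.0]})
        out = predict(m, X)
        assert out[0] == pytest.approx(-0.00133)
        assert out[1] == pytest.approx(-0.00133 + 0.00134 + 0.00274)

    def test_reference_fruit_values(self):
        m = reference_fruit_model()
        X = pd.DataFrame(
            {
                "n_actual_junctions": [1, 0, 0],
                "n_slab_pixels": [0, 1, 0],
                "n_triple_points": [0, 0, 1],
            }
        )
        assert predict(m, X) == pytest.approx([0.181, 0.003, 0.226])

    def test_missing_predictor_column_raises(self):
        with pytest.raises(ValueError, match="Circ"):
            predict(reference_dry_mass_model(), pd.DataFrame({"RA": [1.0]}))


class TestCrossValidate:
    def test_noiseless_linear_data_scores_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.uniform(size=150), "b": rng.uniform(size=150)})
        y = 2 * X.a - X.b + 0.5
        res = cross_validate(
            X, y, ["linear"],
            CVConfig(training_sizes=[10], n_permutations=20,
                     holdout_size=50, seed=0),
        )
        assert res.mean_r2("linear", 10) == pytest.approx(1.0)

    def test_r2_invariant_to_affine_rescaling_of_response(self):
        df, _ = synthetic.gen_training_table(
            200, {"a": 2.0, "b": -1.0}, noise_cv=0.1, seed=4
        )
        cfg = CVConfig(training_sizes=[30], n_permutations=20,
                       holdout_size=50, seed=7)
        r1 = cross_validate(df[["a", "b"]], df.response, ["linear"], cfg)
        r2 = cross_validate(
            df[["a", "b"]], 100.0 * df.response + 3.0, ["linear"], cfg
        )
        assert r1.mean_r2("linear", 30) == pytest.approx(
            r2.mean_r2("linear", 30)
        )

    def test_mean_r2_nondecreasing_in_training_size(self):
        df, _ = synthetic.gen_training_table(
            400, {"a": 1.0, "b": 2.0, "c": -1.0}, noise_cv=0.3, seed=5
        )
        res = cross_validate(
            df[["a", "b", "c"]], df.response, ["linear"],
            CVConfig(training_sizes=[10, 30, 100], n_permutations=100,
                     holdout_size=100, seed=1),
        )
        r = [res.mean_r2("linear", s) for s in (10, 30, 100)]
        assert r[0] <= r[1] + 1e-3 and r[1] <= r[2] + 1e-3

    def test_ridge_beats_ols_on_small_collinear_training_sets(self):
        # 9 noisy copies of one signal, trained on only 10 rows: shrinkage
        # should not do worse than plain least squares
        rng = np.random.default_rng(6)
        n = 200
        z = rng.normal(size=n)
        X = pd.DataFrame(
            {f"x{j}": z + rng.normal(scale=0.05, size=n) for j in range(9)}
        )
        y = z + rng.normal(scale=0.3, size=n)
        res = cross_validate(
            X, y, ["linear", "ridge"],
            CVConfig(training_sizes=[10], n_permutations=100,
                     holdout_size=80, seed=2),
        )
        assert res.mean_r2("ridge", 10) >= res.mean_r2("linear", 10)

    def test_identical_seed_reproduces_table(self):
        df, _ = synthetic.gen_training_table(
            150, {"a": 1.0}, noise_cv=0.2, seed=8
        )
        cfg = CVConfig(training_sizes=[20], n_permutations=10,
                       holdout_size=40, seed=11)
        t1 = cross_validate(df[["a"]], df.response, ["linear"], cfg).table
        t2 = cross_validate(df[["a"]], df.response, ["linear"], cfg).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_request_rejected(self):
        df, _ = synthetic.gen_training_table(50, {"a": 1.0}, seed=0)
        with pytest.raises(ValueError):
            cross_validate(
                df[["a"]], df.response, ["linear"],
                CVConfig(training_sizes=[40], holdout_size=20, seed=0),
            )


def _best_subset_oracle(X, y):
    """Exhaustive AIC minimization over all predictor subsets."""
    names = list(X.columns)
    n = len(y)
    best, best_aic = None, np.inf
    for k in range(len(names) + 1):
        for subset in itertools.combinations(names, k):
            cols = X[list(subset)].to_numpy() if subset else np.empty((n, 0))
            A = np.column_stack([np.ones(n), cols])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ beta) ** 2))
            aic = n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)
            if aic < best_aic:
                best, best_aic = set(subset), aic
    return best, best_aic


class TestStepwise:
    def test_single_true_predictor_selected(self):
        rng = np.random.default_rng(9)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
        y = 2.0 * X.x1 + rng.normal(scale=0.5, size=n)
        m = stepwise_select(X, y)
        oracle, _ = _best_subset_oracle(X, y.to_numpy())
        assert set(m.predictor_order) == oracle == {"x1"}

    def test_pure_noise_matches_best_subset_oracle(self):
        """On pure noise the AIC penalty generically leaves the intercept-
        only model; whenever a chance correlation survives, bidirectional
        stepwise must still land on the exhaustive-search optimum."""
        for seed in range(4):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(size=(200, 3)), columns=["a", "b", "c"]
            )
            y = rng.normal(size=200)
            m = stepwise_select(X, y)
            oracle, _ = _best_subset_oracle(X, y)
            assert set(m.predictor_order) == oracle
        # the generic outcome (seed 0): intercept-only
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=200)
        m = stepwise_select(X, y)
        assert m.predictor_order == []
        assert m.intercept == pytest.approx(np.mean(y))

    def test_exact_two_predictor_model_selected(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["x1", "x2", "x3"])
        y = X.x1 + X.x2
        m = stepwise_select(X, y)
        assert set(m.predictor_order) == {"x1", "x2"}

    def test_never_worse_than_full_model(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = X.a - X.c + rng.normal(scale=1.0, size=80)
        m = stepwise_select(X, y)
        n = len(y)
        A = np.column_stack([np.ones(n), X.to_numpy()])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss_full = float(np.sum((y - A @ beta) ** 2))
        aic_full = n * np.log(rss_full / n) + 2 * (X.shape[1] + 1)
        assert m.metadata["aic"] <= aic_full + 1e-9
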