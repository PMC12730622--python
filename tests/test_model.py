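"""Ridge logistic model: optimizer, lambda selection, prediction, curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import karstsdm as k
from karstsdm.model import RidgeLogit


def toy_table(n=200, p=3, seed=0, beta=None, n_presence=None):
    """Non-separable weighted presence-background style table."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    prob = expit(X @ beta - 0.5)
    y = (rng.random(n) < prob).astype(int)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    w = np.where(y == 1, 0.5 / y.sum(), 0.5 / (n - y.sum()))
    return X, y, w


class TestFit:
    def test_extreme_shrinkage_leaves_null_model(self):
        X, y, w = toy_table(seed=1, beta=[2, -1, 0])
        res = RidgeLogit(y, X, w).fit(lambda_=1e6)
        assert np.abs(res.params[1:]).max() < 1e-4
        # weighted prevalence is 0.5 by construction -> intercept logit(0.5)=0
        assert abs(res.intercept) < 1e-4

    def test_unpenalized_fit_matches_independent_optimizer(self):
        """lambda=0 equals a scipy-minimize oracle on the weighted NLL."""
        X, y, w = toy_table(n=150, seed=2, beta=[1.0, -1.0, 0.3])
        res = RidgeLogit(y, X, w).fit(lambda_=0.0)

        def nll(b):
            eta = b[0] + X @ b[1:]
            return np.sum(w * (np.logaddexp(0, eta) - y * eta))

        oracle = minimize(nll, np.zeros(4), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(res.params, oracle.x, atol=1e-6)

    def test_objective_path_monotone_and_converged(self):
        X, y, w = toy_table(seed=3, beta=[1, 1, -1])
        res = RidgeLogit(y, X, w).fit(lambda_=0.05)
        assert res.converged
        diffs = np.diff(res.objective_path)
        assert (diffs <= 1e-12).all()

    def test_slope_norm_non_increasing_in_lambda(self):
        X, y, w = toy_table(n=300, seed=4, beta=[2, -2, 0.5])
        model = RidgeLogit(y, X, w)
        grid = model.default_lambda_grid(20)
        norms = []
        start = None
        for lam in grid:
            b, conv, _, _ = model._fit_one(lam, start=start)
            start = b
            norms.append(np.linalg.norm(b[1:]))
        assert all(n2 >= n1 - 1e-8 for n1, n2 in zip(norms, norms[1:]))

    def test_internal_cv_selects_from_grid(self):
        X, y, w = toy_table(n=400, seed=5, beta=[1.5, -1.5, 0])
        res = RidgeLogit(y, X, w).fit(n_lambda=25, cv_folds=4, seed=0)
        assert res.lambda_ in res.lambda_grid
        assert res.cv_deviance.shape == (25,)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="single class"):
            RidgeLogit(np.ones(20), X)

    def test_single_presence_requires_fixed_lambda(self):
        X, y, w = toy_table(n=50, seed=6)
        y[:] = 0
        y[0] = 1
        w = np.where(y == 1, 0.5, 0.5 / 49)
        with pytest.raises(ValueError, match="lambda"):
            RidgeLogit(y, X, w).fit()
        res = RidgeLogit(y, X, w).fit(lambda_=1.0)  # fixed lambda works
        assert res.converged

    def test_sign_recovery_on_synthetic_landscapes(self):
        """Known generative betas (+2, -2, 0): signs recovered, null smallest."""
        hits = 0
        for seed in range(3):
            stack = k.generate_landscape(k.LandscapeConfig(seed=100 + seed))
            truth = k.TrueModel(-0.5, {"elev_m": 2.0, "SAND_05cm": -2.0, "CEC_05cm": 0.0})
            occ = k.generate_occurrences(stack, truth, 300, seed=seed)
            elev = stack.extract(occ.xy[:, 0], occ.xy[:, 1], ["elev_m"])[:, 0]
            mask = k.build_mask(stack, k.elevation_band(elev))
            stack_z, _ = k.standardize(stack, mask.cells)
            bg = k.sample_background(mask, occ, seed=seed, n_total=2000)
            rep = k.CollinearityReport(kept=["elev_m", "SAND_05cm", "CEC_05cm"])
            table = k.assemble_training(stack_z, occ, bg, rep)
            res = RidgeLogit.from_training_table(table).fit(n_lambda=20, seed=seed)
            c = res.coefficients
            if (
                c["elev_m"] > 0
                and c["SAND_05cm"] < 0
                and abs(c["CEC_05cm"]) == np.abs(c).min()
            ):
                hits += 1
        assert hits >= 2


class TestPredict:
    def test_null_model_gives_half_everywhere(self, fitted_problem):
        table, mask, stack_z = (
            fitted_problem["table"], fitted_problem["mask"], fitted_problem["stack_z"],
        )
        model = RidgeLogit.from_training_table(table)
        res = k.RidgeLogitResults(
            model=model, params=np.zeros(len(table.predictors) + 1), lambda_=1.0,
            lambda_grid=np.array([1.0]), cv_deviance=None, converged=True, n_iter=0,
        )
        smap = res.predict_suitability(stack_z, mask)
        np.testing.assert_allclose(smap.masked_values(), 0.5)

    def test_map_matches_scalar_oracle(self, fitted_problem):
        table, mask, stack_z = (
            fitted_problem["table"], fitted_problem["mask"], fitted_problem["stack_z"],
        )
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.5)
        smap = res.predict_suitability(stack_z, mask)
        rows, cols = np.nonzero(mask.cells)
        for i in np.random.default_rng(0).choice(rows.size, 25, replace=False):
            eta = res.intercept
            for name, beta in res.coefficients.items():
                eta += beta * stack_z[name].values[rows[i], cols[i]]
            assert smap.values[rows[i], cols[i]] == pytest.approx(expit(eta), abs=1e-12)

    def test_monotone_in_positive_coefficient_predictor(self, fitted_problem):
        table = fitted_problem["table"]
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.5)
        name = res.coefficients.abs().idxmax()
        j = table.predictors.index(name)
        x = table.X[:1].copy()
        bumped = x.copy()
        bumped[0, j] += 1.0
        lo, hi = res.predict(x)[0], res.predict(bumped)[0]
        if res.coefficients[name] > 0:
            assert hi > lo
        else:
            assert hi < lo

    def test_missing_layer_named(self, fitted_problem):
        table, mask = fitted_problem["table"], fitted_problem["mask"]
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.5)
        incomplete = k.RasterStack([fitted_problem["stack_z"]["elev_m"].copy()])
        with pytest.raises(ValueError, match="SAND_05cm"):
            res.predict_suitability(incomplete, mask)

    def test_prediction_invariant_to_column_order(self, fitted_problem):
        table = fitted_problem["table"]
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.3)
        reordered = table.predictors[::-1]
        df = table.data[reordered + ["x", "y", "stratum", "label", "weight"]]
        table2 = k.TrainingTable(df, reordered)
        res2 = RidgeLogit.from_training_table(table2).fit(lambda_=0.3)
        np.testing.assert_allclose(
            res.predict(table.data[table.predictors]),
            res2.predict(table2.data[reordered]),
            atol=1e-10,
        )


class TestPartialDependence:
    def test_zero_coefficient_curve_is_flat(self, fitted_problem):
        table = fitted_problem["table"]
        model = RidgeLogit.from_training_table(table)
        params = np.zeros(len(table.predictors) + 1)
        params[0] = 0.3
        res = k.RidgeLogitResults(
            model=model, params=params, lambda_=1.0, lambda_grid=np.array([1.0]),
            cv_deviance=None, converged=True, n_iter=0,
        )
        curve = res.partial_dependence(table, table.predictors[0])
        np.testing.assert_allclose(curve.suitability, expit(0.3))
        assert curve.sign == "near-flat"

    def test_at_background_mean_matches_closed_form(self, fitted_problem):
        table = fitted_problem["table"]
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.2)
        name = table.predictors[1]
        curve = res.partial_dependence(table, name, mode="at-background-mean")
        bg = table.data[table.data["label"] == 0]
        means = bg[table.predictors].mean()
        beta = res.coefficients
        other = sum(beta[p] * means[p] for p in table.predictors if p != name)
        expected = expit(res.intercept + beta[name] * curve.values_z + other)
        np.testing.assert_allclose(curve.suitability, expected, atol=1e-12)

    def test_sign_labels_follow_dominant_effects(self, fitted_problem):
        """Strong +elevation / -sand generative effects produce +/- labels."""
        table = fitted_problem["table"]
        res = RidgeLogit.from_training_table(table).fit(n_lambda=20, seed=0)
        assert res.partial_dependence(table, "elev_m").sign == "+"
        assert res.partial_dependence(table, "SAND_05cm").sign == "-"

    def test_background_averaged_mode_and_unknown_predictor(self, fitted_problem):
        table = fitted_problem["table"]
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.2)
        curve = res.partial_dependence(table, "elev_m", mode="background-averaged")
        assert curve.suitability.min() >= 0 and curve.suitability.max() <= 1
        assert (np.diff(curve.values_z) > 0).all()
        with pytest.raises(ValueError, match="unknown predictor"):
            res.partial_dependence(table, "nope")

    def test_original_units_returned_when_standardized(self, fitted_problem):
        table, params = fitted_problem["table"], fitted_problem["params"]
        res = RidgeLogit.from_training_table(table, standardization=params).fit(lambda_=0.2)
        curve = res.partial_dependence(table, "elev_m")
        np.testing.assert_allclose(
            curve.values, params.inverse("elev_m", curve.values_z)
        )
        assert curve.values.min() > 100.0  # metres, not z-scores


class TestReporting:
    def test_summary_lists_all_predictors(self, fitted_problem):
        table = fitted_problem["table"]
        res = RidgeLogit.from_training_table(table).fit(lambda_=0.4)
        text = res.summary()
        for name in table.predictors:
            assert name in text

    def test_json_roundtrip_fields(self, tmp_path, fitted_problem):
        import json

        table, params = fitted_problem["table"], fitted_problem["params"]
        res = RidgeLogit.from_training_table(table, standardization=params).fit(lambda_=0.4)
        res.to_json(tmp_path / "m.json")
        d = json.loads((tmp_path / "m.json").read_text())
        assert d["exog_names"] == table.predictors
        assert "standardization" in d and d["lambda"] == 0.4
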