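import numpy as np
import pandas as pd
import pytest

import replichrom as rc
from replichrom import lasso as ls
from replichrom import synthetic as syn
from replichrom._rng import substream

from conftest import toy_features


class TestExpansion:
    def test_order2_full_pairs(self, rng):
        X = toy_features(rng, n=50, p=3)
        d = rc.expand_interactions(X, order=2)
        assert d.term_names == ["f0", "f1", "f2", "f0:f1", "f0:f2", "f1:f2"]

    def test_order3_adds_triple(self, rng):
        X = toy_features(rng, n=50, p=3)
        d = rc.expand_interactions(X, order=3)
        assert len(d.term_names) == 7
        assert "f0:f1:f2" in d.term_names

    def test_hm_squared_plus_cbp_recipe(self, rng):
        X = toy_features(rng, n=50, p=4)
        X.columns = ["h1", "h2", "c1", "c2"]
        d = rc.expand_interactions(
            X, order=2, sets={"HM": ["h1", "h2"], "CBP": ["c1", "c2"]},
            interacting_sets=["HM"],
        )
        assert set(d.term_names) == {"h1", "h2", "c1", "c2", "h1:h2"}

    def test_cross_set_pools_features(self, rng):
        X = toy_features(rng, n=50, p=4)
        X.columns = ["h1", "h2", "c1", "c2"]
        d = rc.expand_interactions(
            X, order=2, sets={"HM": ["h1", "h2"], "CBP": ["c1", "c2"]}, mode="cross-set"
        )
        assert "h1:c1" in d.term_names and len(d.term_names) == 4 + 6

    def test_duplicate_features_rejected(self, rng):
        X = toy_features(rng, n=20, p=2)
        X.columns = ["a", "a"]
        with pytest.raises(ValueError, match="duplicate"):
            rc.expand_interactions(X, order=2)

    def test_products_on_standardized_mains(self, rng):
        X = toy_features(rng, n=500, p=2)
        d = rc.expand_interactions(X, order=2)
        z0 = (X["f0"] - X["f0"].mean()) / X["f0"].std(ddof=0)
        z1 = (X["f1"] - X["f1"].mean()) / X["f1"].std(ddof=0)
        np.testing.assert_allclose(d.values["f0:f1"], z0 * z1, atol=1e-12)


class TestSplit:
    def test_disjoint_exhaustive(self):
        tr, te = rc.split_train_test(list("abcdefghij"), 7, seed=0)
        assert len(tr) == 7 and len(te) == 3
        assert set(tr) | set(te) == set("abcdefghij")
        assert not set(tr) & set(te)

    def test_seed_reproducibility(self):
        assert rc.split_train_test(list(range(100)), 60, 5) == rc.split_train_test(
            list(range(100)), 60, 5
        )

    def test_partition_property_over_seeds(self):
        ids = [f"r{i}" for i in range(37)]
        for seed in range(100):
            tr, te = rc.split_train_test(ids, 20, seed)
            assert sorted(tr + te) == sorted(ids)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rc.split_train_test([1, 2, 3], 3, 0)


class TestFit:
    def test_exact_support_recovery(self):
        """Two real effects among eight nuisance columns: λ* support is exact."""
        hits = 0
        for seed in range(20):
            rng = substream(seed, "support-test")
            X = toy_features(rng, n=2000, p=10, prefix="x")
            y = pd.Series(
                2.0 * X["x1"].to_numpy() - 1.0 * X["x2"].to_numpy()
                + 0.1 * rng.standard_normal(2000),
                index=X.index,
            )
            d = rc.build_design(X, rc.ExpansionSpec(order=1))
            fit = rc.fit_lasso_cv(d, y, k_folds=10, seed=seed, n_lambdas=50)
            if set(fit.support) == {"x1", "x2"}:
                hits += 1
        assert hits >= 19

    def test_constant_response_gives_zero_model(self, rng):
        X = toy_features(rng, n=100, p=3)
        y = pd.Series(2.5, index=X.index)
        d = rc.build_design(X, rc.ExpansionSpec(order=1))
        with pytest.warns(UserWarning, match="constant"):
            fit = rc.fit_lasso_cv(d, y, k_folds=5, seed=0)
        assert fit.degenerate
        assert np.all(fit.coefs == 0)
        assert fit.intercepts[0] == pytest.approx(2.5)

    def test_zero_model_at_lambda_max(self, fitted_model):
        _, _, fit, _, _ = fitted_model
        assert np.all(fit.coefs[:, 0] == 0)

    def test_lambda_star_attains_min_cv_mse(self, fitted_model):
        _, _, fit, _, _ = fitted_model
        assert fit.cv_mse_mean[fit.lambda_star_idx] == fit.cv_mse_mean.min()

    def test_penalized_objective_beats_coarse_grid(self):
        """On tiny instances the solver's objective is below any point of a
        21³ coefficient grid over [-3, 3]³, at every λ on the path."""
        rng = substream(99, "grid-oracle")
        for _ in range(3):
            X = rng.standard_normal((30, 3))
            X = (X - X.mean(0)) / X.std(0)
            y = X @ rng.normal(size=3) + 0.5 * rng.standard_normal(30)
            Xdf = pd.DataFrame(X, columns=list("abc"))
            yds = pd.Series(y, index=Xdf.index)
            d = rc.build_design(Xdf, rc.ExpansionSpec(order=1))
            fit = rc.fit_lasso_cv(d, yds, k_folds=5, seed=0, n_lambdas=40,
                                  tol=1e-10, max_iter=100_000)
            # refit on all rows per lambda via the stored standardized design
            from sklearn.linear_model import lasso_path
            D = (d.values.to_numpy() - fit.col_mean) / fit.col_sd
            yc = y - y.mean()
            _, coefs, _ = lasso_path(D, yc, alphas=fit.lambdas, tol=1e-12, max_iter=200_000)
            axis = np.linspace(-3, 3, 21)
            grid = np.stack(np.meshgrid(axis, axis, axis), -1).reshape(-1, 3).T
            rss_grid = ((yc[:, None] - D @ grid) ** 2).sum(0) / (2 * len(y))
            l1_grid = np.abs(grid).sum(0)
            for g, lam in enumerate(fit.lambdas):
                obj_solver = ((yc - D @ coefs[:, g]) ** 2).sum() / (2 * len(y)) \
                    + lam * np.abs(coefs[:, g]).sum()
                obj_grid = (rss_grid + lam * l1_grid).min()
                assert obj_solver <= obj_grid + 1e-9

    def test_in_sample_fit_monotone_in_interaction_order(self, rng):
        X = toy_features(rng, n=300, p=4)
        y = pd.Series(
            X["f0"].to_numpy() + X["f1"].to_numpy() * X["f2"].to_numpy()
            + 0.3 * rng.standard_normal(300),
            index=X.index,
        )
        r2 = {}
        for order in (2, 3):
            d = rc.build_design(X, rc.ExpansionSpec(order=order))
            fit = rc.fit_lasso_cv(d, y, k_folds=5, seed=0, n_lambdas=40)
            res = rc.predict(fit, X, y, lambda_idx=len(fit.lambdas) - 1)
            r2[order] = 1 - np.var(res.residuals) / np.var(y)
        assert r2[3] >= r2[2] - 1e-6

    def test_beats_zero_model_on_informative_data(self):
        """Fold-averaged model at λ* has lower test MSE than predicting the
        training mean whenever the data carry signal (oracle R² ≥ 0.3)."""
        for seed in range(20):
            cfg = syn.SynthConfig(n_regions=800, seed=seed)
            cfg = syn.SynthConfig(**{**cfg.__dict__, "noise_sd": syn.noise_sd_for_r2(cfg, 0.4)})
            ds = syn.generate_promoter_dataset(cfg)
            d = rc.build_design(ds.features, rc.ExpansionSpec(order=1))
            tr, te = rc.split_train_test(list(ds.features.index), 550, seed)
            fit = rc.fit_lasso_cv(d, ds.timing, k_folds=5, seed=seed,
                                  n_lambdas=40, train_ids=tr, test_ids=te)
            res = rc.predict(fit, ds.features.loc[te], ds.timing.loc[te])
            mse_model = float(np.mean(res.residuals**2))
            mse_zero = float(np.mean((ds.timing.loc[te] - ds.timing.loc[tr].mean()) ** 2))
            assert mse_model < mse_zero


class TestPredict:
    def test_perfect_predictions_have_unit_accuracy(self, rng):
        X = toy_features(rng, n=200, p=2)
        y = pd.Series(3 * X["f0"].to_numpy(), index=X.index)
        d = rc.build_design(X, rc.ExpansionSpec(order=1))
        fit = rc.fit_lasso_cv(d, y, k_folds=5, seed=0, n_lambdas=40,
                              lambda_min_ratio=1e-5)
        res = rc.predict(fit, X, y)
        assert res.rho > 0.999

    def test_identical_rows_get_identical_predictions(self, fitted_model):
        ds, _, fit, tr, _ = fitted_model
        row = ds.features.loc[[tr[0]]]
        dup = pd.concat([row, row.set_axis(["copy"])])
        preds = rc.predict(fit, dup).predicted
        assert preds.iloc[0] == preds.iloc[1]

    def test_accuracy_affine_invariant(self, rng):
        y = rng.standard_normal(100)
        yhat = 0.6 * y + rng.standard_normal(100)
        from scipy.stats import pearsonr
        r1 = pearsonr(y, yhat)[0]
        r2 = pearsonr(y, 5.0 * yhat - 3.0)[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_term_mismatch_rejected(self, fitted_model, rng):
        _, _, fit, _, _ = fitted_model
        X_wrong = toy_features(rng, n=10, p=3)
        with pytest.raises((ValueError, KeyError)):
            rc.predict(fit, X_wrong)

    def test_monotone_pcc_at_target_r2(self, promoter_dataset, fitted_model):
        ds, _, fit, _, te = fitted_model
        res = rc.predict(fit, ds.features.loc[te], ds.timing.loc[te])
        assert res.rho == pytest.approx(np.sqrt(0.5), abs=0.07)


class TestResidualCrossPrediction:
    def test_second_feature_set_explains_residuals(self, rng):
        n = 1200
        xa = rng.standard_normal(n)
        xb = rng.standard_normal(n)
        idx = [f"r{i}" for i in range(n)]
        X_a = pd.DataFrame({"a": xa}, index=idx)
        X_b = pd.DataFrame({"b": xb}, index=idx)
        y = pd.Series(xa + xb + 0.02 * rng.standard_normal(n), index=idx)
        tr, te = rc.split_train_test(idx, 800, 0)
        fit_a = rc.fit_lasso_cv(rc.build_design(X_a, rc.ExpansionSpec(order=1)), y,
                                k_folds=5, seed=0, n_lambdas=40,
                                train_ids=tr, test_ids=te)
        res = ls.residual_cross_prediction(fit_a, X_a.loc[te], X_b, y, seed=0,
                                           k_folds=5, n_lambdas=40)
        assert res.rho > 0.9

    def test_perfect_first_stage_flags_degenerate(self, rng):
        n = 400
        idx = [f"r{i}" for i in range(n)]
        X_a = pd.DataFrame({"a": rng.standard_normal(n)}, index=idx)
        y = pd.Series(2.0 * X_a["a"].to_numpy(), index=idx)
        tr, te = rc.split_train_test(idx, 300, 0)
        fit_a = rc.fit_lasso_cv(rc.build_design(X_a, rc.ExpansionSpec(order=1)), y,
                                k_folds=5, seed=0, n_lambdas=60,
                                lambda_min_ratio=1e-8, train_ids=tr, test_ids=te)
        X_b = pd.DataFrame({"b": rng.standard_normal(n)}, index=idx)
        res = ls.residual_cross_prediction(fit_a, X_a.loc[te], X_b, y,
                                           variance_tol=1e-4, seed=0, k_folds=5)
        assert res.degenerate and res.rho == 0.0

    def test_noise_features_have_no_residual_power(self, rng):
        n = 2000
        idx = [f"r{i}" for i in range(n)]
        X_a = pd.DataFrame({"a": rng.standard_normal(n)}, index=idx)
        y = pd.Series(X_a["a"].to_numpy() + rng.standard_normal(n), index=idx)
        X_b = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("xyz"), index=idx)
        tr, te = rc.split_train_test(idx, 1400, 1)
        fit_a = rc.fit_lasso_cv(rc.build_design(X_a, rc.ExpansionSpec(order=1)), y,
                                k_folds=5, seed=1, n_lambdas=40,
                                train_ids=tr, test_ids=te)
        res = ls.residual_cross_prediction(fit_a, X_a.loc[te], X_b, y, seed=1, k_folds=5)
        assert abs(res.rho) < 0.1 or res.degenerate
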