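"""Ridge regression, VIF selection and nested leave-one-out prediction."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from disconnectome.features import FeatureTable
from disconnectome.prediction import (
    inner_lambda_search,
    loo_predict,
    r_squared,
    ridge_fit,
    ridge_predict,
    standardize_fold,
    vif,
    vif_select,
    vif_sweep,
)


def frame(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestStandardize:
    def test_population_sd_convention(self):
        train = frame([[1.0], [2.0], [3.0]])
        test = frame([[2.0]])
        z_tr, z_te, _ = standardize_fold(train, test)
        np.testing.assert_allclose(
            z_tr.to_numpy().ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )
        assert z_te.iloc[0, 0] == pytest.approx(0.0)

    def test_constant_column_dropped_with_warning(self):
        train = frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            z_tr, z_te, stats = standardize_fold(train, train.iloc[:1])
        assert list(z_tr.columns) == ["f0"]
        assert stats["dropped"] == ["f1"]

    def test_all_constant_is_error(self):
        train = frame([[1.0], [1.0], [1.0]])
        with pytest.raises(ValueError):
            standardize_fold(train, train)


class TestVIF:
    def test_orthogonal_columns(self):
        Z = frame([[1, 1], [1, -1], [-1, 1], [-1, -1]])
        np.testing.assert_allclose(vif(Z).to_numpy(), [1.0, 1.0])

    def test_duplicated_column_infinite(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        v = vif(frame(np.column_stack([x, x])))
        assert np.all(np.isinf(v.to_numpy()))

    def test_known_r2_gives_vif_4(self):
        # x2 = x1 + e with e orthogonal to {1, x1} and var chosen so the
        # auxiliary regression has R^2 = 0.75 exactly
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, -1.0, -1.0, 1.0]) * np.sqrt(5.0 / 12.0)
        Z = frame(np.column_stack([x1, x1 + e]))
        np.testing.assert_allclose(vif(Z).to_numpy(), [4.0, 4.0], atol=1e-9)

    def test_matches_statsmodels_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        X[:, 4] = X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.normal(size=30)
        Z = frame(X)
        mine = vif(Z).to_numpy()
        design = np.column_stack([np.ones(30), X])
        theirs = [variance_inflation_factor(design, j + 1) for j in range(5)]
        np.testing.assert_allclose(mine, theirs, rtol=1e-8)

    def test_single_feature_convention(self):
        assert vif(frame([[1.0], [2.0], [4.0]])).iloc[0] == 1.0


class TestVIFSelect:
    def test_noop_below_threshold(self):
        rng = np.random.default_rng(1)
        Z = frame(rng.normal(size=(40, 4)))
        assert vif_select(Z, 10.0, protected=()) == list(Z.columns)

    def test_duplicate_pair_removes_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        Z = frame(np.column_stack([rng.normal(size=40), x, x]),
                  cols=["a", "dup1", "dup2"])
        kept = vif_select(Z, 10.0, protected=())
        assert kept == ["a", "dup1"]  # reverse column order drops dup2

    def test_greedy_removal_order_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        n = 60
        z1 = rng.normal(size=n)
        z2 = z1 + 0.3 * rng.normal(size=n)
        z3 = z1 + z2 + 0.2 * rng.normal(size=n)
        Z = frame(np.column_stack([z1, z2, z3]), cols=["z1", "z2", "z3"])
        threshold = 4.0
        # independent greedy using statsmodels VIFs, with the same
        # tie-break: among equal maxima drop the latest-added column
        cols = ["z1", "z2", "z3"]
        while True:
            design = np.column_stack([np.ones(n), Z[cols].to_numpy()])
            vs = np.array(
                [variance_inflation_factor(design, j + 1) for j in range(len(cols))]
            )
            if vs.max() <= threshold:
                break
            tied = np.nonzero(np.isclose(vs, vs.max(), rtol=1e-9))[0]
            cols.pop(int(tied[-1]))
        assert vif_select(Z, threshold, protected=()) == cols

    def test_protected_features_survive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        Z = frame(np.column_stack([x, x, x]), cols=["keep1", "keep2", "extra"])
        with pytest.warns(UserWarning, match="unreachable"):
            kept = vif_select(Z, 5.0, protected=("keep1", "keep2"))
        assert kept == ["keep1", "keep2"]


class TestRidge:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(5)
        Z = frame(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        model = ridge_fit(Z, y, 0.0)
        X = Z.to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.beta, beta_ols, atol=1e-10)

    def test_identity_design_closed_form(self):
        n = 6
        y = np.arange(n, dtype=float)
        yc = y - y.mean()
        for lam in (0.0, 0.5, 2.0):
            model = ridge_fit(frame(np.eye(n)), y, lam)
            np.testing.assert_allclose(model.beta, yc / (1 + n * lam), atol=1e-12)

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(6)
        Z = frame(rng.normal(size=(20, 3)))
        y = rng.normal(size=20)
        b_ols = ridge_fit(Z, y, 0.0).beta
        b_big = ridge_fit(Z, y, 1e6).beta
        assert np.linalg.norm(b_big) < 1e-3 * np.linalg.norm(b_ols)

    def test_stationarity_residual(self):
        rng = np.random.default_rng(7)
        Z = frame(rng.normal(size=(25, 6)))
        y = rng.normal(size=25)
        for lam in (0.0, 0.01, 1.0, 100.0):
            m = ridge_fit(Z, y, lam)
            X = Z.to_numpy()
            yc = y - y.mean()
            resid = (X.T @ X + 25 * lam * np.eye(6)) @ m.beta - X.T @ yc
            assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(X.T @ yc)

    def test_singular_at_lambda_zero_raises(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        Z = frame(np.column_stack([x, x]))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            ridge_fit(Z, y, 0.0)


class TestInnerLambdaSearch:
    def test_single_value_grid(self):
        rng = np.random.default_rng(8)
        Z = frame(rng.normal(size=(10, 2)))
        y = rng.normal(size=10)
        assert inner_lambda_search(Z, y, [0.7]) == 0.7

    def test_noiseless_linear_selects_zero(self):
        rng = np.random.default_rng(9)
        Z = frame(rng.normal(size=(15, 3)))
        y = Z.to_numpy() @ np.array([1.0, -2.0, 0.5]) + 3.0
        assert inner_lambda_search(Z, y, [0.0, 1.0, 10.0]) == 0.0

    def test_pure_noise_prefers_large_lambda(self):
        grid = np.logspace(-3, 3, 7)
        median = np.median(grid)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Z = frame(rng.normal(size=(12, 4)))
            y = rng.normal(size=12)
            if inner_lambda_search(Z, y, grid) >= median:
                hits += 1
        assert hits >= 40  # >= 80% of repeats


class TestPaperR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_hand_cases(self):
        assert r_squared([0, 10], [5, 5]) == pytest.approx(0.0)
        assert r_squared([0, 10], [10, 0]) == pytest.approx(-3.0)

    def test_zero_denominator_raises(self):
        # every observation equals the mean of the predictions
        with pytest.raises(ZeroDivisionError):
            r_squared([5.0, 5.0], [4.0, 6.0])

    def test_observed_mean_variant_behind_flag(self):
        y = np.array([0.0, 10.0, 20.0])
        yp = np.array([1.0, 9.0, 21.0])
        std = r_squared(y, yp, convention="observed-mean")
        assert std == pytest.approx(1 - 3 / 200)


def planted_table(n=20, noise=0.0, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    beta = np.linspace(1.0, 2.0, n_features)
    y = X @ beta + noise * rng.normal(size=n)
    cols = ["age", "initial_fma", "cst_asymmetry", "lesion_volume"][:n_features]
    return FeatureTable(
        X=pd.DataFrame(X, columns=cols, index=[f"p{i}" for i in range(n)]),
        y=pd.Series(y, index=[f"p{i}" for i in range(n)], name="recovery"),
    )


class TestLooPredict:
    def test_noiseless_planted_cohort_recovered(self):
        res = loo_predict(planted_table(n=20, noise=0.0))
        assert res.r2 >= 0.99

    def test_permuted_targets_have_no_skill(self):
        ft = planted_table(n=20, noise=0.0, seed=1)
        rng = np.random.default_rng(42)
        r2s = []
        for _ in range(20):
            yp = pd.Series(
                rng.permutation(ft.y.to_numpy()), index=ft.y.index, name="recovery"
            )
            r2s.append(loo_predict(FeatureTable(X=ft.X, y=yp)).r2)
        assert np.mean(r2s) <= 0.1

    def test_protected_features_always_selected(self):
        rng = np.random.default_rng(10)
        n = 25
        x = rng.normal(size=n)
        X = pd.DataFrame(
            {
                "age": rng.normal(size=n),
                "initial_fma": x,
                "cst_asymmetry": x + 0.01 * rng.normal(size=n),
                "lesion_volume": x + 0.01 * rng.normal(size=n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        y = pd.Series(x + rng.normal(size=n), index=X.index)
        res = loo_predict(FeatureTable(X=X, y=y), vif_threshold=5.0)
        for fold_feats in res.fold_features:
            assert "age" in fold_feats
            assert "initial_fma" in fold_feats
            assert "cst_asymmetry" in fold_feats

    def test_no_leakage_from_held_out_row(self):
        """Perturbing the held-out row leaves that fold's internals unchanged."""
        ft = planted_table(n=12, noise=1.0, seed=11)
        res1 = loo_predict(ft, vif_threshold=50.0)
        X2 = ft.X.copy()
        X2.iloc[0] = X2.iloc[0] + 100.0  # only patient 0's features change
        res2 = loo_predict(FeatureTable(X=X2, y=ft.y), vif_threshold=50.0)
        assert res1.fold_features[0] == res2.fold_features[0]
        assert res1.fold_lambda[0] == res2.fold_lambda[0]
        np.testing.assert_allclose(
            list(res1.fold_weights[0].values()), list(res2.fold_weights[0].values())
        )
        # predictions for the other folds DO change (row 0 is in their training)
        assert res1.y_pred[0] != pytest.approx(res2.y_pred[0])


class TestVifSweep:
    def test_determinism_and_saturation(self):
        ft = planted_table(n=15, noise=0.5, seed=12)
        curve = vif_sweep(ft, thresholds=[50, 50], grid=[0.1, 1.0], protected=())
        assert curve.loc[0, "r2"] == curve.loc[1, "r2"]
        res_unselected = loo_predict(ft, vif_threshold=None, grid=[0.1, 1.0])
        big = vif_sweep(ft, thresholds=[10_000], grid=[0.1, 1.0], protected=())
        assert big.loc[0, "r2"] == pytest.approx(res_unselected.r2)

    def test_redundancy_removal_helps_on_collinear_cohort(
        self, small_cohort, small_measures
    ):
        """The connectivity battery is heavily collinear; on the seeded
        synthetic cohort some VIF threshold beats no selection at all."""
        from disconnectome.features import assemble_feature_set

        ft = assemble_feature_set(4, small_cohort, measures=small_measures)
        grid = tuple(np.logspace(-3, 3, 7))
        base = loo_predict(ft, vif_threshold=None, grid=grid).r2
        curve = vif_sweep(ft, thresholds=[5, 23, 100], grid=grid)
        assert curve["r2"].max() >= base
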