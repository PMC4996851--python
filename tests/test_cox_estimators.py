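"""Cox estimation strategies: likelihood oracles, solver equivalences,
selection behavior, cross-validation and fold construction."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from coxbench import (
    BEConfig,
    PenaltyConfig,
    SurvivalOutcome,
    cox_partial_loglik,
    cv_partial_loglik,
    fit_backward_elimination,
    fit_cox_full,
    fit_coxnet,
    fit_method,
    kmeans_balanced_folds,
    lambda_path,
    wald_pvalues,
)
from conftest import simulate_cox_dataset


def brute_force_partial_loglik(beta, X, time, status):
    """Direct enumeration of the Breslow partial likelihood product."""
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    ll = 0.0
    for i in np.flatnonzero(status):
        risk = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


class TestPartialLoglik:
    def test_closed_form_at_zero(self, four_obs):
        """At beta = 0 the log-likelihood is -sum(log risk-set sizes)."""
        x, out = four_obs
        expected = -(np.log(4) + np.log(3) + np.log(2) + np.log(1))
        np.testing.assert_allclose(cox_partial_loglik([0.0], x, out), expected, rtol=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            n = 12
            X = rng.standard_normal((n, 3))
            time = rng.exponential(1.0, n)
            status = rng.integers(0, 2, n)
            status[0] = 1
            out = SurvivalOutcome(time, status)
            beta = rng.normal(0, 0.5, 3)
            np.testing.assert_allclose(
                cox_partial_loglik(beta, X, out),
                brute_force_partial_loglik(beta, X, time, status),
                rtol=1e-10,
            )

    def test_no_events_rejected(self):
        out = SurvivalOutcome([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="without events"):
            cox_partial_loglik([0.0], np.ones((2, 1)), out)


class TestFullModel:
    def test_one_dimensional_grid_oracle(self, four_obs):
        """Newton solution equals the scalar maximizer of the Breslow
        partial likelihood found by bounded scalar optimization."""
        x, out = four_obs
        res = minimize_scalar(
            lambda b: -brute_force_partial_loglik([b], x, out.time, out.status),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        fit = fit_cox_full(x, out)
        assert abs(fit.beta_hat[0] - res.x) < 1e-4

    def test_matches_lifelines(self, cox_dataset_200x10):
        import pandas as pd
        from lifelines import CoxPHFitter

        V, out = cox_dataset_200x10
        fit = fit_cox_full(V, out)
        assert fit.converged
        df = pd.DataFrame(V, columns=[f"x{j}" for j in range(10)])
        df["T"], df["E"] = out.time, out.status
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", fit_options={"precision": 1e-9})
        np.testing.assert_allclose(fit.beta_hat, cph.params_.to_numpy(), atol=1e-5)

    def test_parameter_recovery_high_epv(self):
        beta = np.array([0.5, -0.4, 0.3, 0.0])
        V, out = simulate_cox_dataset(2000, 4, beta, seed=55, censor_quantile=0.2)
        assert out.n_events >= 150  # EPV ~ 50+
        fit = fit_cox_full(V, out)
        assert np.mean(np.abs(fit.beta_hat - beta)) < 0.05

    def test_zero_variance_column_rejected(self, four_obs):
        x, out = four_obs
        X = np.hstack([x, np.ones((4, 1))])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_cox_full(X, out)

    def test_duplicated_column_flagged_or_rejected(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        X = np.hstack([V[:, :3], V[:, [0]]])
        try:
            fit = fit_cox_full(X, out)
            assert not fit.converged
        except (ValueError, np.linalg.LinAlgError):
            pass


class TestWaldPvalues:
    def test_null_pvalues_roughly_uniform(self):
        """Under a zero-coefficient truth the Wald p-values behave like
        Uniform(0,1): a KS test on 300 of them is not rejected at 1%."""
        from scipy import stats

        pvals = []
        for rep in range(100):
            V, out = simulate_cox_dataset(
                200, 3, np.zeros(3), seed=1000 + rep, censor_quantile=0.6
            )
            fit = fit_cox_full(V, out)
            pvals.extend(wald_pvalues(fit, V, out))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_predictor_has_smallest_pvalue(self):
        V, out = simulate_cox_dataset(400, 4, [1.0, 0.0, 0.0, 0.0], seed=77)
        fit = fit_cox_full(V, out)
        p = wald_pvalues(fit, V, out)
        assert np.argmin(p) == 0

    def test_standard_errors_match_lifelines(self, cox_dataset_200x10):
        import pandas as pd
        from lifelines import CoxPHFitter
        from scipy.stats import norm

        V, out = cox_dataset_200x10
        fit = fit_cox_full(V, out)
        p = wald_pvalues(fit, V, out)
        df = pd.DataFrame(V, columns=[f"x{j}" for j in range(10)])
        df["T"], df["E"] = out.time, out.status
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", fit_options={"precision": 1e-9})
        se_ll = cph.standard_errors_.to_numpy()
        p_ll = 2 * norm.sf(np.abs(cph.params_.to_numpy() / se_ll))
        np.testing.assert_allclose(p, p_ll, atol=1e-4)


class TestBackwardElimination:
    def test_equals_full_model_when_everything_significant(self):
        V, out = simulate_cox_dataset(800, 3, [0.8, -0.8, 0.6], seed=3, censor_quantile=0.4)
        full = fit_cox_full(V, out)
        assert np.nanmax(wald_pvalues(full, V, out)) <= 0.05  # precondition
        be = fit_backward_elimination(V, out, BEConfig(0.05))
        assert be.selected.all()
        np.testing.assert_allclose(be.beta_hat, full.beta_hat, atol=1e-10)

    def test_scripted_trace_oracle(self, cox_dataset_200x10):
        """The BE loop reproduces an explicit drop-the-worst trace built
        from repeated full fits and Wald p-values."""
        V, out = cox_dataset_200x10
        alpha = 0.999
        selected = np.ones(10, bool)
        while selected.any():
            sub = fit_cox_full(V[:, selected], out)
            p = wald_pvalues(sub, V[:, selected], out)
            worst = int(np.nanargmax(p))
            if p[worst] <= alpha:
                break
            selected[np.flatnonzero(selected)[worst]] = False
        be = fit_backward_elimination(V, out, BEConfig(alpha))
        np.testing.assert_array_equal(be.selected, selected)

    def test_pure_noise_low_epv_often_selects_nothing(self):
        """With noise predictors and few events, BE 0.05 frequently ends
        empty (and never less often than BE 0.5 ends empty)."""
        none_05 = none_50 = 0
        for rep in range(25):
            V, out = simulate_cox_dataset(
                150, 5, np.zeros(5), seed=400 + rep, censor_quantile=0.1
            )
            none_05 += not fit_backward_elimination(V, out, BEConfig(0.05)).selected.any()
            none_50 += not fit_backward_elimination(V, out, BEConfig(0.5)).selected.any()
        assert none_05 >= 10
        assert none_05 >= none_50

    def test_empty_selection_is_constant_prediction(self):
        V, out = simulate_cox_dataset(150, 5, np.zeros(5), seed=404, censor_quantile=0.1)
        be = fit_backward_elimination(V, out, BEConfig(1e-6))
        assert not be.selected.any()
        assert be.constant_prediction

    def test_likelihood_ratio_variant_runs(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        be = fit_backward_elimination(V, out, BEConfig(0.05, test="likelihood_ratio"))
        assert be.beta_hat.shape == (10,)


class TestLambdaPath:
    def test_grid_shape_and_monotonicity(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        grid = lambda_path(V, out, 1.0)
        assert grid.size == 100
        assert np.all(np.diff(grid) < 0)
        np.testing.assert_allclose(grid[-1] / grid[0], 1e-4, rtol=1e-9)

    def test_halving_ratio_extends_downward_keeping_upper_entries(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        g1 = lambda_path(V, out, 0.5, lambda_min_ratio=1e-4)
        g2 = lambda_path(V, out, 0.5, lambda_min_ratio=5e-5)
        assert g2.size > g1.size
        np.testing.assert_allclose(g2[: g1.size], g1, rtol=1e-12)

    def test_ridge_grid_inflated_1000x(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        np.testing.assert_allclose(
            lambda_path(V, out, 0.0)[0], 1000.0 * lambda_path(V, out, 1.0)[0], rtol=1e-9
        )


class TestCoxnet:
    def test_unpenalized_matches_full_model(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        full = fit_cox_full(V, out)
        for alpha in (1.0, 0.0):
            b = fit_coxnet(V, out, alpha, 0.0)
            np.testing.assert_allclose(b, full.beta_hat, atol=1e-5)

    def test_lasso_zero_at_lambda_max(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        lam_max = lambda_path(V, out, 1.0)[0]
        assert np.all(fit_coxnet(V, out, 1.0, lam_max) == 0.0)
        assert np.all(fit_coxnet(V, out, 1.0, 2 * lam_max) == 0.0)

    @pytest.mark.parametrize("alpha", [1.0, 0.5, 0.0])
    def test_two_predictor_solution_matches_objective_grid_search(self, alpha):
        """Penalized solution agrees with a two-stage brute-force search
        over the penalized objective itself."""
        from coxbench._risk import SurvivalOrder, loglik_many
        from conftest import simulate_cox_dataset

        V, out = simulate_cox_dataset(60, 2, [0.6, -0.4], seed=9, censor_quantile=0.5)
        mu, sd = V.mean(0), V.std(0)
        Vs = (V - mu) / sd
        lam = lambda_path(Vs, out, max(alpha, 0.001))[25]
        bhat = fit_coxnet(Vs, out, alpha, lam)  # standardized data: no back-transform

        order = SurvivalOrder(out.time, out.status)
        n = out.n

        def objective_grid(center, half_width, m):
            b1 = np.linspace(center[0] - half_width, center[0] + half_width, m)
            b2 = np.linspace(center[1] - half_width, center[1] + half_width, m)
            B = np.stack(np.meshgrid(b1, b2, indexing="ij"), axis=-1).reshape(-1, 2)
            ll = loglik_many(order, (Vs @ B.T)[order.order])
            pen = lam * (alpha * np.abs(B).sum(1) + 0.5 * (1 - alpha) * (B**2).sum(1))
            obj = 2.0 / n * ll - pen
            return B[np.argmax(obj)]

        best = objective_grid(np.zeros(2), 2.0, 161)  # step 0.025
        best = objective_grid(best, 0.05, 201)  # step 5e-4
        np.testing.assert_allclose(bhat, best, atol=1e-3)

    def test_matches_scikit_survival_after_scale_mapping(self, cox_dataset_200x10):
        """Independent solver cross-check: scikit-survival's coxnet scales
        the log-likelihood by 1/n (ours by 2/n), so its penalty at
        lambda/2 corresponds to ours at lambda."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        V, out = cox_dataset_200x10
        Vs = (V - V.mean(0)) / V.std(0)
        y = np.array(
            [(bool(e), t) for e, t in zip(out.status, out.time)],
            dtype=[("e", bool), ("t", float)],
        )
        for l1r in (1.0, 0.5):
            lam = lambda_path(Vs, out, l1r)[30]
            cn = CoxnetSurvivalAnalysis(
                l1_ratio=l1r, alphas=[lam / 2], tol=1e-12, normalize=False
            )
            cn.fit(Vs, y)
            ours = fit_coxnet(Vs, out, l1r, lam)
            np.testing.assert_allclose(ours, cn.coef_.ravel(), atol=5e-5)

    def test_ridge_shrinkage_monotone_in_lambda(self, cox_dataset_200x10):
        from coxbench.cox_estimators import _fit_path

        V, out = cox_dataset_200x10
        lambdas = lambda_path(V, out, 0.0)[::10]
        B, _ = _fit_path(V, out.time, out.status, 0.0, lambdas)
        norms = np.linalg.norm(B, axis=1)
        assert np.all(np.diff(norms) >= -1e-10)  # lambda decreasing -> norm grows

    def test_cd_surrogate_objective_monotone_over_sweeps(self):
        """Each coordinate-descent sweep decreases (never increases) the
        penalized weighted quadratic surrogate."""
        from coxbench._risk import cd_sweep

        rng = np.random.default_rng(14)
        n, p = 80, 6
        X = rng.standard_normal((n, p))
        w = rng.random(n) + 0.1
        z = rng.standard_normal(n)
        lam_l1, lam_l2 = 0.05, 0.03
        beta = np.zeros(p)
        eta = X @ beta
        xtx = 2.0 * (w[:, None] * X**2).sum(0) / n

        def surrogate():
            pen = lam_l1 * np.abs(beta).sum() + 0.5 * lam_l2 * (beta**2).sum()
            return (w * (z - eta) ** 2).sum() / n + pen

        vals = [surrogate()]
        for _ in range(15):
            cd_sweep(X, w, z, eta, beta, lam_l1, lam_l2, xtx)
            eta = X @ beta
            vals.append(surrogate())
        assert np.all(np.diff(vals) <= 1e-12)


class TestCrossValidation:
    def test_closed_form_at_zero_coefficients(self, cox_dataset_200x10):
        """Above every training fold's lambda_max (lasso), all fold fits are
        exactly the zero vector, so the CV criterion reduces to
        log risk-set-size sums computable directly."""
        from coxbench.cox_estimators import _make_random_folds

        V, out = cox_dataset_200x10
        folds = _make_random_folds(out.n, 10, out.status == 1, seed=2)
        lam_max = lambda_path(V, out, 1.0)[0]
        lambdas = np.array([8.0 * lam_max, 4.0 * lam_max])
        res = cv_partial_loglik(V, out, 1.0, lambdas, folds=folds)
        expected = 0.0
        for f in range(10):
            tr = folds != f
            l_all = cox_partial_loglik(np.zeros(10), V, out)
            l_tr = cox_partial_loglik(
                np.zeros(10), V[tr], SurvivalOutcome(out.time[tr], out.status[tr])
            )
            expected += l_all - l_tr
        np.testing.assert_allclose(res.values[0, 0], expected, rtol=1e-10)

    def test_curve_matches_independent_recomputation(self, cox_dataset_200x10):
        """CV values recomputed from separately refit fold models agree."""
        from coxbench.cox_estimators import _fit_path, _make_random_folds
        from coxbench._risk import SurvivalOrder, loglik_many

        V, out = cox_dataset_200x10
        folds = _make_random_folds(out.n, 5, out.status == 1, seed=8)
        lambdas = lambda_path(V, out, 0.5)[::5]
        res = cv_partial_loglik(V, out, 0.5, lambdas, folds=folds)
        order_all = SurvivalOrder(out.time, out.status)
        recomputed = np.zeros(lambdas.size)
        for f in range(5):
            tr = folds != f
            B, _ = _fit_path(
                V[tr], out.time[tr], out.status[tr], 0.5, lambdas,
                tol=1e-6, max_outer=3, max_sweeps=2,
            )
            order_tr = SurvivalOrder(out.time[tr], out.status[tr])
            recomputed += loglik_many(order_all, (V @ B.T)[order_all.order])
            recomputed -= loglik_many(order_tr, (V[tr] @ B.T)[order_tr.order])
        np.testing.assert_allclose(res.values[0], recomputed, rtol=1e-10)
        assert res.values[0, res.chosen_lambda_index] == res.values.max()

    @pytest.mark.parametrize("k", [5, 10])
    def test_fold_counts_both_supported(self, cox_dataset_200x10, k):
        V, out = cox_dataset_200x10
        res = cv_partial_loglik(V, out, 1.0, k=k, fold_seed=1)
        assert res.values.shape == (1, 100)
        assert np.all(np.isfinite(res.values))


class TestKMeansFolds:
    def test_balance_and_determinism(self, cox_dataset_200x10):
        V, _ = cox_dataset_200x10
        folds = kmeans_balanced_folds(V, k=10, seed=5)
        again = kmeans_balanced_folds(V, k=10, seed=5)
        np.testing.assert_array_equal(folds, again)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 10

    def test_within_cluster_balance(self, cox_dataset_200x10):
        from sklearn.cluster import KMeans

        V, _ = cox_dataset_200x10
        folds = kmeans_balanced_folds(V, k=5, seed=3)
        # regardless of the internal clustering, fold sizes must be near-equal
        sizes = np.bincount(folds, minlength=5)
        assert sizes.max() - sizes.min() <= 5


class TestFitMethodDispatch:
    def test_unknown_method_rejected(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        with pytest.raises(ValueError, match="unknown method"):
            fit_method("stepwise", V, out)

    def test_elastic_endpoints_equal_lasso_and_ridge(self, cox_dataset_200x10):
        """An elastic net restricted to a single endpoint of the mixing grid
        reproduces the corresponding pure penalty exactly."""
        V, out = cox_dataset_200x10
        for endpoint, pure in ((1.0, "lasso"), (0.0, "ridge")):
            cfg = PenaltyConfig(fold_seed=6, alpha_grid=np.array([endpoint]))
            el = fit_method("elastic", V, out, penalty_cfg=cfg)
            ref = fit_method(pure, V, out, penalty_cfg=PenaltyConfig(fold_seed=6))
            assert el.tuning.chosen_alpha == endpoint
            assert np.max(np.abs(el.beta_hat - ref.beta_hat)) < 1e-8

    def test_be_ridge_with_empty_selection_is_constant(self):
        V, out = simulate_cox_dataset(150, 5, np.zeros(5), seed=404, censor_quantile=0.1)
        fit = fit_method("be_ridge", V, out, be_cfg=BEConfig(1e-6))
        assert fit.constant_prediction
        assert np.all(fit.beta_hat == 0)

    def test_be_ridge_shrinks_selected_subset_only(self, cox_dataset_200x10):
        V, out = cox_dataset_200x10
        fit = fit_method(
            "be_ridge", V, out,
            penalty_cfg=PenaltyConfig(fold_seed=2), be_cfg=BEConfig(0.05),
        )
        assert np.all(fit.beta_hat[~fit.selected] == 0)
        assert fit.selected.sum() >= 1
        be_only = fit_backward_elimination(V, out, BEConfig(0.05))
        sel = fit.selected
        # ridge shrinks the BE coefficients toward zero in aggregate
        assert np.linalg.norm(fit.beta_hat[sel]) <= np.linalg.norm(be_only.beta_hat[sel]) + 1e-9
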