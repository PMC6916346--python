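import numpy as np
import pandas as pd
import pytest

import mixedintervals as mi
from mixedintervals.reml import RemlError, restricted_loglik, restricted_loglik_grad

from conftest import anova_one_way, make_one_way


def _design(data):
    return mi.build_design(data, mi.ModelSpec(response="y", random_terms=["run"]))


class TestRestrictedLoglik:
    def test_translation_invariance(self, one_way_data):
        design = _design(one_way_data)
        y = one_way_data["y"].to_numpy()
        theta = np.array([0.4, 0.9])
        ll1 = restricted_loglik(theta, design, y)
        ll2 = restricted_loglik(theta, design, y + 123.456)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_reorder_invariance(self, one_way_data):
        y = one_way_data["y"].to_numpy()
        theta = np.array([0.4, 0.9])
        d1 = _design(one_way_data)
        perm = np.random.default_rng(2).permutation(len(y))
        d2 = _design(one_way_data.iloc[perm].reset_index(drop=True))
        assert restricted_loglik(theta, d1, y) == pytest.approx(
            restricted_loglik(theta, d2, y[perm]), rel=1e-12
        )

    def test_all_mass_on_residual_matches_single_variance_model(self, one_way_data):
        # with theta_run = 0 the model is iid N(mu, s2): the REML loglik has
        # the closed form of the one-variance model on the OLS residuals
        design = _design(one_way_data)
        y = one_way_data["y"].to_numpy()
        s2 = 1.37
        n, p = len(y), 1
        rss = float(np.sum((y - y.mean()) ** 2))
        # log|V| = n log s2, log|X'V^-1 X| = log(n/s2), y'Py = rss/s2
        closed = -0.5 * (
            (n - p) * np.log(2 * np.pi) + n * np.log(s2) + np.log(n / s2) + rss / s2
        )
        assert restricted_loglik(np.array([0.0, s2]), design, y) == pytest.approx(
            closed, rel=1e-10
        )

    def test_gradient_zero_at_anova_estimates(self, one_way_data):
        design = _design(one_way_data)
        y = one_way_data["y"].to_numpy()
        *_, sa2, se2, _ = anova_one_way(y, 6, 3)
        grad = restricted_loglik_grad(np.array([sa2, se2]), design, y)
        assert np.linalg.norm(grad) < 1e-8

    def test_analytic_gradient_matches_finite_differences(self, nested_fit):
        design, y = nested_fit.design, nested_fit.y
        theta = np.array([4.0, 2.5, 1.5])
        g = restricted_loglik_grad(theta, design, y)
        eps = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            fd = (
                restricted_loglik(theta + e, design, y)
                - restricted_loglik(theta - e, design, y)
            ) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_errors(self, one_way_data):
        design = _design(one_way_data)
        y = one_way_data["y"].to_numpy()
        with pytest.raises(RemlError):
            restricted_loglik(np.array([0.0, 0.0]), design, y)
        with pytest.raises(RemlError):
            restricted_loglik(np.array([1.0]), design, y)
        with pytest.raises(RemlError):
            restricted_loglik(np.array([1.0, -0.5]), design, y)


class TestFitReml:
    def test_matches_anova_oracle(self, one_way_fit, one_way_data):
        y = one_way_data["y"].to_numpy()
        *_, sa2, se2, grand = anova_one_way(y, 6, 3)
        assert one_way_fit.theta_hat[0] == pytest.approx(sa2, rel=1e-8)
        assert one_way_fit.theta_hat[1] == pytest.approx(se2, rel=1e-8)
        assert one_way_fit.beta_hat[0] == pytest.approx(grand, rel=1e-10)

    def test_scale_equivariance(self, one_way_data):
        design = _design(one_way_data)
        y = one_way_data["y"].to_numpy()
        f1 = mi.fit_reml(design, y)
        f2 = mi.fit_reml(design, 3.0 * y)
        np.testing.assert_allclose(f2.theta_hat, 9.0 * f1.theta_hat, rtol=1e-6)

    def test_equal_group_means_hit_boundary(self):
        data = make_one_way(A=5, n=4, sigma_a2=0.0, seed=0)
        # force exactly equal group means
        y = data["y"].to_numpy().reshape(5, 4)
        y = y - y.mean(axis=1, keepdims=True)
        data["y"] = y.ravel()
        design = _design(data)
        fit = mi.fit_reml(design, data["y"].to_numpy())
        assert fit.theta_hat[0] == 0.0
        assert fit.boundary[0]
        assert "boundary" in fit.vartheta_flags

    def test_beta_equals_gls_recomputed_from_scratch(self, nested_fit):
        theta = nested_fit.theta_hat
        design = nested_fit.design
        V = sum(
            t * (b.matrix @ b.matrix.T)
            for t, b in zip(theta, design.Z_blocks)
        ) + theta[-1] * np.eye(design.n)
        Vinv = np.linalg.inv(V)
        X = design.X
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ nested_fit.y)
        np.testing.assert_allclose(nested_fit.beta_hat, beta, rtol=1e-8)

    def test_c21_block_identity(self, nested_fit):
        # C21 = -G Z' V^-1 X C11 at theta-hat
        theta = nested_fit.theta_hat
        design = nested_fit.design
        Z = design.Z_full()
        g_diag = np.concatenate(
            [np.full(b.matrix.shape[1], t) for t, b in zip(theta, design.Z_blocks)]
        )
        V = (Z * g_diag[None, :]) @ Z.T + theta[-1] * np.eye(design.n)
        C21 = -(g_diag[:, None] * (Z.T @ np.linalg.solve(V, design.X))) @ nested_fit.C11
        np.testing.assert_allclose(nested_fit.C21, C21, rtol=1e-7, atol=1e-12)

    def test_nested_parameter_recovery_within_3_se(self, nested_fit):
        # sampling SD of the ANOVA estimators at the true components
        # (balanced nested: mean squares are independent scaled chi-squares)
        A = B = n = 5
        sa2, sb2, se2 = 5.0, 3.0, 2.0
        ems_a = se2 + n * sb2 + n * B * sa2
        ems_b = se2 + n * sb2
        v_a = (2 / (n * B) ** 2) * (ems_a**2 / (A - 1) + ems_b**2 / (A * (B - 1)))
        v_b = (2 / n**2) * (ems_b**2 / (A * (B - 1)) + se2**2 / (A * B * (n - 1)))
        v_e = 2 * se2**2 / (A * B * (n - 1))
        sd = np.sqrt([v_a, v_b, v_e])
        assert np.all(np.abs(nested_fit.theta_hat - [sa2, sb2, se2]) <= 3 * sd)

    def test_mean_recovery_across_simulations(self):
        # unbiasedness of REML across 200 balanced one-way datasets
        truth = np.array([2.0, 8.0])
        sc = mi.Scenario("one_random", tuple(truth), (10, 5), n_sims=200, seed=9)
        spec = sc.model_spec()
        thetas = []
        for j in range(200):
            data = mi.generate_dataset(sc, j)
            design = mi.build_design(data, spec)
            fit = mi.fit_reml(design, data["y"].to_numpy(), compute_vartheta=False)
            thetas.append(fit.theta_hat)
        mean = np.mean(thetas, axis=0)
        mc_se = np.std(thetas, axis=0, ddof=1) / np.sqrt(200)
        assert np.all(np.abs(mean - truth) <= 3 * mc_se)


class TestObservedInformation:
    def test_matches_analytic_one_way_information(self, one_way_fit):
        sa2, se2 = one_way_fit.theta_hat
        A, n = 6, 3
        ems_a = se2 + n * sa2
        v_ee = 2 * se2**2 / (A * (n - 1))
        v_aa = (2 / n**2) * (ems_a**2 / (A - 1) + se2**2 / (A * (n - 1)))
        v_ae = -2 * se2**2 / (n * A * (n - 1))
        analytic = np.array([[v_aa, v_ae], [v_ae, v_ee]])
        np.testing.assert_allclose(one_way_fit.vartheta, analytic, rtol=1e-3)

    def test_duplicating_data_shrinks_all_variances(self, one_way_data):
        design1 = _design(one_way_data)
        y = one_way_data["y"].to_numpy()
        fit1 = mi.fit_reml(design1, y)
        doubled = pd.concat([one_way_data, one_way_data], ignore_index=True)
        design2 = _design(doubled)
        fit2 = mi.fit_reml(design2, doubled["y"].to_numpy())
        assert np.all(np.diag(fit2.vartheta) < np.diag(fit1.vartheta))
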