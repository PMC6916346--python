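import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mixedintervals as mi
from mixedintervals.ems import balanced_one_way, decomposition_for_fit

from conftest import anova_one_way


class TestUnivariate:
    def test_ci_known_quantile(self):
        res = mi.univariate_ci(0.0, 1.0, 5, alpha=0.05)
        assert res.upper == pytest.approx(2.7764451 / np.sqrt(5), rel=1e-6)

    def test_pi_known_quantile(self):
        res = mi.univariate_pi(0.0, 1.0, 5, psi=0.05)
        assert res.upper == pytest.approx(2.7764451 * np.sqrt(1.2), rel=1e-6)

    def test_ti_known_quantiles(self):
        res = mi.univariate_ti(0.0, 1.0, 10, psi=0.05, alpha=0.2)
        expected = stats.norm.ppf(0.975) * np.sqrt(1.1 * 9 / stats.chi2.ppf(0.2, 9))
        assert res.upper == pytest.approx(expected, rel=1e-9)

    def test_degenerate_sd_zero(self):
        res = mi.univariate_ci(3.0, 0.0, 5)
        assert res.lower == res.upper == 3.0

    @given(n=st.integers(2, 500))
    @settings(deadline=None, max_examples=30)
    def test_pi_always_wider_than_ci(self, n):
        ci = mi.univariate_ci(0.0, 1.0, n)
        pi = mi.univariate_pi(0.0, 1.0, n)
        assert pi.width > ci.width

    def test_large_n_limits(self):
        z = stats.norm.ppf(0.975)
        assert mi.univariate_ci(0.0, 1.0, 10**6).upper == pytest.approx(0.0, abs=0.01)
        assert mi.univariate_pi(0.0, 1.0, 10**6).upper == pytest.approx(z, rel=1e-2)
        assert mi.univariate_ti(0.0, 1.0, 10**6, alpha=0.2).upper == pytest.approx(
            z, rel=1e-2
        )

    def test_ti_with_50pct_confidence_close_to_pi_large_n(self):
        n = 2000
        pi = mi.univariate_pi(0.0, 1.0, n)
        ti = mi.univariate_ti(0.0, 1.0, n, alpha=0.5)
        assert ti.upper == pytest.approx(pi.upper, rel=5e-3)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            mi.univariate_ci(0.0, 1.0, 1)


class TestTotalVariance:
    def test_published_assay_df(self):
        df = mi.satterthwaite_df(0.000681 + 0.001253, 5.995e-7)
        assert df == pytest.approx(12.484, rel=2e-3)

    def test_published_orthopedic_df(self):
        df = mi.satterthwaite_df(7.349 + 18.074, 18.372)
        assert df == pytest.approx(70.36, rel=1e-3)

    def test_single_component_reduces_to_classical_satterthwaite(self):
        # a lone chi-square variance with r df has Var = 2 v^2 / r
        v, r = 3.7, 11.0
        assert mi.satterthwaite_df(v, 2 * v**2 / r) == pytest.approx(r, rel=1e-12)

    def test_df_identity_on_fit(self, one_way_fit):
        tv = mi.total_variance(one_way_fit)
        assert tv.sigmaT2 == pytest.approx(float(one_way_fit.theta_hat.sum()), rel=1e-12)
        assert tv.df_r == pytest.approx(2 * tv.sigmaT2**2 / tv.var_sigmaT2, rel=1e-12)


class TestFixedEffectDf:
    def test_balanced_one_way_intercept_df_is_A_minus_1(self, one_way_fit):
        df = mi.satterthwaite_df_fixed(one_way_fit, "(Intercept)")
        assert df == pytest.approx(5.0, rel=1e-4)

    def test_balanced_nested_intercept_df_is_A_minus_1(self, nested_fit):
        df = mi.satterthwaite_df_fixed(nested_fit, "(Intercept)")
        assert df == pytest.approx(4.0, rel=1e-3)

    def test_df_invariant_to_response_scaling(self, one_way_data):
        spec = mi.ModelSpec(response="y", random_terms=["run"])
        design = mi.build_design(one_way_data, spec)
        y = one_way_data["y"].to_numpy()
        f1 = mi.fit_reml(design, y)
        f2 = mi.fit_reml(design, 5.0 * y)
        assert mi.satterthwaite_df_fixed(f1, "(Intercept)") == pytest.approx(
            mi.satterthwaite_df_fixed(f2, "(Intercept)"), rel=1e-5
        )


class TestMixedModelIntervals:
    def test_ci_nesting_in_alpha(self, one_way_fit):
        narrow = mi.confidence_interval(one_way_fit, "(Intercept)", alpha=0.10)
        wide = mi.confidence_interval(one_way_fit, "(Intercept)", alpha=0.05)
        assert wide.lower < narrow.lower < narrow.upper < wide.upper

    def test_pi_variance_exceeds_ci_variance(self, one_way_fit):
        ci = mi.confidence_interval(one_way_fit, "(Intercept)")
        pi = mi.prediction_interval(one_way_fit, "(Intercept)")
        assert pi.variance_used > ci.variance_used

    def test_ti_width_decreases_with_alpha_and_exceeds_z_pi(self, one_way_fit):
        widths = [
            mi.tolerance_interval(one_way_fit, "(Intercept)", alpha=a).width
            for a in (0.05, 0.10, 0.20, 0.40)
        ]
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))
        tv = mi.total_variance(one_way_fit)
        z_pi_width = 2 * stats.norm.ppf(0.975) * np.sqrt(
            mi.confidence_interval(one_way_fit, "(Intercept)").variance_used
            + tv.sigmaT2
        )
        assert all(w > z_pi_width for w in widths)

    def test_conditional_with_zero_gamma_part_reduces_to_ci(self, one_way_fit):
        p, g = one_way_fit.design.p, one_way_fit.gamma_hat.size
        l_nu = np.zeros(p + g)
        l_nu[0] = 1.0
        cond = mi.conditional_interval(one_way_fit, l_nu)
        ci = mi.confidence_interval(one_way_fit, "(Intercept)")
        assert cond.lower == pytest.approx(ci.lower, rel=1e-10)
        assert cond.upper == pytest.approx(ci.upper, rel=1e-10)

    def test_conditional_center_matches_mme_oracle(self, one_way_fit):
        # nu-hat from the mixed-model equations solved from scratch
        design = one_way_fit.design
        theta = one_way_fit.theta_hat
        X, Z = design.X, design.Z_full()
        rinv = 1.0 / theta[-1]
        G_inv = np.eye(Z.shape[1]) / theta[0]
        lhs = np.block(
            [
                [X.T @ X * rinv, X.T @ Z * rinv],
                [Z.T @ X * rinv, Z.T @ Z * rinv + G_inv],
            ]
        )
        rhs = np.concatenate([X.T @ one_way_fit.y, Z.T @ one_way_fit.y]) * rinv
        nu = np.linalg.solve(lhs, rhs)
        l_nu = np.zeros(1 + Z.shape[1])
        l_nu[0] = 1.0
        l_nu[1] = 1.0  # intercept + first run effect
        cond = mi.conditional_interval(one_way_fit, l_nu)
        assert cond.estimate == pytest.approx(float(nu[0] + nu[1]), rel=1e-8)

    def test_pi_and_ti_converge_to_z_quantiles(self):
        # growing balanced one-way designs: bounds approach lbeta +/- z sigma_T
        sa2, se2 = 2.0, 8.0
        sigma_t = np.sqrt(sa2 + se2)
        z = stats.norm.ppf(0.975)
        gaps = []
        for A in (10, 40, 100):
            sc = mi.Scenario("one_random", (sa2, se2), (A, 5), n_sims=1, seed=21)
            data = mi.generate_dataset(sc, 0)
            design = mi.build_design(data, sc.model_spec())
            fit = mi.fit_reml(design, data["y"].to_numpy())
            pi = mi.prediction_interval(fit, "(Intercept)")
            ti = mi.tolerance_interval(fit, "(Intercept)", alpha=0.10)
            target = pi.estimate + z * np.sqrt(fit.theta_hat.sum())
            gaps.append((abs(pi.upper - target), abs(ti.upper - target)))
        # half-width excess over the limiting z-based form shrinks with A
        assert gaps[0][0] > gaps[-1][0]
        assert gaps[0][1] > gaps[-1][1]
        assert gaps[-1][0] < 0.05 * sigma_t
        assert gaps[-1][1] < 0.10 * sigma_t

    def test_paradox_detection_reports_condition(self):
        sc = mi.Scenario("nested", (5.0, 3.0, 2.0), (2, 2, 2), n_sims=1, seed=3)
        data = mi.generate_dataset(sc, 0)
        design = mi.build_design(data, sc.model_spec())
        fit = mi.fit_reml(design, data["y"].to_numpy())
        ci = mi.confidence_interval(fit, "(Intercept)")
        pi = mi.prediction_interval(fit, "(Intercept)")
        assert mi.detect_paradox(ci, pi) == (ci.width > pi.width)


class TestAppendixEquivalence:
    def test_effective_sample_size_form_and_classical_df(self):
        """On balanced one-way fits the mixed-model PI variance equals the
        effective-sample-size form sigma_T^2 (1 + 1/N_e), and the df from
        the information matrix equals classical Satterthwaite on the
        independent mean squares."""
        A, n = 8, 4
        checked = 0
        for seed in range(75):
            sc = mi.Scenario("one_random", (2.0, 8.0), (A, n), n_sims=1, seed=seed)
            data = mi.generate_dataset(sc, 0)
            design = mi.build_design(data, sc.model_spec())
            fit = mi.fit_reml(design, data["y"].to_numpy())
            if fit.boundary.any():
                continue
            sa2, se2 = fit.theta_hat
            ms_a, ms_e, *_ = anova_one_way(fit.y, A, n)
            sigma_t2 = sa2 + se2
            # variance identity (Eq 21 vs effective-sample-size form)
            ne = A * n * sigma_t2 / (n * sa2 + se2)
            lhs = float(fit.C11[0, 0]) + sigma_t2
            assert lhs == pytest.approx(sigma_t2 * (1 + 1 / ne), rel=1e-6)
            # df identity against mean-square Satterthwaite
            k_a, k_e = 1 / n, 1 - 1 / n
            r_classical = sigma_t2**2 / (
                (k_a * ms_a) ** 2 / (A - 1) + (k_e * ms_e) ** 2 / (A * (n - 1))
            )
            tv = mi.total_variance(fit)
            assert tv.df_r == pytest.approx(r_classical, rel=1e-6)
            checked += 1
            if checked >= 50:
                break
        assert checked >= 50


class TestSummaryMode:
    def test_balanced_assay_ci(self):
        ci = mi.ci_from_summary(0.981, 0.01353, df=5, alpha=0.05)
        assert ci.lower == pytest.approx(0.946, abs=5e-4)
        assert ci.upper == pytest.approx(1.016, abs=5e-4)

    def test_balanced_assay_pi(self):
        pi = mi.pi_from_summary(0.981, 0.01353, 0.001934, 5.995e-7, psi=0.05)
        assert pi.lower == pytest.approx(0.881, abs=1e-3)
        assert pi.upper == pytest.approx(1.081, abs=1e-3)

    def test_balanced_assay_ti(self):
        decomp = balanced_one_way(0.000681, 0.001253, 6, 3, alpha=0.10)
        ti = mi.ti_from_summary(0.981, 0.01353, decomp, psi=0.05)
        assert ti.lower == pytest.approx(0.845, rel=5e-3)
        assert ti.upper == pytest.approx(1.117, rel=5e-3)

    def test_orthopedic_pi(self):
        pi = mi.pi_from_summary(0.114, 1.051, 25.423, 18.372, psi=0.05)
        assert pi.lower == pytest.approx(-10.16, abs=0.01)
        assert pi.upper == pytest.approx(10.39, abs=0.01)

    def test_orthopedic_ti_80pct_confidence(self):
        decomp = balanced_one_way(7.349, 18.074, 23, 4, alpha=0.20, residual_df=66)
        ti = mi.ti_from_summary(0.114, 1.051, decomp, psi=0.05)
        assert ti.lower == pytest.approx(-10.89, rel=1e-2)
        assert ti.upper == pytest.approx(11.1, rel=1e-2)


class TestDecompositionConsistency:
    def test_auto_decomposition_matches_fit_total_variance(self, nested_fit):
        decomp = decomposition_for_fit(nested_fit, alpha=0.2)
        decomp.check_identity(float(nested_fit.theta_hat.sum()))

    def test_ti_rejects_inconsistent_decomposition(self, one_way_fit):
        bad = balanced_one_way(99.0, 1.0, 6, 3)
        with pytest.raises(ValueError, match="decomposition"):
            mi.tolerance_interval(one_way_fit, "(Intercept)", decomp=bad)
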