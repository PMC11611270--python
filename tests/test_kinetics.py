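"""Multi-duration MLE, deviance goodness of fit, selection and robustness."""

import numpy as np
import pytest
from scipy.optimize import brentq

from labelvelo.distributions import mean_new_baseline, mean_new_splicing
from labelvelo.kinetics import (
    _profile_alpha_baseline,
    _profile_alpha_splicing,
    fit_csp_baseline,
    fit_csp_splicing,
    fit_csp_switching,
    robustness_measure,
    select_genes,
)

DURATIONS = np.array([0.25, 0.5, 0.75, 1.0, 2.0, 3.0])


def cells_per_duration(n):
    return np.repeat(DURATIONS, n)


class TestBaseline:
    def test_profile_alpha_closed_form_example(self):
        # l=[1,2], p=1, t=1, gamma=1: alpha = 3 / (2 (1 - e^{-1}))
        alpha = _profile_alpha_baseline(
            1.0, np.array([1.0, 2.0]), np.array([1.0, 1.0]), np.array([1.0, 1.0])
        )
        assert alpha == pytest.approx(3.0 / (2.0 * (1 - np.exp(-1))), rel=1e-12)

    def test_rejects_single_duration(self):
        with pytest.raises(ValueError, match="one-shot"):
            fit_csp_baseline(np.ones(10), np.ones(10), np.ones(10))

    def test_all_zero_gene_flagged(self):
        t = cells_per_duration(5)
        fit = fit_csp_baseline(np.zeros_like(t), np.ones_like(t), t)
        assert fit.params["alpha"] == 0.0
        assert not fit.converged

    def test_recovery_at_reference_conditions(self):
        """Median relative error of gamma under the fixed-rate reference design
        (alpha=1, gamma=0.5, K=6 durations, 500 cells each) is below 10%."""
        rng = np.random.default_rng(100)
        t = cells_per_duration(500)
        errs = []
        for _ in range(20):
            p = rng.uniform(0.5, 2.0, t.size)
            l = rng.poisson(p * mean_new_baseline(1.0, 0.5, t))
            fit = fit_csp_baseline(l, p, t)
            errs.append(abs(fit.params["gamma_t"] - 0.5) / 0.5)
        assert np.median(errs) < 0.10

    def test_profile_identity_at_optimum(self):
        rng = np.random.default_rng(101)
        t = cells_per_duration(100)
        for _ in range(5):
            p = rng.uniform(0.5, 2.0, t.size)
            l = rng.poisson(p * mean_new_baseline(rng.uniform(0.5, 2), rng.uniform(0.1, 1), t))
            fit = fit_csp_baseline(l, p, t)
            expect = _profile_alpha_baseline(fit.params["gamma_t"], l.astype(float), p, t)
            assert fit.params["alpha"] == pytest.approx(expect, rel=1e-6)

    def test_matches_bruteforce_grid(self):
        rng = np.random.default_rng(102)
        t = cells_per_duration(200)
        p = np.ones(t.size)
        l = rng.poisson(p * mean_new_baseline(0.75, 0.25, t))
        fit = fit_csp_baseline(l, p, t)
        g_grid = np.linspace(0.01, 1.0, 300)
        best_ll, best_g = -np.inf, None
        for g in g_grid:
            a = _profile_alpha_baseline(g, l.astype(float), p, t)
            m = np.maximum(p * mean_new_baseline(a, g, t), 1e-12)
            ll = (l * np.log(m) - m).sum()
            if ll > best_ll:
                best_ll, best_g = ll, g
        assert abs(fit.params["gamma_t"] - best_g) <= g_grid[1] - g_grid[0]

    def test_steady_initializer_used_when_totals_given(self):
        rng = np.random.default_rng(103)
        t = cells_per_duration(200)
        p = np.ones(t.size)
        alpha, gamma = 1.0, 0.4
        l = rng.poisson(p * mean_new_baseline(alpha, gamma, t))
        r = l + rng.poisson(p * (alpha / gamma) * np.exp(-gamma * t))
        fit = fit_csp_baseline(l, p, t, r=r)
        assert 0 < fit.init["gamma_t"] < 10 * gamma
        assert abs(fit.params["gamma_t"] - gamma) / gamma < 0.3


class TestSplicing:
    def test_noiseless_forward_inverse(self):
        t = cells_per_duration(20)
        alpha, beta, gamma_s = 2.0, 1.0, 0.5
        b, c = mean_new_splicing(alpha, beta, gamma_s, t)
        # continuous relaxation: place "counts" exactly at the means
        fit = fit_csp_splicing(b, c, np.ones(t.size), t)
        assert fit.params["beta"] == pytest.approx(beta, abs=1e-4)
        assert fit.params["gamma_s"] == pytest.approx(gamma_s, abs=1e-4)
        assert fit.params["alpha"] == pytest.approx(alpha, abs=1e-4)

    def test_recovery_at_reference_conditions(self):
        """gamma_s median relative error below 15% at the fixed-rate design."""
        rng = np.random.default_rng(104)
        t = cells_per_duration(500)
        errs = []
        for _ in range(15):
            alpha = rng.uniform(0.5, 1.0)
            beta = rng.uniform(0.5, 1.0)
            b, c = mean_new_splicing(alpha, beta, 0.5, t)
            p = rng.uniform(0.5, 2.0, t.size)
            fit = fit_csp_splicing(rng.poisson(p * b), rng.poisson(p * c), p, t)
            errs.append(abs(fit.params["gamma_s"] - 0.5) / 0.5)
        assert np.median(errs) < 0.15

    def test_profile_identity_at_optimum(self):
        rng = np.random.default_rng(105)
        t = cells_per_duration(100)
        p = rng.uniform(0.5, 2.0, t.size)
        b, c = mean_new_splicing(1.0, 0.8, 0.4, t)
        ul, sl = rng.poisson(p * b), rng.poisson(p * c)
        fit = fit_csp_splicing(ul, sl, p, t)
        expect = _profile_alpha_splicing(
            fit.params["beta"], fit.params["gamma_s"], ul.astype(float), sl.astype(float), p, t
        )
        assert fit.params["alpha"] == pytest.approx(expect, rel=1e-6)

    def test_zero_spliced_layer_flagged(self):
        rng = np.random.default_rng(106)
        t = cells_per_duration(100)
        p = np.ones(t.size)
        ul = rng.poisson(p * mean_new_baseline(1.0, 0.8, t))
        fit = fit_csp_splicing(ul, np.zeros_like(ul), p, t)
        assert not fit.converged


class TestSwitching:
    def test_p_off_zero_reduces_to_baseline(self):
        rng = np.random.default_rng(107)
        t = cells_per_duration(500)
        p = rng.uniform(0.5, 2.0, t.size)
        l = rng.poisson(p * mean_new_baseline(2.0, 0.5, t))
        fit_b = fit_csp_baseline(l, p, t)
        fit_s = fit_csp_switching(l, p, t)
        assert fit_s.params["p_off"] <= 0.05
        assert fit_s.params["alpha"] == pytest.approx(fit_b.params["alpha"], rel=0.05)
        assert fit_s.params["gamma_t"] == pytest.approx(fit_b.params["gamma_t"], rel=0.05)

    def test_recovers_p_off(self):
        rng = np.random.default_rng(108)
        t = cells_per_duration(1000)
        p = rng.uniform(0.5, 2.0, t.size)
        a = mean_new_baseline(2.0, 0.5, t)
        on = rng.random(t.size) >= 0.3
        l = np.where(on, rng.poisson(p * a), 0)
        fit = fit_csp_switching(l, p, t)
        assert abs(fit.params["p_off"] - 0.3) < 0.05

    def test_all_zero_gene_hits_off_boundary(self):
        t = cells_per_duration(10)
        fit = fit_csp_switching(np.zeros_like(t), np.ones_like(t), t)
        assert fit.params["p_off"] == 1.0
        assert not fit.converged

    def test_moment_initializer_clipped_with_warning(self):
        # strongly underdispersed data pushes the moment estimate of p_off
        # below zero, which must be clipped with a warning
        t = cells_per_duration(50)
        l = np.tile([1.0, 1.0, 1.0, 2.0], t.size // 4)
        with pytest.warns(UserWarning, match="clipped"):
            fit_csp_switching(l, np.ones(t.size), t)


class TestDeviance:
    @staticmethod
    def perfect_fit_data():
        # choose (alpha, gamma) so a(t1)=2 and a(t2)=3 are integers
        t1, t2 = 1.0, 3.0
        g = brentq(lambda g: (1 - np.exp(-g * t2)) / (1 - np.exp(-g * t1)) - 1.5, 1e-3, 5.0)
        t = np.concatenate([np.full(50, t1), np.full(50, t2)])
        l = np.concatenate([np.full(50, 2.0), np.full(50, 3.0)])
        return l, t

    def test_perfect_fit_gives_zero_deviance_and_unit_r2(self):
        l, t = self.perfect_fit_data()
        fit = fit_csp_baseline(l, np.ones(t.size), t)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-8)

    def test_null_equals_model_identity(self):
        """When the fitted model cannot beat the intercept, the adjusted index
        equals 1 - d_D0/d_D = -1/(N-2)."""
        n = 40
        # constant duration would be rejected; use two durations but force the
        # fit to the null by data with no duration trend and gamma ~ 0
        t = np.array([1.0, 2.0] * (n // 2))
        l = np.full(n, 3.0)
        fit = fit_csp_baseline(l, np.ones(n) * 2.0 / t, t)  # p*w(t) constant-ish
        # identity check performed on the definition itself
        r2_from_parts = 1 - (fit.deviance / fit.d_D) / (fit.null_deviance / fit.d_D0)
        assert fit.r2_adj == pytest.approx(r2_from_parts)

    def test_likelihood_ordering_on_simulated_panel(self):
        rng = np.random.default_rng(110)
        t = cells_per_duration(100)
        for _ in range(10):
            p = rng.uniform(0.5, 2.0, t.size)
            l = rng.poisson(p * mean_new_baseline(rng.uniform(0.5, 2), rng.uniform(0.05, 1), t))
            fit = fit_csp_baseline(l, p, t)
            assert fit.loglik_sat >= fit.loglik - 1e-6
            assert fit.loglik >= fit.loglik_null - 1e-6

    def test_baseline_deviance_matches_bruteforce_sum(self):
        from scipy.stats import poisson

        rng = np.random.default_rng(111)
        t = cells_per_duration(50)
        p = rng.uniform(0.5, 2.0, t.size)
        l = rng.poisson(p * mean_new_baseline(1.0, 0.5, t))
        fit = fit_csp_baseline(l, p, t)
        mean = p * mean_new_baseline(fit.params["alpha"], fit.params["gamma_t"], t)
        direct = -2 * (
            poisson.logpmf(l, np.maximum(mean, 1e-12)).sum()
            - poisson.logpmf(l, np.maximum(l, 1e-12)).sum()
        )
        assert fit.deviance == pytest.approx(direct, rel=1e-10)


class TestSelection:
    def test_top_third(self):
        np.testing.assert_array_equal(select_genes([0.9, 0.5, 0.1], 1 / 3), [0])

    def test_full_fraction_returns_all(self):
        np.testing.assert_array_equal(select_genes([0.2, 0.4], 1.0), [0, 1])

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(112)
        r2 = rng.normal(size=100)
        chosen = select_genes(r2, 0.4)
        assert len(chosen) == 40
        assert r2[chosen].min() >= np.quantile(r2, 0.6) - 1e-12

    def test_missing_values_rank_last(self):
        r2 = np.array([0.5, np.nan, 0.7, np.nan])
        np.testing.assert_array_equal(select_genes(r2, 0.5), [0, 2])

    def test_ceil_count(self):
        assert len(select_genes(np.arange(7) / 7, 0.4)) == 3  # ceil(2.8)


class TestRobustness:
    def test_nonnegative(self):
        rng = np.random.default_rng(113)
        t = cells_per_duration(50)
        l = rng.poisson(mean_new_baseline(1.0, 0.5, t))
        assert robustness_measure(l, np.ones(t.size), t) >= 0

    def test_quasi_linear_gene_scores_lower(self):
        """A gene in the gamma*t << 1 regime (accumulation linear in t) is
        less identifiable than a fast-degrading gene at matched expression:
        transcription rates are set so both genes reach the same labeled mean
        at the longest duration, isolating shape from depth."""
        rng = np.random.default_rng(114)
        t = cells_per_duration(300)
        p = np.ones(t.size)
        target = 3.0  # labeled mean at t = 3 h
        measures = {}
        for gamma in (0.01, 1.2):
            alpha = target * gamma / (1 - np.exp(-gamma * 3.0))
            l = rng.poisson(p * mean_new_baseline(alpha, gamma, t))
            measures[gamma] = robustness_measure(l, p, t)
        assert measures[0.01] < measures[1.2]

    def test_quadrature_matches_riemann_sum(self):
        from labelvelo.kinetics import _profile_alpha_baseline

        rng = np.random.default_rng(115)
        t = cells_per_duration(100)
        p = rng.uniform(0.5, 2.0, t.size)
        l = rng.poisson(p * mean_new_baseline(1.0, 0.8, t)).astype(float)
        val = robustness_measure(l, p, t)

        def integrand(gamma):
            gamma = max(gamma, 1e-12)
            alpha = _profile_alpha_baseline(gamma, l, p, t)
            w = mean_new_baseline(1.0, gamma, t)
            x = gamma * t
            dw = np.where(x < 1e-6, -(t**2) / 2 + (t**2) * x / 3, (t * np.exp(-x) - w) / gamma)
            return abs(np.sum((np.where(w > 0, l / np.maximum(w, 1e-12), 0) - p * alpha) * dw))

        grid = np.linspace(1e-9, 1.5, 10001)
        riemann = np.trapezoid([integrand(g) for g in grid], grid)
        assert val == pytest.approx(riemann, rel=1e-4)


class TestOrderInvariance:
    def test_results_independent_of_gene_order(self):
        rng = np.random.default_rng(116)
        t = cells_per_duration(100)
        p = rng.uniform(0.5, 2.0, t.size)
        genes = [rng.poisson(p * mean_new_baseline(1.0, g, t)) for g in (0.2, 0.5, 0.9)]
        direct = [fit_csp_baseline(l, p, t).params for l in genes]
        reverse = [fit_csp_baseline(l, p, t).params for l in genes[::-1]][::-1]
        for d, r in zip(direct, reverse):
            assert d == r
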