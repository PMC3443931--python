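"""Cumulative-Gaussian fitting, bootstrap SEs, bias correction, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from avbisect import (
    FitError,
    PsychometricFit,
    PsychometricModel,
    asymptotic_se,
    bias_correct,
    bootstrap_se,
    fit_cumulative_gaussian,
    pooled_bimodal_threshold,
    probit_nll,
)


def simulate_xy(mu, sigma, n, placement_sd, seed):
    gen = np.random.default_rng(seed)
    x = gen.normal(0.0, placement_sd, n)
    y = (gen.random(n) < ndtr((x - mu) / sigma)).astype(float)
    return x, y


class TestFit:
    def test_recovers_generating_parameters(self, probit_sample):
        x, y = probit_sample
        f = fit_cumulative_gaussian((x, y))
        assert 7 <= f.pse <= 13
        assert 45 <= f.threshold <= 55
        assert f.converged

    def test_mirrored_data_give_zero_pse(self):
        x = np.array([-60.0, -40, -20, -5, 5, 20, 40, 60] * 5)
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1] * 5)
        x_all = np.concatenate([x, -x])
        y_all = np.concatenate([y, 1 - y])
        # add central overlap so the sample is not perfectly separated
        x_all = np.concatenate([x_all, [-10.0, 10.0, -10.0, 10.0]])
        y_all = np.concatenate([y_all, [1.0, 0.0, 1.0, 0.0]])
        f = fit_cumulative_gaussian((x_all, y_all))
        assert f.pse == pytest.approx(0.0, abs=1e-6)

    def test_refit_is_deterministic(self, probit_sample):
        f1 = fit_cumulative_gaussian(probit_sample)
        f2 = fit_cumulative_gaussian(probit_sample)
        assert f1.pse == f2.pse and f1.threshold == f2.threshold

    def test_single_class_error_names_condition(self):
        x = np.linspace(-10, 10, 30)
        y = np.ones(30)
        with pytest.raises(FitError, match="auditory"):
            fit_cumulative_gaussian((x, y), condition="auditory")

    def test_too_few_trials_rejected(self):
        with pytest.raises(FitError, match="minimum"):
            fit_cumulative_gaussian((np.arange(5.0), np.array([0, 0, 1, 1, 1.0])))

    def test_perfect_separation_flagged_not_fitted(self):
        x = np.concatenate([np.linspace(-50, -10, 15), np.linspace(10, 50, 15)])
        y = np.concatenate([np.zeros(15), np.ones(15)])
        f = fit_cumulative_gaussian((x, y))
        assert not f.converged
        assert any("separated" in w for w in f.warnings)
        assert np.isnan(f.threshold)

    def test_threshold_below_placement_resolution_flagged(self):
        # One overlap pair keeps the MLE finite but far below what the
        # placement grid can resolve.
        x = np.concatenate([np.linspace(-50, -10, 14), [0.1, -0.1],
                            np.linspace(10, 50, 14)])
        y = np.concatenate([np.zeros(14), [0.0, 1.0], np.ones(14)])
        f = fit_cumulative_gaussian((x, y))
        assert not f.converged

    def test_shift_and_scale_equivariance(self, probit_sample):
        x, y = probit_sample
        base = fit_cumulative_gaussian((x, y))
        shifted = fit_cumulative_gaussian((x + 25.0, y))
        assert shifted.pse == pytest.approx(base.pse + 25.0, abs=1e-6)
        assert shifted.threshold == pytest.approx(base.threshold, abs=1e-6)
        scaled = fit_cumulative_gaussian((3.0 * x, y))
        assert scaled.pse == pytest.approx(3.0 * base.pse, abs=1e-6)
        assert scaled.threshold == pytest.approx(3.0 * base.threshold, abs=1e-6)

    def test_recovers_generative_model_within_asymptotic_error(self):
        """On data from the observer model (no lapse), the fit recovers the
        analytic PSE and effective sigma within 4 asymptotic SEs."""
        from avbisect import ObserverParams, TrialSpec, response_probability

        params = ObserverParams(sigma_v=80.0, sigma_a=60.0, rule="optimal")
        gen = np.random.default_rng(5)
        x = gen.normal(0.0, 120.0, 2000)
        specs = [TrialSpec("time", "bimodal", 50.0, float(xi)) for xi in x]
        p = np.array([response_probability(s, params) for s in specs])
        y = (gen.random(2000) < p).astype(float)
        # analytic: e = x + 2 w_A Δ, σ_eff = Eq-1 value
        w_a = 80.0**2 / (80.0**2 + 60.0**2)
        sigma_eff = np.sqrt(80.0**2 * 60.0**2 / (80.0**2 + 60.0**2))
        true_pse = -2 * w_a * 50.0
        f = fit_cumulative_gaussian((x, y))
        se_mu, se_sigma = asymptotic_se(x, true_pse, sigma_eff)
        assert abs(f.pse - true_pse) < 4 * se_mu
        assert abs(f.threshold - sigma_eff) < 4 * se_sigma


class TestGridSearchOracle:
    def test_ml_fit_matches_exhaustive_grid_search(self):
        x, y = simulate_xy(mu=5.0, sigma=20.0, n=200, placement_sd=30.0, seed=42)
        f = fit_cumulative_gaussian((x, y))
        mus = np.arange(f.pse - 10, f.pse + 10, 0.25)
        sigmas = np.arange(max(f.threshold - 10, 1.0), f.threshold + 10, 0.25)
        nll = np.array([[probit_nll(x, y, m, s) for s in sigmas] for m in mus])
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        assert abs(f.pse - mus[i]) <= 0.25 + 1e-9
        assert abs(f.threshold - sigmas[j]) <= 0.25 + 1e-9


class TestStatsmodelsCrossCheck:
    def test_agrees_with_probit_regression(self, probit_sample):
        sm = pytest.importorskip("statsmodels.api")
        x, y = probit_sample
        X = sm.add_constant(x)
        res = sm.Probit(y, X).fit(disp=0)
        a, b = res.params
        f = fit_cumulative_gaussian((x, y))
        assert f.pse == pytest.approx(-a / b, rel=1e-4)
        assert f.threshold == pytest.approx(1 / b, rel=1e-4)


class TestBootstrap:
    def test_se_within_factor_of_asymptotic(self, probit_sample):
        x, y = probit_sample
        f = fit_cumulative_gaussian((x, y))
        pse_se, thr_se, n_failed, _ = bootstrap_se(
            (x, y), n_boot=100, rng=np.random.default_rng(0)
        )
        se_mu, se_sigma = asymptotic_se(x, f.pse, f.threshold)
        assert se_mu / 1.5 < pse_se < se_mu * 1.5
        assert se_sigma / 1.5 < thr_se < se_sigma * 1.5
        assert n_failed == 0

    def test_se_shrinks_like_root_n(self):
        x1, y1 = simulate_xy(0.0, 50.0, 800, 100.0, 7)
        x2, y2 = simulate_xy(0.0, 50.0, 1600, 100.0, 8)
        se1, _, _, _ = bootstrap_se((x1, y1), n_boot=200, rng=np.random.default_rng(1))
        se2, _, _, _ = bootstrap_se((x2, y2), n_boot=200, rng=np.random.default_rng(2))
        ratio = se2 / se1
        assert abs(ratio - 2**-0.5) < 0.25 * 2**-0.5

    def test_single_replicate_degenerate(self, probit_sample):
        pse_se, thr_se, _, warnings = bootstrap_se(
            probit_sample, n_boot=1, rng=np.random.default_rng(0)
        )
        assert pse_se == 0.0 and thr_se == 0.0
        assert any("degenerate" in w for w in warnings)


class TestBiasCorrect:
    def make_fit(self, conflict, pse):
        return PsychometricFit(pse=pse, threshold=50.0, conflict=conflict,
                               condition="bimodal", pse_se=1.0)

    def test_subtracts_zero_conflict_pse(self):
        out = bias_correct([self.make_fit(0.0, 12.0), self.make_fit(50.0, 40.0)])
        by_c = {p.conflict: p.pse_corrected for p in out}
        assert by_c[50.0] == pytest.approx(28.0)
        assert by_c[0.0] == 0.0

    def test_equal_pses_map_to_zero(self):
        out = bias_correct([self.make_fit(c, 5.0) for c in (-50.0, 0.0, 50.0)])
        assert all(p.pse_corrected == pytest.approx(0.0) for p in out)

    def test_translation_invariance(self):
        fits = [self.make_fit(c, p) for c, p in [(-50.0, -20.0), (0.0, 3.0), (50.0, 31.0)]]
        shifted = [self.make_fit(f.conflict, f.pse + 17.0) for f in fits]
        a = {p.conflict: p.pse_corrected for p in bias_correct(fits)}
        b = {p.conflict: p.pse_corrected for p in bias_correct(shifted)}
        assert a == pytest.approx(b)

    def test_missing_zero_conflict_errors(self):
        with pytest.raises(FitError, match="zero-conflict"):
            bias_correct([self.make_fit(50.0, 1.0), self.make_fit(-50.0, -1.0)])


class TestPooledThreshold:
    def make_condition(self, conflict, pse, sigma, n, seed):
        gen = np.random.default_rng(seed)
        x = gen.normal(pse, 120.0, n)
        y = (gen.random(n) < ndtr((x - pse) / sigma)).astype(float)
        return (conflict, x, y)

    def test_recovers_common_sigma_across_conflicts(self):
        # Average over independent replicate cohorts: the pooled estimator
        # is centered on the common sigma (one 270-trial replicate alone
        # has an SE of ~7, wider than this band).
        estimates = []
        for rep in range(5):
            conds = [
                self.make_condition(-50.0, -40.0, 80.0, 90, 10 * rep + 1),
                self.make_condition(0.0, 0.0, 80.0, 90, 10 * rep + 2),
                self.make_condition(50.0, 40.0, 80.0, 90, 10 * rep + 3),
            ]
            pooled = pooled_bimodal_threshold(conds, recenter=True)
            assert pooled.converged and pooled.pse == 0.0
            estimates.append(pooled.threshold)
        assert 74 <= np.mean(estimates) <= 86

    def test_single_condition_matches_plain_fit(self):
        cond = self.make_condition(0.0, 10.0, 60.0, 400, 4)
        pooled = pooled_bimodal_threshold([cond], recenter=True)
        plain = fit_cumulative_gaussian((cond[1], cond[2]))
        assert pooled.threshold == pytest.approx(plain.threshold, rel=0.02)

    def test_invariant_to_condition_order(self):
        conds = [
            self.make_condition(-50.0, -40.0, 80.0, 90, 1),
            self.make_condition(0.0, 0.0, 80.0, 90, 2),
            self.make_condition(50.0, 40.0, 80.0, 90, 3),
        ]
        a = pooled_bimodal_threshold(conds, recenter=True).threshold
        b = pooled_bimodal_threshold(conds[::-1], recenter=True).threshold
        assert a == pytest.approx(b, abs=1e-9)

    def test_without_recentering_conflict_shifts_inflate_sigma(self):
        conds = [
            self.make_condition(-50.0, -40.0, 80.0, 300, 1),
            self.make_condition(0.0, 0.0, 80.0, 300, 2),
            self.make_condition(50.0, 40.0, 80.0, 300, 3),
        ]
        recentered = pooled_bimodal_threshold(conds, recenter=True).threshold
        raw = pooled_bimodal_threshold(conds, recenter=False).threshold
        assert raw > recentered

    def test_bootstrap_se_available(self):
        conds = [self.make_condition(c, 0.0, 80.0, 90, int(c) + 60)
                 for c in (-50.0, 0.0, 50.0)]
        pooled = pooled_bimodal_threshold(
            conds, recenter=True, n_boot=100, rng=np.random.default_rng(0)
        )
        assert np.isfinite(pooled.threshold_se) and pooled.threshold_se > 0


class TestSklearnEstimator:
    def test_fit_predict_proba(self, probit_sample):
        x, y = probit_sample
        m = PsychometricModel().fit(x, y)
        proba = m.predict_proba(np.array([-100.0, m.pse_, 200.0]))
        assert proba.shape == (3, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert proba[1, 1] == pytest.approx(0.5, abs=1e-9)
        assert m.predict(np.array([[1e4]]))[0] == 1

    def test_get_set_params_round_trip(self):
        m = PsychometricModel(n_boot=7)
        assert m.get_params()["n_boot"] == 7
        m.set_params(n_boot=3)
        assert m.n_boot == 3

    def test_sklearn_clone(self, probit_sample):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.base import clone

        m = PsychometricModel(n_boot=0, random_state=1)
        m2 = clone(m)
        x, y = probit_sample
        assert m2.fit(x, y).pse_ == pytest.approx(m.fit(x, y).pse_)
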