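"""Hypoexponential models: density, ML fitting, GOF, moment subtraction."""

import numpy as np
import pytest
from scipy.integrate import quad

from arakin.interval_statistics import SampleStats, sample_stats
from arakin.step_model import (HypoExpModel, estimate_tdiff, fit_hypoexp,
                               hypoexp_cdf, hypoexp_pdf,
                               hypoexp_pdf_partial_fraction, ks_gof)
from arakin.synthetic_data import sample_hypoexp


class TestDensity:
    def test_single_step_is_exponential(self):
        lam = 1 / 800.0
        t = np.linspace(0, 5000, 50)
        np.testing.assert_allclose(hypoexp_pdf([lam], t),
                                   lam * np.exp(-lam * t), rtol=1e-9)

    def test_equal_rates_match_erlang_closed_form(self):
        r = 1 / 480.0
        t = np.linspace(1, 6000, 60)
        erlang = r * (r * t) ** 2 * np.exp(-r * t) / 2.0
        np.testing.assert_allclose(hypoexp_pdf([r, r, r], t), erlang, rtol=1e-8)
        model = HypoExpModel(rates=(r, r, r))
        assert model.var / model.mean**2 == pytest.approx(1 / 3)

    def test_density_integrates_to_one_with_correct_mean(self):
        rates = (1 / 1000.0, 1 / 2000.0)
        total, _ = quad(lambda t: hypoexp_pdf(rates, t), 0, 60_000, limit=200)
        mean, _ = quad(lambda t: t * hypoexp_pdf(rates, t), 0, 60_000, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)
        assert mean == pytest.approx(3000.0, rel=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_phase_type_matches_partial_fractions_when_stable(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1e-4, 1e-2)
        rates = base * np.cumprod(rng.uniform(1.15, 2.0, size=3))
        t = np.linspace(0, 5 / base / 3, 200)
        f_pt = hypoexp_pdf(rates, t)
        f_pf = hypoexp_pdf_partial_fraction(rates, t)
        assert np.max(np.abs(f_pt - f_pf)) < 1e-10

    def test_near_equal_rates_remain_normalized(self):
        r = 1e-3
        rates = (r, r * (1 + 1e-8), r * (1 - 1e-8))
        total, _ = quad(lambda t: hypoexp_pdf(rates, t), 0, 40_000, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)
        t = np.linspace(0, 20_000, 100)
        cdf = hypoexp_cdf(rates, t)
        assert (np.diff(cdf) >= -1e-12).all()
        # Erlang-3 closed-form survival at the horizon
        x = r * 20_000
        survival = np.exp(-x) * (1 + x + x**2 / 2)
        assert cdf[-1] == pytest.approx(1.0 - survival, abs=1e-9)

    def test_negative_time_has_zero_density(self):
        assert hypoexp_pdf([1 / 100], -5.0) == 0.0
        assert hypoexp_cdf([1 / 100, 1 / 200], -5.0) == 0.0


class TestFit:
    def test_single_step_closed_form_mle(self):
        x = sample_hypoexp([1 / 900.0], 200, seed=1)
        m = fit_hypoexp(x, d=1)
        assert m.rates[0] == pytest.approx(1.0 / x.mean(), rel=1e-12)

    def test_erlang3_mean_recovered_within_five_percent(self):
        x = sample_hypoexp([1 / 480.0] * 3, 500, seed=2)
        m = fit_hypoexp(x, d=3, seed=0)
        assert m.mean == pytest.approx(1440.0, rel=0.05)

    def test_nested_family_loglikelihood_ordering(self):
        x = sample_hypoexp([1 / 480.0] * 3, 500, seed=3)
        ll3 = fit_hypoexp(x, d=3, seed=0).loglik
        ll1 = fit_hypoexp(x, d=1).loglik
        assert ll3 >= ll1

    def test_ml_consistency_large_sample(self):
        x = sample_hypoexp([1 / 300.0, 1 / 500.0, 1 / 700.0], 10_000, seed=4)
        m = fit_hypoexp(x, d=3, seed=0, n_starts=4)
        assert m.mean == pytest.approx(1500.0, rel=0.01)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_hypoexp([100.0] * 20, d=3)


class TestGof:
    def test_well_specified_model_not_rejected(self):
        model = HypoExpModel(rates=(1 / 400.0, 1 / 500.0, 1 / 600.0))
        x = model.sample(500, seed=5)
        d, p = ks_gof(x, model)
        assert d < 1.358 / np.sqrt(500)   # asymptotic 5% critical value
        assert p > 0.05

    def test_misspecified_model_strongly_rejected(self):
        model = HypoExpModel(rates=(1 / 400.0, 1 / 500.0, 1 / 600.0))
        fast = HypoExpModel(rates=tuple(10 * r for r in model.rates))
        x = model.sample(500, seed=6)
        _, p = ks_gof(x, fast)
        assert p < 1e-6

    def test_small_sample_p_agrees_with_simulation_oracle(self):
        model = HypoExpModel(rates=(1 / 300.0, 1 / 900.0))
        x = model.sample(10, seed=7)
        d_obs, p = ks_gof(x, model)
        # oracle: distribution of D under the model by direct simulation
        rng = np.random.default_rng(8)
        exceed = 0
        reps = 4000
        for _ in range(reps):
            u = np.sort(model.cdf(model.sample(10, rng)))
            k = np.arange(1, 11)
            d = max((k / 10 - u).max(), (u - (k - 1) / 10).max())
            exceed += d >= d_obs - 1e-12
        p_mc = exceed / reps
        assert p == pytest.approx(p_mc, abs=4 * np.sqrt(p_mc * (1 - p_mc) / reps))

    def test_parametric_bootstrap_p_in_range(self):
        model = HypoExpModel(rates=(1 / 700.0,))
        x = model.sample(80, seed=9)
        fitted = fit_hypoexp(x, d=1)
        _, p = ks_gof(x, fitted, bootstrap=40, seed=0)
        assert 0.0 < p <= 1.0


class TestTdiff:
    def test_strong_induction_intake_mean(self):
        t0 = SampleStats(84, 2885.0, 1159.8, (1159.8 / 2885.0) ** 2)
        dt = SampleStats(102, 1440.6, 532.8, (532.8 / 1440.6) ** 2)
        est = estimate_tdiff(t0, dt)
        assert est.valid
        assert est.mean == pytest.approx(1444.4, abs=0.1)
        assert est.sd == pytest.approx(np.sqrt(1159.8**2 - 532.8**2), rel=1e-12)

    def test_iptg_intake_sd(self):
        t0 = SampleStats(286, 2697.0, 913.6, (913.6 / 2697.0) ** 2)
        dt = SampleStats(485, 1314.4, 576.0, (576.0 / 1314.4) ** 2)
        est = estimate_tdiff(t0, dt)
        assert est.sd == pytest.approx(709.2, abs=0.5)

    def test_identical_stats_give_zero(self):
        s = SampleStats(100, 1000.0, 300.0, 0.09)
        est = estimate_tdiff(s, s)
        assert est.mean == 0.0
        assert est.sd == 0.0
        assert est.valid

    def test_negative_variance_difference_flagged_not_raised(self):
        t0 = SampleStats(50, 2000.0, 100.0, 0.0025)
        dt = SampleStats(50, 1500.0, 500.0, 0.111)
        est = estimate_tdiff(t0, dt)
        assert not est.valid
        assert est.mean == pytest.approx(500.0)
        assert np.isnan(est.sd)

    def test_recovers_true_intake_moments_on_synthetic_population(self):
        # independent intake (2-step) and initiation (3-step) by construction
        n = 300
        intake = sample_hypoexp([1 / 722.0] * 2, n, seed=10)
        first = sample_hypoexp([3 / 1440.6] * 3, n, seed=11)
        dts = sample_hypoexp([3 / 1440.6] * 3, 400, seed=12)
        est = estimate_tdiff(sample_stats(intake + first), sample_stats(dts))
        true_mean, true_sd = 1444.0, 722.0 * np.sqrt(2)
        se_mean = np.sqrt((2 * 722**2 + 1440.6**2 / 3) / n
                          + (1440.6**2 / 3) / 400)
        assert est.valid
        assert abs(est.mean - true_mean) < 3 * se_mean
        assert est.sd == pytest.approx(true_sd, rel=0.25)
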