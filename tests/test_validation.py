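import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logsumexp

from frailpheno.distributions import beta_logpdf
from frailpheno.model import BetaFrailtyRegressor, ModelSpec
from frailpheno.validation import (bayes_r2, calibration_curve, elpd_compare,
                                   fit_generalized_pareto, loo_for_model,
                                   pointwise_loglik, psis_loo,
                                   smooth_log_weights)


@pytest.fixture(scope="module")
def small_fit():
    """Intercept-only beta fit on iid data, reused across LOO tests."""
    rng = np.random.default_rng(10)
    y = np.clip(rng.beta(0.12 * 20, 0.88 * 20, 60), 1e-5, 1 - 1e-5)
    df = pd.DataFrame({"dummy": np.zeros(60)})
    m = BetaFrailtyRegressor(spec=ModelSpec(kind="custom"), chains=2,
                             iterations=600, seed=10).fit(df, y)
    return m, y


class TestPointwiseLoglik:
    def test_shape_and_direct_evaluation(self, small_fit):
        m, y = small_fit
        ll = pointwise_loglik(m)
        assert ll.shape == (m._flat.shape[0], 60)
        # independent recomputation of a few entries
        mu = m.mu_draws()
        phi = m.phi_draws_
        for s, i in [(0, 0), (5, 30), (100, 59)]:
            ref = beta_logpdf(y[i], mu[s, i], phi[s])
            assert ll[s, i] == pytest.approx(ref, abs=1e-12)

    def test_uniform_model_gives_zeros(self):
        y = np.array([0.2, 0.5, 0.9])
        ll = beta_logpdf(y[None, :], np.full((4, 3), 0.5), np.full((4, 1), 2.0))
        np.testing.assert_allclose(ll, 0.0, atol=1e-12)


class TestGPDFit:
    def test_recovers_known_shape(self):
        rng = np.random.default_rng(5)
        u = rng.random(10000)
        x = (np.power(1 - u, -0.3) - 1) / 0.3  # GPD(k=0.3, sigma=1) inverse CDF
        k, sigma = fit_generalized_pareto(x)
        assert k == pytest.approx(0.3, abs=0.05)

    def test_exponential_limit_is_shape_zero(self):
        rng = np.random.default_rng(6)
        k, _ = fit_generalized_pareto(rng.exponential(size=10000))
        assert k == pytest.approx(0.0, abs=0.05)

    def test_constant_tail_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_generalized_pareto(np.ones(50))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_generalized_pareto(np.array([1.0, 2.0, 3.0]))


class TestPsisLoo:
    def test_degenerate_draws_give_plain_log_density(self):
        y = np.array([0.1, 0.3, 0.6])
        ll_row = beta_logpdf(y, 0.25, 10.0)
        ll = np.tile(ll_row, (500, 1))  # likelihood independent of the draw
        res = psis_loo(ll)
        np.testing.assert_allclose(res.pointwise, ll_row, atol=1e-12)

    def test_perfect_loo_predictions_give_r2_one(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0.05, 0.3, 50)
        mu = np.tile(y, (500, 1))
        ll = beta_logpdf(np.tile(y, (500, 1)), np.clip(mu, 1e-6, 1 - 1e-6), 50.0)
        res = psis_loo(ll, mu_draws=mu, y=y)
        assert res.loo_r2 == pytest.approx(1.0, abs=1e-10)

    def test_smoothing_preserves_order_and_max(self):
        rng = np.random.default_rng(8)
        lr = rng.normal(0, 2, 2000)
        lw, k = smooth_log_weights(lr)
        assert lw.max() <= 1e-12  # never exceeds the raw maximum (0 after shift)
        order_raw = np.argsort(lr)
        assert (np.diff(lw[order_raw]) >= -1e-12).all()

    def test_matches_arviz_psislw(self):
        import warnings
        import xarray
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from arviz.stats import psislw
        rng = np.random.default_rng(9)
        lr = rng.normal(0, 1.5, size=(2000, 20))
        lw_az, k_az = psislw(xarray.DataArray(lr.T, dims=["obs", "__sample__"]))
        for i in range(20):
            lw, k = smooth_log_weights(lr[:, i])
            lwn = lw - logsumexp(lw)
            np.testing.assert_allclose(lwn, lw_az.values[i], atol=1e-10)
            assert k == pytest.approx(float(k_az[i]), abs=1e-10)

    def test_loo_elpd_below_in_sample_elpd(self, small_fit):
        """PSIS-LOO removes in-sample optimism."""
        m, _ = small_fit
        ll = pointwise_loglik(m)
        res = psis_loo(ll, mu_draws=m.mu_draws(), y=m.y_train_)
        in_sample = float(np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0])))
        assert res.elpd_loo <= in_sample + 1e-9
        assert np.all(np.isfinite(res.pareto_k))
        assert res.elpd_loo == pytest.approx(res.pointwise.sum(), abs=1e-10)
        assert res.se == pytest.approx(np.std(res.pointwise, ddof=1) * np.sqrt(60), abs=1e-12)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            psis_loo(np.zeros((50, 5)))


class TestElpdCompare:
    def test_self_comparison_zero(self, small_fit):
        m, _ = small_fit
        loo = loo_for_model(m)
        d = elpd_compare(loo, loo)
        assert d.diff == 0.0 and d.se == 0.0

    def test_antisymmetry(self, small_fit):
        m, y = small_fit
        loo = loo_for_model(m)
        other = psis_loo(pointwise_loglik(m) * 0.97, mu_draws=m.mu_draws(), y=y)
        ab, ba = elpd_compare(loo, other), elpd_compare(other, loo)
        assert ab.diff == pytest.approx(-ba.diff, abs=1e-10)
        assert ab.se == pytest.approx(ba.se, abs=1e-10)

    def test_mismatched_n_rejected(self, small_fit):
        m, _ = small_fit
        loo = loo_for_model(m)
        short = psis_loo(pointwise_loglik(m)[:, :30])
        with pytest.raises(ValueError):
            elpd_compare(loo, short)


class TestBayesR2:
    def test_constant_mu_gives_zero(self, small_fit):
        m, _ = small_fit
        mean, ci, draws = bayes_r2(m)  # intercept-only: mu constant per draw
        assert mean == pytest.approx(0.0, abs=1e-10)

    def test_large_phi_drives_r2_to_one(self):
        class Fake:
            phi_draws_ = np.full(100, 1e9)
            def mu_draws(self, X=None):
                rng = np.random.default_rng(0)
                return np.tile(rng.uniform(0.05, 0.4, 200), (100, 1))
        mean, _, _ = bayes_r2(Fake())
        assert mean > 0.999

    def test_matches_monte_carlo_oracle(self):
        """Simulating y from each draw reproduces the variance decomposition."""
        rng = np.random.default_rng(11)
        n, S = 2000, 40
        mu = np.tile(expit(rng.normal(-2, 0.6, n)), (S, 1))
        phi = np.full(S, 25.0)
        class Fake:
            phi_draws_ = phi
            def mu_draws(self, X=None):
                return mu
        mean, _, _ = bayes_r2(Fake())
        r2_mc = []
        for s in range(S):
            y_rep = rng.beta(mu[s] * phi[s], (1 - mu[s]) * phi[s])
            r2_mc.append(mu[s].var() / y_rep.var())
        assert mean == pytest.approx(np.mean(r2_mc), abs=0.02)


class TestCalibration:
    def test_identity_when_perfect(self):
        rng = np.random.default_rng(12)
        pred = rng.uniform(0.05, 0.35, 400)
        gx, gy = calibration_curve(pred, pred)
        inner = (gx > np.quantile(pred, 0.05)) & (gx < np.quantile(pred, 0.95))
        np.testing.assert_allclose(gy[inner], gx[inner], atol=1e-6)

    @staticmethod
    def iqr_slope(gx, gy, pred):
        lo, hi = np.quantile(pred, [0.25, 0.75])
        sel = (gx >= lo) & (gx <= hi)
        return np.polyfit(gx[sel], gy[sel], 1)[0]

    def test_well_calibrated_slope_near_one(self):
        rng = np.random.default_rng(13)
        pred = rng.uniform(0.05, 0.35, 2000)
        obs = pred + rng.normal(0, 0.03, 2000)
        gx, gy = calibration_curve(obs, pred)
        assert 0.9 <= self.iqr_slope(gx, gy, pred) <= 1.1

    def test_known_miscalibration_slope_two(self):
        rng = np.random.default_rng(14)
        pred = rng.uniform(0.1, 0.4, 1500)
        obs = 2 * pred - 0.1 + rng.normal(0, 0.01, 1500)
        gx, gy = calibration_curve(obs, pred)
        assert self.iqr_slope(gx, gy, pred) == pytest.approx(2.0, abs=0.15)

    def test_constant_predictions_flagged(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            calibration_curve(np.linspace(0, 1, 30), np.full(30, 0.2))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve(np.ones(5), np.ones(5))
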