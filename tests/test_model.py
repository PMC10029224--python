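import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from frailpheno.model import (BetaFrailtyRegressor, ModelSpec, PosteriorFI,
                              classify_model_pfp, fit_model)


def make_design(n=150, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "gait_speed": rng.normal(1.3, 0.25, n),
        "cesd_q1": rng.integers(0, 4, n).astype(float),
        "sex": rng.choice(["woman", "man"], n),
    })


SMALL_SPEC = ModelSpec(kind="custom", smooth_terms=(("gait_speed", 6),),
                       monotonic_terms=(("cesd_q1", 4),), linear_terms=("sex",))


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    df = make_design()
    y = np.clip(rng.beta(2, 12, len(df)), 1e-4, 1 - 1e-4)
    m = BetaFrailtyRegressor(spec=SMALL_SPEC)
    m.spec_ = m._resolve_spec()
    m.bases_ = {}
    design = m._design(df, training=True)
    m._idx = m._layout()
    lg = m._make_logp_grad(y, *design)
    theta = rng.normal(0, 0.3, m._idx["dim"])
    _, g = lg(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        num = (lg(theta + e)[0] - lg(theta - e)[0]) / 2e-6
        assert g[i] == pytest.approx(num, abs=1e-5, rel=1e-5)


def test_zero_smooth_and_monotonic_reduces_to_linear_logistic():
    """With all spline and monotonic coefficients zero, mu is exactly
    logistic(intercept + linear terms)."""
    df = make_design(n=40, seed=1)
    m = BetaFrailtyRegressor(spec=SMALL_SPEC)
    m.spec_ = m._resolve_spec()
    m.bases_ = {}
    X_lin, s_lin, s_pen, monos = m._design(df, training=True)
    m._idx = m._layout()
    flat = np.zeros((1, m._idx["dim"]))
    flat[0, m._idx["intercept"]] = -2.0
    flat[0, m._idx["linear"]] = 0.7
    flat[0, m._idx["log_tau"]] = -30.0  # tau ~ 0 kills the penalized part
    mu = m._mu_from_design(flat, X_lin, s_lin, s_pen, monos)
    expected = expit(-2.0 + 0.7 * X_lin[:, 0])
    np.testing.assert_allclose(mu[0], expected, atol=1e-10)


def test_seeded_fit_is_deterministic():
    rng = np.random.default_rng(2)
    df = make_design(n=80, seed=2)
    y = np.clip(rng.beta(2, 14, 80), 1e-4, 1 - 1e-4)
    kw = dict(spec=SMALL_SPEC, chains=2, iterations=120, seed=7)
    a = BetaFrailtyRegressor(**kw).fit(df, y)
    b = BetaFrailtyRegressor(**kw).fit(df, y)
    np.testing.assert_array_equal(a.theta_draws_, b.theta_draws_)


def test_boundary_response_rejected():
    df = make_design(n=50, seed=3)
    y = np.linspace(0, 1, 50)  # contains 0 and 1
    with pytest.raises(ValueError, match="shrink"):
        BetaFrailtyRegressor(spec=SMALL_SPEC, chains=1, iterations=50).fit(df, y)


def test_missing_predictor_rejected():
    df = make_design(n=50, seed=4)
    df.loc[0, "gait_speed"] = np.nan
    y = np.full(50, 0.1)
    with pytest.raises(ValueError, match="impute"):
        BetaFrailtyRegressor(spec=SMALL_SPEC, chains=1, iterations=50).fit(df, y)


class TestFittedModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(5)
        df = make_design(n=200, seed=5)
        eta = -2.1 - 0.8 * (df["gait_speed"] - 1.3) + 0.15 * df["cesd_q1"]
        mu = expit(eta)
        y = np.clip(rng.beta(mu * 25, (1 - mu) * 25), 1e-5, 1 - 1e-5)
        m = BetaFrailtyRegressor(spec=SMALL_SPEC, chains=2, iterations=500, seed=5)
        return m.fit(df, y), df, mu.to_numpy()

    def test_posterior_fi_in_unit_interval_and_ordered(self, fitted):
        m, df, _ = fitted
        pfi = m.predict_fi(df)
        assert ((pfi.mean > 0) & (pfi.mean < 1)).all()
        assert (pfi.lower <= pfi.mean + 1e-12).all()
        assert (pfi.mean <= pfi.upper + 1e-12).all()

    def test_training_repredictions_match_stored_fit(self, fitted):
        m, df, _ = fitted
        np.testing.assert_allclose(m.predict(df), m.fitted_mean_, atol=1e-9)

    def test_simplex_constraint_on_every_draw(self, fitted):
        m, _, _ = fitted
        flat = m._flat
        for sl in m._idx["mono_a"]:
            a = np.concatenate([flat[:, sl], np.zeros((flat.shape[0], 1))], axis=1)
            ez = np.exp(a - a.max(axis=1, keepdims=True))
            zeta = ez / ez.sum(axis=1, keepdims=True)
            assert (zeta >= 0).all()
            np.testing.assert_allclose(zeta.sum(axis=1), 1.0, atol=1e-12)

    def test_monotone_ordinal_effect_for_every_draw(self, fitted):
        """The implied CES-D effect is monotone in the level, draw by draw."""
        m, df, _ = fitted
        grid = df.iloc[[0]].copy()
        mus = []
        for lev in range(4):
            g = grid.copy()
            g["cesd_q1"] = float(lev)
            mus.append(m.mu_draws(g)[:, 0])
        mus = np.column_stack(mus)  # draws x 4 levels
        b = m._flat[:, m._idx["mono_b"]][:, 0]
        diffs = np.diff(mus, axis=1)
        sign = np.sign(b)[:, None]
        assert (sign * diffs >= -1e-12).all()

    def test_recovers_signal(self, fitted):
        m, df, mu_true = fitted
        assert np.corrcoef(m.fitted_mean_, mu_true)[0, 1] > 0.9

    def test_phi_draws_positive(self, fitted):
        m, _, _ = fitted
        assert (m.phi_draws_ > 0).all()
        assert np.isfinite(m.diagnostics_["max_rhat"])

    def test_serialization_roundtrip_keys(self, fitted, tmp_path):
        import json
        m, _, _ = fitted
        text = m.to_json(tmp_path / "m.json")
        d = json.loads(text)
        assert set(d) >= {"spec", "draws", "transform_state", "diagnostics", "fitted_mean"}


def test_intercept_only_recovery():
    """Intercept-only model on iid beta data recovers the true mean."""
    rng = np.random.default_rng(6)
    mu0, phi0 = 0.12, 18.0
    y = np.clip(rng.beta(mu0 * phi0, (1 - mu0) * phi0, 300), 1e-5, 1 - 1e-5)
    df = pd.DataFrame({"dummy": np.zeros(300)})
    spec = ModelSpec(kind="custom")
    m = BetaFrailtyRegressor(spec=spec, chains=2, iterations=600, seed=6).fit(df, y)
    b0 = m._flat[:, m._idx["intercept"]]
    mu_post = expit(b0)
    assert abs(mu_post.mean() - mu0) < 2 * mu_post.std() + 0.01


def test_prior_predictive_mu_covers_unit_interval():
    """Weakly informative priors put mass across (0.01, 0.99) for mu."""
    rng = np.random.default_rng(7)
    intercept = 2.5 * rng.standard_t(3, size=4000)
    mu = expit(intercept)
    assert mu.min() < 0.01 and mu.max() > 0.99
    assert ((mu > 0.01) & (mu < 0.99)).mean() > 0.5


@pytest.mark.parametrize("mean,expected", [(0.10, "robust"), (0.15, "prefrail"),
                                           (0.25, "frail")])
def test_classify_model_pfp(mean, expected):
    pfi = PosteriorFI(mean=np.array([mean]), lower=np.array([mean]),
                      upper=np.array([mean]))
    assert classify_model_pfp(pfi) == [expected]


def test_spec_presets():
    full = ModelSpec.preset("full_pfp")
    assert {v for v, _ in full.smooth_terms} == {"gait_speed", "grip_strength",
                                                 "weight", "height", "walk_cbrt"}
    assert {v for v, _ in full.monotonic_terms} == {"cesd_q1", "cesd_q2"}
    assert full.linear_terms == ("sex",)
    assert ModelSpec.preset("referent").linear_terms == ("pfp_count",)
    gait = ModelSpec.preset("gait_speed")
    assert {v for v, _ in gait.smooth_terms} == {"gait_speed", "age", "weight", "height"}
    with pytest.raises(ValueError):
        ModelSpec.preset("nope")


def test_fit_model_functional_wrapper(scored_cohort):
    sub = scored_cohort.head(120).copy()
    from frailpheno.distributions import shrink_boundary
    sub["fi"] = shrink_boundary(sub["fi"].to_numpy(), len(sub))
    m = fit_model(sub, ModelSpec(kind="custom", linear_terms=("pfp_count",)),
                  chains=1, iterations=200, seed=0)
    assert m.fitted_mean_.shape == (120,)
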