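"""Bayesian beta regression for the frailty index: the model-based PFP.

The frailty index (a proportion in (0,1)) is regressed on non-dichotomized
physical-frailty-phenotype criterion measures: thin-plate regression spline
smooths for the continuous criteria (gait speed, grip strength, body weight,
body height, cube-root weekly walking time), monotonic ordinal effects for
the two CES-D exhaustion items, and sex as a linear covariate.  The mean of a
Beta(mu*phi, (1-mu)*phi) likelihood is linked to the linear predictor by the
logistic function.  Weakly informative priors; posterior sampled by
Hamiltonian Monte Carlo with analytic gradients.

Two comparator models share the machinery: a *referent* model with the
count-based PFP score as its only (linear) predictor, and a *gait speed*
model with a gait-speed smooth plus routine covariates (age, weight, height
smooths and sex).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, psi, logit
from sklearn.base import BaseEstimator, RegressorMixin

from . import hmc
from .preprocess import TransformState, transform_walk_time
from .scoring import classify_fi
from .splines import ThinPlateSplineBasis

logger = logging.getLogger(__name__)

RHAT_MAX = 1.01
ESS_MIN = 400


@dataclass
class PriorConfig:
    """Weakly informative prior scales (predictors standardized)."""

    coef_scale: float = 2.5          # Normal(0, .) linear and monotonic-scale coefficients
    intercept_scale: float = 2.5     # Student-t(3, 0, .) intercept
    intercept_df: float = 3.0
    smooth_sd_scale: float = 2.5     # half-Student-t(3, 0, .) per-smooth SD
    smooth_sd_df: float = 3.0
    dirichlet_conc: float = 1.0      # Dirichlet(conc, ...) on each simplex
    phi_shape: float = 0.01          # Gamma(shape, rate) on the precision phi
    phi_rate: float = 0.01


@dataclass
class ModelSpec:
    """Which terms enter the linear predictor.

    smooth_terms: (variable, basis size k) pairs — thin-plate spline smooths.
    monotonic_terms: (variable, number of ordinal levels) pairs.
    linear_terms: plain linear covariates (binary columns enter as 0/1).
    """

    kind: str = "custom"
    smooth_terms: tuple = ()
    monotonic_terms: tuple = ()
    linear_terms: tuple = ()
    prior_config: PriorConfig = field(default_factory=PriorConfig)

    KINDS = ("full_pfp", "referent", "gait_speed")

    @classmethod
    def preset(cls, kind: str, k: int = 10, referent_linear: bool = True) -> "ModelSpec":
        if kind == "full_pfp":
            return cls(kind=kind,
                       smooth_terms=(("gait_speed", k), ("grip_strength", k),
                                     ("weight", k), ("height", k), ("walk_cbrt", k)),
                       monotonic_terms=(("cesd_q1", 4), ("cesd_q2", 4)),
                       linear_terms=("sex",))
        if kind == "referent":
            if referent_linear:
                return cls(kind=kind, linear_terms=("pfp_count",))
            return cls(kind=kind, smooth_terms=(("pfp_count", 5),))
        if kind == "gait_speed":
            return cls(kind=kind,
                       smooth_terms=(("gait_speed", k), ("age", k),
                                     ("weight", k), ("height", k)),
                       linear_terms=("sex",))
        raise ValueError(f"unknown model kind {kind!r}; choose from {cls.KINDS}")


@dataclass
class PosteriorFI:
    """Per-subject posterior summary of the model's mean FI."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray | None = None  # (n_draws, n_subjects)


def _prepare_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Derived/encoded columns: sex -> 0/1, walk_cbrt from walk_time."""
    X = X.copy()
    if "sex" in X.columns and X["sex"].dtype == object:
        X["sex"] = (X["sex"] == "man").astype(float)
    if "walk_cbrt" not in X.columns and "walk_time" in X.columns:
        X["walk_cbrt"] = transform_walk_time(X["walk_time"].to_numpy(dtype=float))
    return X


class BetaFrailtyRegressor(BaseEstimator, RegressorMixin):
    """Beta regression of a (0,1) response on spline/monotonic/linear terms.

    scikit-learn style estimator: ``fit(X, y)`` with ``X`` a DataFrame holding
    the spec's named columns and ``y`` the frailty index strictly inside
    (0, 1) (shrink boundary values first), then ``predict(X)`` for posterior
    mean FI or :meth:`predict_fi` for mean plus 95% credible interval.

    Parameters
    ----------
    spec : ModelSpec or str
        Term structure; a string selects a preset ('full_pfp', 'referent',
        'gait_speed').
    chains, iterations : int
        MCMC budget; half of each chain is discarded as warm-up.
    seed : int
        Seeds the sampler; fixed seed gives identical draws.

    Attributes
    ----------
    draws_ : dict of parameter-block posterior draws
    diagnostics_ : per-parameter split R-hat and bulk ESS (max/min summaries)
    converged_ : bool, the R-hat <= 1.01 and ESS >= 400 contract
    transform_state_ : per-variable standardization used at prediction time
    fitted_mean_ : posterior mean mu for the training rows
    """

    def __init__(self, spec="full_pfp", chains: int = 4, iterations: int = 3000,
                 seed: int = 0, target_accept: float = 0.8, max_leapfrog: int = 96,
                 sim_length: float = 4.0):
        self.spec = spec
        self.chains = chains
        self.iterations = iterations
        self.seed = seed
        self.target_accept = target_accept
        self.max_leapfrog = max_leapfrog
        self.sim_length = sim_length

    # ------------------------------------------------------------------ setup
    def _resolve_spec(self) -> ModelSpec:
        return ModelSpec.preset(self.spec) if isinstance(self.spec, str) else self.spec

    def _design(self, X: pd.DataFrame, training: bool):
        """Assemble design pieces; on training, fit transforms and bases."""
        spec = self.spec_
        X = _prepare_columns(X)
        for v, _ in list(spec.smooth_terms) + list(spec.monotonic_terms):
            if v not in X.columns:
                raise ValueError(f"column {v!r} required by the model spec is absent")
        for v in spec.linear_terms:
            if v not in X.columns:
                raise ValueError(f"column {v!r} required by the model spec is absent")
        if training:
            state = TransformState()
            for v, _k in spec.smooth_terms:
                x = X[v].to_numpy(dtype=float)
                sd = float(np.std(x, ddof=1))
                if sd <= 0:
                    raise ValueError(f"smooth variable {v!r} has zero variance")
                state.means[v], state.sds[v] = float(np.mean(x)), sd
            for v in spec.linear_terms:
                x = X[v].to_numpy(dtype=float)
                if len(np.unique(x)) > 2:
                    sd = float(np.std(x, ddof=1))
                    if sd <= 0:
                        raise ValueError(f"linear variable {v!r} has zero variance")
                    state.means[v], state.sds[v] = float(np.mean(x)), sd
            self.transform_state_ = state
        state = self.transform_state_

        def std(v):
            x = X[v].to_numpy(dtype=float)
            if np.any(np.isnan(x)):
                raise ValueError(f"missing values in {v!r}; impute before fitting")
            if v in state.means:
                return (x - state.means[v]) / state.sds[v]
            return x

        X_lin = (np.column_stack([std(v) for v in spec.linear_terms])
                 if spec.linear_terms else np.zeros((len(X), 0)))
        smooth_lin, smooth_pen = [], []
        for si, (v, k) in enumerate(spec.smooth_terms):
            xs = std(v)
            if training:
                self.bases_[v] = ThinPlateSplineBasis(xs, k=k)
                lin, pen = self.bases_[v].linear_, self.bases_[v].penalized_
            else:
                lin, pen = self.bases_[v].evaluate(xs)
            smooth_lin.append(lin)
            smooth_pen.append(pen)
        mono_levels = []
        for v, L in spec.monotonic_terms:
            lev = X[v].to_numpy(dtype=float)
            if np.any(np.isnan(lev)):
                raise ValueError(f"missing values in {v!r}; impute before fitting")
            lev = lev.astype(int)
            if np.any((lev < 0) | (lev >= L)):
                raise ValueError(f"{v!r} levels must lie in 0..{L - 1}")
            mono_levels.append(lev)
        return X_lin, smooth_lin, smooth_pen, mono_levels

    def _layout(self):
        """Index map over the flat parameter vector."""
        spec = self.spec_
        idx, pos = {}, 0
        idx["intercept"] = pos; pos += 1
        idx["linear"] = slice(pos, pos + len(spec.linear_terms)); pos = idx["linear"].stop
        idx["smooth"] = []
        for v, k in spec.smooth_terms:
            s0 = pos; pos += 1
            sp = slice(pos, pos + (k - 2)); pos = sp.stop
            idx["smooth"].append((s0, sp))
        idx["log_tau"] = slice(pos, pos + len(spec.smooth_terms)); pos = idx["log_tau"].stop
        idx["mono_b"] = slice(pos, pos + len(spec.monotonic_terms)); pos = idx["mono_b"].stop
        idx["mono_a"] = []
        for v, L in spec.monotonic_terms:
            sl = slice(pos, pos + (L - 2)); pos = sl.stop
            idx["mono_a"].append(sl)
        idx["log_phi"] = pos; pos += 1
        idx["dim"] = pos
        return idx

    # ----------------------------------------------------------- log posterior
    def _make_logp_grad(self, y, X_lin, smooth_lin, smooth_pen, mono_levels):
        spec, idx = self.spec_, self._idx
        pc = spec.prior_config
        n = y.size
        log_y, log1m_y, logit_y = np.log(y), np.log1p(-y), logit(y)
        mono_ind = []
        for (v, L), lev in zip(spec.monotonic_terms, mono_levels):
            ind = (np.arange(1, L)[None, :] <= lev[:, None]).astype(float)  # n x (L-1)
            mono_ind.append(ind)

        def logp_grad(theta):
            g = np.zeros_like(theta)
            eta = np.full(n, theta[idx["intercept"]])
            beta = theta[idx["linear"]]
            if beta.size:
                eta += X_lin @ beta
            # non-centered smooths: penalized coefficients are tau * gamma_tilde
            log_tau_all = theta[idx["log_tau"]]
            tau_all = np.exp(np.clip(log_tau_all, -15, 15))
            gammas = []
            for s, ((s0, sp), lin, pen) in enumerate(zip(idx["smooth"], smooth_lin, smooth_pen)):
                gam = theta[sp]
                gammas.append(gam)
                eta += lin * theta[s0] + tau_all[s] * (pen @ gam)
            zetas, cums = [], []
            for m, sl in enumerate(idx["mono_a"]):
                a = np.append(theta[sl], 0.0)
                ez = np.exp(a - a.max())
                zeta = ez / ez.sum()
                zetas.append(zeta)
                cum = np.cumsum(zeta)
                cums.append(cum)
                b = theta[idx["mono_b"]][m]
                eta += b * (mono_ind[m] @ zeta)
            log_phi = theta[idx["log_phi"]]
            phi = np.exp(np.clip(log_phi, -20, 20))
            mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
            a_sh, b_sh = mu * phi, (1 - mu) * phi
            ll = (n * gammaln(phi) - gammaln(a_sh).sum() - gammaln(b_sh).sum()
                  + ((a_sh - 1) * log_y).sum() + ((b_sh - 1) * log1m_y).sum())
            psi_a, psi_b = psi(a_sh), psi(b_sh)
            r = logit_y - (psi_a - psi_b)
            gscore = phi * mu * (1 - mu) * r  # dll/deta
            g[idx["intercept"]] = gscore.sum()
            if beta.size:
                g[idx["linear"]] = X_lin.T @ gscore
            pen_scores = []
            for s, ((s0, sp), lin, pen) in enumerate(zip(idx["smooth"], smooth_lin, smooth_pen)):
                g[s0] = lin @ gscore
                ps = pen.T @ gscore
                pen_scores.append(ps)
                g[sp] = tau_all[s] * ps
            for m, (sl, ind) in enumerate(zip(idx["mono_a"], mono_ind)):
                b = theta[idx["mono_b"]][m]
                zeta, cum = zetas[m], cums[m]
                cvals = ind @ zeta
                g[idx["mono_b"].start + m] = cvals @ gscore
                if sl.stop > sl.start:
                    ind_g = ind.T @ gscore          # (L-1,)
                    cg = cvals @ gscore
                    ga = b * zeta * (ind_g - cg)    # all L-1 components
                    g[sl] = ga[: sl.stop - sl.start]
            g[idx["log_phi"]] = phi * (n * psi(phi)
                                       - (mu * psi_a).sum() - ((1 - mu) * psi_b).sum()
                                       + (mu * log_y).sum() + ((1 - mu) * log1m_y).sum())

            # ---- priors
            lp = ll
            ic = theta[idx["intercept"]]
            nu, s2 = pc.intercept_df, pc.intercept_scale**2
            lp += -0.5 * (nu + 1) * np.log1p(ic * ic / (nu * s2))
            g[idx["intercept"]] += -(nu + 1) * ic / (nu * s2 + ic * ic)
            if beta.size:
                lp += -0.5 * (beta @ beta) / pc.coef_scale**2
                g[idx["linear"]] += -beta / pc.coef_scale**2
            for s, ((s0, sp), gam) in enumerate(zip(idx["smooth"], gammas)):
                # null-space (linear) part of the smooth gets the linear-coef prior
                lp += -0.5 * theta[s0] ** 2 / pc.coef_scale**2
                g[s0] += -theta[s0] / pc.coef_scale**2
                # standard-normal prior on the non-centered coefficients
                lp += -0.5 * (gam @ gam)
                g[sp] += -gam
                gl = tau_all[s] * (gam @ pen_scores[s])
                # half-t prior on tau plus the log-jacobian of tau = exp(log_tau)
                nu_s, A2 = pc.smooth_sd_df, pc.smooth_sd_scale**2
                q = tau_all[s] ** 2 / (nu_s * A2)
                lp += -0.5 * (nu_s + 1) * np.log1p(q) + log_tau_all[s]
                gl += -(nu_s + 1) * q / (1 + q) + 1.0
                g[idx["log_tau"].start + s] = gl
            bvec = theta[idx["mono_b"]]
            if bvec.size:
                lp += -0.5 * (bvec @ bvec) / pc.coef_scale**2
                g[idx["mono_b"]] += -bvec / pc.coef_scale**2
            for m, sl in enumerate(idx["mono_a"]):
                zeta = zetas[m]
                L1 = zeta.size
                lp += pc.dirichlet_conc * np.log(np.clip(zeta, 1e-300, None)).sum()
                if sl.stop > sl.start:
                    g[sl] += pc.dirichlet_conc * (1 - L1 * zeta[: sl.stop - sl.start])
            lp += pc.phi_shape * log_phi - pc.phi_rate * phi
            g[idx["log_phi"]] += pc.phi_shape - pc.phi_rate * phi
            return lp, g

        return logp_grad

    # ---------------------------------------------------------------- fitting
    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(y)) or np.any((y <= 0) | (y >= 1)):
            raise ValueError("response must lie strictly in (0, 1); apply shrink_boundary first")
        self.spec_ = self._resolve_spec()
        self.bases_ = {}
        X_lin, smooth_lin, smooth_pen, mono_levels = self._design(X, training=True)
        self._idx = self._layout()
        logp_grad = self._make_logp_grad(y, X_lin, smooth_lin, smooth_pen, mono_levels)

        init = np.zeros(self._idx["dim"])
        ybar, yvar = float(np.mean(y)), float(np.var(y))
        init[self._idx["intercept"]] = float(logit(ybar))
        phi0 = max(ybar * (1 - ybar) / max(yvar, 1e-8) - 1.0, 2.0)
        init[self._idx["log_phi"]] = float(np.log(phi0))
        init[self._idx["log_tau"]] = np.log(0.5)

        warmup = self.iterations // 2
        res = hmc.sample(logp_grad, init, n_chains=self.chains, n_iter=self.iterations,
                         warmup=warmup, seed=self.seed, target_accept=self.target_accept,
                         sim_length=self.sim_length, max_leapfrog=self.max_leapfrog,
                         jitter=0.2)
        self.theta_draws_ = res.draws  # (chains, kept, dim)
        self.accept_rate_ = res.accept_rate
        self.divergences_ = res.divergences
        self._diagnose()
        flat = res.draws.reshape(-1, res.draws.shape[-1])
        self._flat = flat
        self.phi_draws_ = np.exp(flat[:, self._idx["log_phi"]])
        self._train_design = (X_lin, smooth_lin, smooth_pen, mono_levels)
        mu = self._mu_from_design(flat, *self._train_design)
        self._train_mu_draws = mu
        self.fitted_mean_ = mu.mean(axis=0)
        self.n_obs_ = y.size
        self.y_train_ = y
        return self

    def _diagnose(self):
        import arviz as az
        data = az.convert_to_dataset({"theta": self.theta_draws_})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.theta_draws_.shape[0] >= 2:
                rhat = az.rhat(data)["theta"].to_numpy()
            else:  # split R-hat undefined on a single chain
                rhat = np.full(self.theta_draws_.shape[-1], np.inf)
            ess = az.ess(data, method="bulk")["theta"].to_numpy()
        self.diagnostics_ = {
            "max_rhat": float(np.nanmax(rhat)),
            "min_ess_bulk": float(np.nanmin(ess)),
            "rhat": rhat,
            "ess_bulk": ess,
        }
        self.converged_ = bool(self.diagnostics_["max_rhat"] <= RHAT_MAX
                               and self.diagnostics_["min_ess_bulk"] >= ESS_MIN)
        if not self.converged_:
            logger.warning(
                "MCMC diagnostic failure: max split R-hat %.3f (limit %.2f), "
                "min bulk ESS %.0f (floor %d); increase the sampling budget",
                self.diagnostics_["max_rhat"], RHAT_MAX,
                self.diagnostics_["min_ess_bulk"], ESS_MIN)

    # ------------------------------------------------------------- prediction
    def _mu_from_design(self, flat, X_lin, smooth_lin, smooth_pen, mono_levels):
        idx = self._idx
        n = X_lin.shape[0]
        eta = np.tile(flat[:, idx["intercept"]][:, None], (1, n))
        if X_lin.shape[1]:
            eta += flat[:, idx["linear"]] @ X_lin.T
        for s, ((s0, sp), lin, pen) in enumerate(zip(idx["smooth"], smooth_lin, smooth_pen)):
            tau = np.exp(flat[:, idx["log_tau"]][:, s])
            eta += np.outer(flat[:, s0], lin) + (tau[:, None] * flat[:, sp]) @ pen.T
        for m, sl in enumerate(idx["mono_a"]):
            a = np.concatenate([flat[:, sl], np.zeros((flat.shape[0], 1))], axis=1)
            ez = np.exp(a - a.max(axis=1, keepdims=True))
            zeta = ez / ez.sum(axis=1, keepdims=True)
            cum = np.concatenate([np.zeros((flat.shape[0], 1)), np.cumsum(zeta, axis=1)], axis=1)
            b = flat[:, idx["mono_b"]][:, m]
            eta += b[:, None] * cum[:, mono_levels[m]]
        return expit(eta)

    def mu_draws(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Posterior draws of mu, shape (n_draws, n_subjects)."""
        self._check_fitted()
        if X is None:
            return self._train_mu_draws
        design = self._design(X, training=False)
        return self._mu_from_design(self._flat, *design)

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Posterior mean of mu per subject."""
        if X is None:
            return self.fitted_mean_.copy()
        return self.mu_draws(X).mean(axis=0)

    def predict_fi(self, X: pd.DataFrame | None = None, keep_draws: bool = False) -> PosteriorFI:
        """Posterior mean and equal-tailed 95% credible interval of mu."""
        mu = self.mu_draws(X)
        lo, hi = np.percentile(mu, [2.5, 97.5], axis=0)
        return PosteriorFI(mean=mu.mean(axis=0), lower=lo, upper=hi,
                           draws=mu if keep_draws else None)

    def _check_fitted(self):
        if not hasattr(self, "theta_draws_"):
            raise RuntimeError("model is not fitted")

    # ---------------------------------------------------------- serialization
    def to_json(self, path=None) -> str:
        self._check_fitted()
        spec = self.spec_
        payload = {
            "spec": {"kind": spec.kind, "smooth_terms": list(map(list, spec.smooth_terms)),
                     "monotonic_terms": list(map(list, spec.monotonic_terms)),
                     "linear_terms": list(spec.linear_terms),
                     "prior_config": asdict(spec.prior_config)},
            "params": {"chains": self.chains, "iterations": self.iterations, "seed": self.seed},
            "transform_state": {"means": self.transform_state_.means,
                                "sds": self.transform_state_.sds},
            "draws": self.theta_draws_.tolist(),
            "diagnostics": {"max_rhat": self.diagnostics_["max_rhat"],
                            "min_ess_bulk": self.diagnostics_["min_ess_bulk"],
                            "converged": self.converged_,
                            "divergences": int(self.divergences_)},
            "fitted_mean": self.fitted_mean_.tolist(),
            "y_train": self.y_train_.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classify_model_pfp(pfi: PosteriorFI) -> list[str]:
    """Frailty class from the posterior mean FI, using the FI cut-points."""
    return [classify_fi(min(max(m, 0.0), 1.0)) for m in pfi.mean]


def fit_model(table: pd.DataFrame, spec, response: str = "fi", chains: int = 4,
              iterations: int = 3000, seed: int = 0) -> BetaFrailtyRegressor:
    """Functional wrapper: fit a BetaFrailtyRegressor on a scored table."""
    y = table[response].to_numpy(dtype=float)
    model = BetaFrailtyRegressor(spec=spec, chains=chains, iterations=iterations, seed=seed)
    return model.fit(table, y)


def predict_fi(model: BetaFrailtyRegressor, newdata: pd.DataFrame | None = None,
               keep_draws: bool = False) -> PosteriorFI:
    """Functional wrapper over :meth:`BetaFrailtyRegressor.predict_fi`."""
    return model.predict_fi(newdata, keep_draws=keep_draws)
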