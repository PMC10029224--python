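"""Approximate leave-one-out cross-validation and calibration diagnostics.

PSIS-LOO: for each observation the importance ratios 1/p(y_i | theta^s) are
stabilized by fitting a generalized Pareto distribution (GPD) to the largest
ratios and replacing them with expected order statistics of the fitted tail
(truncated at the raw maximum); the fitted shape k diagnoses reliability
(k > 0.7 flags an untrustworthy observation).  LOO-R² is 1 minus the ratio of
leave-one-out squared prediction error to total response variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .distributions import beta_logpdf

PARETO_K_WARN = 0.7


@dataclass
class LooResult:
    elpd_loo: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    loo_r2: float
    loo_r2_interval: tuple[float, float]
    loo_predicted: np.ndarray

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


@dataclass
class ElpdDiff:
    diff: float
    se: float

    @property
    def decisive(self) -> bool:
        """|diff| greater than twice its SE."""
        return bool(abs(self.diff) > 2.0 * self.se)


def pointwise_loglik(model, table=None, y=None) -> np.ndarray:
    """(draws x n) matrix of log p(y_i | mu_i^(s), phi^(s)).

    ``y`` defaults to the model's training response; boundary values are
    rejected by the beta density (shrink first).
    """
    mu = model.mu_draws(table)
    phi = model.phi_draws_
    if y is None:
        y = model.y_train_
    y = np.asarray(y, dtype=float)
    return beta_logpdf(y[None, :], mu, phi[:, None])


def fit_generalized_pareto(tail, regularize: bool = True) -> tuple[float, float]:
    """Profile-likelihood (quantile-grid) GPD fit to positive exceedances.

    Returns (shape k, scale sigma) in the heavy-tail-positive sign convention.
    The shape is lightly regularized toward 0.5 (10 pseudo-observations)
    unless ``regularize=False``; negligible for large samples, stabilizing
    for the short tails met inside PSIS.
    """
    x = np.sort(np.asarray(tail, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("GPD fit needs at least 5 tail values")
    if x[0] < 0:
        raise ValueError("exceedances must be non-negative")
    if x[-1] <= x[0] or np.ptp(x) < 1e-30 * max(abs(x[-1]), 1.0):
        raise ValueError("degenerate tail: no spread in the exceedances")
    m = 30 + int(np.sqrt(n))
    j = np.arange(1, m + 1)
    xstar = x[int(n / 4 + 0.5) - 1]
    if xstar <= 0:  # ties at zero in the lower quartile
        xstar = x[x > 0][0]
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (3.0 * xstar)
    # profile log-likelihood over the grid of b = -k/sigma values
    with np.errstate(divide="ignore", invalid="ignore"):
        k_b = np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
        prof = n * (np.log(-b / k_b) - k_b - 1.0)
    prof[~np.isfinite(prof)] = -np.inf
    if not np.any(np.isfinite(prof)):
        raise ValueError("degenerate tail: profile likelihood is unbounded")
    w = np.exp(prof - prof[np.isfinite(prof)].max())
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_hat = float(np.mean(np.log1p(-b_post * x)))  # heavy-tail-positive shape
    sigma = float(-k_hat / b_post) if b_post != 0 else float(np.mean(x))
    if regularize:
        k_hat = (n * k_hat + 10 * 0.5) / (n + 10.0)
    return k_hat, sigma


def _gpd_quantile(p, k, sigma):
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def smooth_log_weights(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth one observation's log importance ratios.

    The largest M = min(0.2*S, 3*sqrt(S)) ratios are replaced by expected
    order statistics of the fitted GPD, truncated at the raw maximum; returns
    (unnormalized smoothed log weights, fitted shape k).
    """
    lr = np.asarray(log_ratios, dtype=float)
    S = lr.size
    M = int(min(np.ceil(0.2 * S), np.ceil(3.0 * np.sqrt(S))))
    lw = lr - lr.max()
    if M < 5:
        return lw, 0.0
    order = np.argsort(lw)
    tail_idx = order[-M:]
    cutoff = lw[order[-M - 1]] if S > M else lw.min()
    exc = np.exp(lw[tail_idx]) - np.exp(cutoff)
    if np.ptp(exc) < 1e-30:
        return lw, 0.0
    try:
        k, sigma = fit_generalized_pareto(exc)
    except ValueError:
        return lw, 0.0
    if not (np.isfinite(k) and np.isfinite(sigma) and sigma > 0):
        return lw, 0.0
    probs = (np.arange(1, M + 1) - 0.5) / M
    repl = np.log(_gpd_quantile(probs, k, sigma) + np.exp(cutoff))
    repl = np.minimum(repl, 0.0)  # never exceed the raw maximum (which is 0 after shift)
    smoothed = lw.copy()
    smoothed[tail_idx[np.argsort(lw[tail_idx])]] = repl
    return smoothed, k


def psis_loo(loglik: np.ndarray, mu_draws: np.ndarray | None = None,
             y: np.ndarray | None = None) -> LooResult:
    """PSIS-LOO from a (draws x n) pointwise log-likelihood matrix.

    ``mu_draws`` (same shape) and ``y`` enable the LOO predictive means and
    LOO-R²; without them those fields are NaN.
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be (draws x n)")
    S, n = loglik.shape
    if S < 100:
        raise ValueError("need at least 100 posterior draws for PSIS-LOO")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("log-likelihood matrix contains non-finite entries")
    pointwise = np.empty(n)
    pareto_k = np.empty(n)
    loo_pred = np.full(n, np.nan)
    for i in range(n):
        lw, k = smooth_log_weights(-loglik[:, i])
        pareto_k[i] = k
        lw_norm = lw - logsumexp(lw)
        pointwise[i] = logsumexp(lw_norm + loglik[:, i])
        if mu_draws is not None:
            loo_pred[i] = float(np.exp(lw_norm) @ mu_draws[:, i])
    elpd = float(pointwise.sum())
    se = float(np.std(pointwise, ddof=1) * np.sqrt(n))
    loo_r2, interval = float("nan"), (float("nan"), float("nan"))
    if mu_draws is not None and y is not None:
        y = np.asarray(y, dtype=float)
        err2 = (y - loo_pred) ** 2
        tot2 = (y - y.mean()) ** 2
        loo_r2 = float(1.0 - err2.sum() / tot2.sum())
        # Bayesian-bootstrap interval over the pointwise terms
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(n), size=2000)
        r2_bb = 1.0 - (w @ err2) / (w @ tot2)
        interval = tuple(np.percentile(r2_bb, [2.5, 97.5]))
    return LooResult(elpd, se, pointwise, pareto_k, loo_r2, interval, loo_pred)


def loo_for_model(model, table=None) -> LooResult:
    """Convenience: PSIS-LOO of a fitted beta regression on its training data."""
    ll = pointwise_loglik(model, table)
    return psis_loo(ll, mu_draws=model.mu_draws(table), y=model.y_train_)


def elpd_compare(loo_a: LooResult, loo_b: LooResult) -> ElpdDiff:
    """Paired ELPD difference (a - b) with its pointwise SE."""
    if loo_a.pointwise.size != loo_b.pointwise.size:
        raise ValueError("LOO results cover different numbers of observations")
    d = loo_a.pointwise - loo_b.pointwise
    n = d.size
    return ElpdDiff(float(d.sum()), float(np.std(d, ddof=1) * np.sqrt(n)))


def bayes_r2(model) -> tuple[float, tuple[float, float], np.ndarray]:
    """Posterior distribution of R² for a beta regression.

    Per draw: explained variance var_i(mu_i) over explained plus expected
    residual variance mean_i(mu_i(1-mu_i)/(1+phi)).  Returns (mean, 95% CrI,
    per-draw values).
    """
    mu = model.mu_draws()
    phi = model.phi_draws_
    expl = mu.var(axis=1)
    resid = (mu * (1 - mu) / (1 + phi[:, None])).mean(axis=1)
    r2 = expl / (expl + resid)
    return float(r2.mean()), tuple(np.percentile(r2, [2.5, 97.5])), r2


def calibration_curve(observed, predicted, frac: float = 2.0 / 3.0, it: int = 3,
                      grid: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Lowess calibration curve of observed against predicted values.

    Tricube-weighted local linear smoothing (span ``frac``, ``it`` robustness
    iterations) evaluated on an even grid over the predicted range; plot with
    the identity line to read calibration.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size or observed.size < 20:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 20")
    if np.ptp(predicted) < 1e-12:
        raise ValueError("degenerate (constant) predictions: calibration undefined")
    sm = lowess(observed, predicted, frac=frac, it=it, return_sorted=True)
    gx = np.linspace(predicted.min(), predicted.max(), grid)
    gy = np.interp(gx, sm[:, 0], sm[:, 1])
    return gx, gy
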