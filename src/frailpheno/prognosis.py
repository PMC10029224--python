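"""One-year outcome models: logistic fits, nested LR tests, explained variation.

Falls and hospitalization over one year are modeled by binary logistic
regression with either the count-based PFP score (a count) or the model-based
PFP (the posterior predicted FI, a continuous variable) as predictor,
complete cases only.  Incremental value of the model-based predictor is
summarized by a likelihood-ratio test and by 1 minus the variance ratio of
linear predictors before and after adding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    linpred: np.ndarray
    fitted: np.ndarray
    n: int
    converged: bool
    separation: bool


def fit_logistic(y, X, names=None) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS) with an intercept.

    ``X`` is the predictor matrix without the constant column.  Complete
    cases only; perfect separation is flagged, not silently returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(np.isnan(y)) or np.any(np.isnan(X)):
        raise ValueError("missing values: restrict to complete cases first")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    linpred = design @ res.params
    fitted = res.fittedvalues
    separation = bool(np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10)
                      or np.any(np.abs(res.params) > 30))
    return LogisticFit(
        names=["const"] + list(names),
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        loglik=float(res.llf),
        linpred=np.asarray(linpred),
        fitted=np.asarray(fitted),
        n=int(y.size),
        converged=bool(res.converged),
        separation=separation,
    )


def lr_test(reduced: LogisticFit, full: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of nested logistic models."""
    if reduced.n != full.n:
        raise ValueError("models fitted on different numbers of subjects")
    if not set(reduced.names) <= set(full.names):
        raise ValueError("reduced model's predictors are not a subset of the full model's")
    df = len(full.names) - len(reduced.names)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def explained_fraction(fit_before: LogisticFit, fit_both: LogisticFit) -> float:
    """1 - var(linear predictor before) / var(linear predictor after).

    The share of the full model's prognostic information attributable to the
    added predictor; 0 when nothing is added, 1 when the before-model is
    intercept-only.
    """
    if fit_before.n != fit_both.n:
        raise ValueError("fits cover different subjects")
    v_full = float(np.var(fit_both.linpred))
    if v_full <= 1e-14:
        raise ValueError("full model's linear predictor has zero variance")
    v_before = float(np.var(fit_before.linpred))
    return float(np.clip(1.0 - v_before / v_full, 0.0, 1.0))
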