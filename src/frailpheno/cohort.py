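"""Synthetic cohorts of community-dwelling older adults.

A single scalar latent frailty factor z ~ N(0,1) per subject drives
(a) the continuous PFP criterion measures through linear loadings plus
Gaussian noise (gait speed and grip strength fall with frailty, the CES-D
exhaustion items rise through an ordered-logit link), (b) each of the 36
frailty-index deficit items through Bernoulli(logistic(intercept + slope*z)),
and (c) the one-year outcomes through Bernoulli(logistic(intercept +
slope*FI)).  Deficit intercepts are solved from target marginal prevalences
by Gauss-Hermite inversion, so the population mean FI equals the mean of the
configured prevalences by construction.  Missingness is injected completely
at random at per-variable rates; follow-up outcomes are jointly missing for
a random subset of subjects (loss to follow-up independent of baseline).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .scoring import DEFICIT_COLUMNS, N_DEFICITS

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(60)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)

PREDICTOR_COLUMNS = ("age", "gait_speed", "grip_strength", "weight", "height",
                     "walk_time", "cesd_q1", "cesd_q2")


def _marginal_expit(c, slope):
    """E_z[expit(c + slope*z)] for z ~ N(0,1), by Gauss-Hermite quadrature."""
    return float(_GH_WEIGHTS @ expit(c + slope * _GH_NODES))


def _solve_intercept(target, slope):
    """Intercept c with E_z[expit(c + slope*z)] = target."""
    return brentq(lambda c: _marginal_expit(c, slope) - target, -25.0, 25.0, xtol=1e-10)


@dataclass
class CohortParams:
    """Generative parameters; defaults reproduce the study-population marginals."""

    n_participants: int = 998
    prop_women: float = 0.74
    age_mean_sd: tuple = (67.6, 7.0)
    weight_mean_sd: tuple = (60.0, 11.0)     # within-sex SD; men/women differ by weight_sex_diff
    height_mean_sd: tuple = (1.56, 0.055)
    gait_mean_sd: tuple = (1.32, 0.25)       # m/s
    grip_mean_sd: tuple = (27.0, 5.0)        # kg, within-sex
    walk_cbrt_mean_sd: tuple = (1.65, 0.45)  # cube-root h/week scale
    weight_sex_diff: float = 9.0             # men minus women, kg
    height_sex_diff: float = 0.11            # m
    grip_sex_diff: float = 12.0              # kg
    #: correlation-scale loadings of the latent frailty factor on each measure
    latent_frailty_loadings: dict = field(default_factory=lambda: {
        "age": 0.35, "gait_speed": -0.65, "grip_strength": -0.5,
        "weight": -0.15, "height": -0.05, "walk_cbrt": -0.4, "cesd": 0.9,
    })
    #: target marginal prevalence of each deficit item (mean = population mean FI)
    deficit_base_probs: tuple = tuple(np.linspace(0.02, 0.20, N_DEFICITS).round(6))
    #: logit-scale slopes of each deficit on the latent factor
    deficit_frailty_slopes: tuple = tuple(np.linspace(0.4, 0.8, N_DEFICITS).round(6))
    #: cumulative P(level >= k), k = 1..3, for each CES-D item
    cesd_cum_probs: tuple = (0.18, 0.07, 0.025)
    #: logit-scale (intercept, slope on FI) per outcome
    outcome_intercepts_slopes: dict = field(default_factory=lambda: {
        "fall_1y": (-2.20, 3.5), "hosp_1y": (-2.49, 4.5),
    })
    #: MCAR missingness per variable; deficit items share the 'deficits' rate
    missing_rates: dict = field(default_factory=lambda: {
        "gait_speed": 0.005, "grip_strength": 0.008, "weight": 0.002,
        "height": 0.002, "walk_time": 0.015, "cesd_q1": 0.010,
        "cesd_q2": 0.010, "deficits": 0.003,
    })
    followup_rate: float = 0.56
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("prop_women", "followup_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v!r}")
        if len(self.deficit_base_probs) != N_DEFICITS:
            raise ValueError(f"deficit_base_probs must have {N_DEFICITS} entries")
        if len(self.deficit_frailty_slopes) != N_DEFICITS:
            raise ValueError(f"deficit_frailty_slopes must have {N_DEFICITS} entries")
        if np.any(~((np.asarray(self.deficit_base_probs) > 0)
                    & (np.asarray(self.deficit_base_probs) < 1))):
            raise ValueError("deficit_base_probs entries must lie in (0, 1)")
        if np.any(np.asarray(self.deficit_frailty_slopes) < 0):
            raise ValueError("deficit_frailty_slopes must be non-negative")
        for k, v in self.missing_rates.items():
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(f"missing_rates[{k!r}] must be a fraction in [0, 1]")
        for pair_name in ("age_mean_sd", "weight_mean_sd", "height_mean_sd",
                          "gait_mean_sd", "grip_mean_sd", "walk_cbrt_mean_sd"):
            m, s = getattr(self, pair_name)
            if not np.isfinite(m) or not np.isfinite(s) or s <= 0:
                raise ValueError(f"{pair_name} must be finite with positive SD")
        for k, (a, b) in self.outcome_intercepts_slopes.items():
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"outcome_intercepts_slopes[{k!r}] must be finite")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else o)


def default_params(seed: int = 0, **overrides) -> CohortParams:
    """Parameters matching the study population's printed marginals.

    74% women; age 67.6 (7) years; weight 60 (12) kg overall; height 1.56
    (0.08) m; mean FI 0.11; 1-year falls/hospitalization incidence 14%/12%
    among completers; predictor missingness between 0.2% and 1.5%; 56%
    follow-up completion.
    """
    p = CohortParams(seed=seed, **overrides)
    p.validate()
    return p


def _loaded_normal(rng, n, z, mean, sd, loading):
    """mean + sd * (loading*z + sqrt(1-loading^2)*noise): marginal N(mean, sd)."""
    lam = float(np.clip(loading, -1.0, 1.0))
    return mean + sd * (lam * z + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n))


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate one participant-level table (one row per subject)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    z = rng.standard_normal(n)
    load = params.latent_frailty_loadings

    sex = np.where(rng.random(n) < params.prop_women, "woman", "man")
    men = sex == "man"

    age = _loaded_normal(rng, n, z, *params.age_mean_sd, load.get("age", 0.0))
    gait = _loaded_normal(rng, n, z, *params.gait_mean_sd, load.get("gait_speed", 0.0))
    gait = np.clip(gait, 0.1, None)

    grip_base = _loaded_normal(rng, n, z, 0.0, params.grip_mean_sd[1],
                               load.get("grip_strength", 0.0))
    women_mean = params.grip_mean_sd[0] - (1 - params.prop_women) * params.grip_sex_diff
    grip = women_mean + np.where(men, params.grip_sex_diff, 0.0) + grip_base
    grip = np.clip(grip, 2.0, None)

    w_women = params.weight_mean_sd[0] - (1 - params.prop_women) * params.weight_sex_diff
    weight = (w_women + np.where(men, params.weight_sex_diff, 0.0)
              + _loaded_normal(rng, n, z, 0.0, params.weight_mean_sd[1],
                               load.get("weight", 0.0)))
    weight = np.clip(weight, 30.0, None)

    h_women = params.height_mean_sd[0] - (1 - params.prop_women) * params.height_sex_diff
    height = (h_women + np.where(men, params.height_sex_diff, 0.0)
              + _loaded_normal(rng, n, z, 0.0, params.height_mean_sd[1],
                               load.get("height", 0.0)))
    height = np.clip(height, 1.3, 2.1)

    walk_cbrt = _loaded_normal(rng, n, z, *params.walk_cbrt_mean_sd,
                               load.get("walk_cbrt", 0.0))
    walk = np.clip(walk_cbrt, 0.0, None) ** 3

    # CES-D items: ordered logit on the latent factor with solved thresholds
    s_cesd = load.get("cesd", 0.0)
    # P(level >= k) = E_z[expit(s*z - t_k)] = target  =>  t_k = -intercept
    thresholds = [-_solve_intercept(c, s_cesd) for c in params.cesd_cum_probs]
    cesd = np.zeros((n, 2), dtype=float)
    for q in range(2):
        u = s_cesd * z + rng.logistic(size=n)
        lev = np.zeros(n, dtype=float)
        for t in thresholds:
            lev += (u > t)
        cesd[:, q] = lev

    # deficit items
    slopes = np.asarray(params.deficit_frailty_slopes, dtype=float)
    intercepts = np.array([_solve_intercept(p, s)
                           for p, s in zip(params.deficit_base_probs, slopes)])
    p_items = expit(intercepts[None, :] + slopes[None, :] * z[:, None])
    deficits = (rng.random((n, N_DEFICITS)) < p_items).astype(float)
    fi_true = deficits.mean(axis=1)

    outcomes = {}
    for name, (a, b) in params.outcome_intercepts_slopes.items():
        outcomes[name] = (rng.random(n) < expit(a + b * fi_true)).astype(float)

    table = pd.DataFrame({
        "id": [f"S{i + 1:04d}" for i in range(n)],
        "sex": sex, "age": age, "gait_speed": gait, "grip_strength": grip,
        "weight": weight, "height": height, "walk_time": walk,
        "cesd_q1": cesd[:, 0], "cesd_q2": cesd[:, 1],
    })
    for j, col in enumerate(DEFICIT_COLUMNS):
        table[col] = deficits[:, j]
    for name in params.outcome_intercepts_slopes:
        table[name] = outcomes[name]

    # MCAR missingness
    for var, rate in params.missing_rates.items():
        if rate <= 0:
            continue
        if var == "deficits":
            mask = rng.random((n, N_DEFICITS)) < rate
            block = table[DEFICIT_COLUMNS].to_numpy()
            block[mask] = np.nan
            table[DEFICIT_COLUMNS] = block
        elif var in table.columns:
            mask = rng.random(n) < rate
            table.loc[mask, var] = np.nan
    # loss to follow-up: both outcomes jointly missing
    lost = rng.random(n) >= params.followup_rate
    for name in params.outcome_intercepts_slopes:
        table.loc[lost, name] = np.nan
    return table


def write_cohort(table: pd.DataFrame, path, params: CohortParams | None = None) -> None:
    """CSV with a header row, empty fields for missing; sidecar JSON for params."""
    table.to_csv(path, index=False, na_rep="")
    if params is not None:
        sidecar = str(path) + ".params.json"
        with open(sidecar, "w") as fh:
            fh.write(params.to_json())


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
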