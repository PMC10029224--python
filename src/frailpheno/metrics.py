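"""Agreement, discrimination and reclassification statistics.

Quadratic weighted kappa (with the Fleiss-Cohen-Everitt large-sample SE),
AUROC with the DeLong placement-value variance, the DeLong test for two
correlated AUROCs, and the categorical net reclassification improvement with
event / non-event decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]


@dataclass
class AurocResult:
    auc: float
    variance: float
    ci: tuple[float, float]


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    diff: float
    se: float
    z: float
    p: float
    ci: tuple[float, float]


@dataclass
class NriResult:
    event_nri: float
    nonevent_nri: float
    overall_nri: float
    event_up: int
    event_down: int
    n_events: int
    nonevent_up: int
    nonevent_down: int
    n_nonevents: int
    event_ci: tuple[float, float]
    nonevent_ci: tuple[float, float]
    overall_ci: tuple[float, float]


def confusion_table(labels_a, labels_b, categories) -> np.ndarray:
    """K x K cross-tabulation of two ordinal classifications (rows = a)."""
    cat = list(categories)
    a = pd.Categorical(labels_a, categories=cat)
    b = pd.Categorical(labels_b, categories=cat)
    if a.isna().any() or b.isna().any():
        raise ValueError("labels outside the declared categories")
    K = len(cat)
    table = np.zeros((K, K), dtype=int)
    np.add.at(table, (a.codes, b.codes), 1)
    return table


def weighted_kappa(table, weighting: str = "quadratic", alpha: float = 0.05) -> KappaResult:
    """Cohen's weighted kappa with large-sample SE and normal CI.

    Quadratic weights w_ij = 1 - (i-j)^2/(K-1)^2 reward near agreement on the
    ordinal scale; linear weights use |i-j| instead.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise ValueError("confusion table must be square, K >= 2")
    n = t.sum()
    if n < 2:
        raise ValueError("confusion table is empty")
    K = t.shape[0]
    i, j = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    if weighting == "quadratic":
        w = 1.0 - (i - j) ** 2 / (K - 1) ** 2
    elif weighting == "linear":
        w = 1.0 - np.abs(i - j) / (K - 1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    p = t / n
    pr, pc = p.sum(axis=1), p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pr, pc)).sum())
    if abs(1.0 - pe) < 1e-12:
        raise ValueError("chance-expected weighted agreement is 1: kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance (non-null)
    wbar_r = w @ pc          # row-conditional expected weight
    wbar_c = w.T @ pr
    term = (w * (1 - pe) - (wbar_r[:, None] + wbar_c[None, :]) * (1 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    zq = stats.norm.ppf(1 - alpha / 2)
    return KappaResult(float(kappa), se, (kappa - zq * se, kappa + zq * se))


def _placements(y, score):
    """DeLong structural components (placement values) and the AUC."""
    y = np.asarray(y).astype(int)
    score = np.asarray(score, dtype=float)
    pos, neg = score[y == 1], score[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    # V10[i]: fraction of negatives below positive i (ties count 1/2)
    order = np.argsort(neg)
    neg_sorted = neg[order]
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size
    pos_sorted = np.sort(pos)
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / pos.size
    auc = float(v10.mean())
    return auc, v10, v01


def auroc(y, score, alpha: float = 0.05) -> AurocResult:
    """AUROC (Mann-Whitney, ties half-weighted) with the DeLong variance."""
    auc, v10, v01 = _placements(y, score)
    var = (np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)
    zq = stats.norm.ppf(1 - alpha / 2)
    hw = zq * np.sqrt(var)
    return AurocResult(auc, float(var), (auc - hw, auc + hw))


def delong_test(y, score_a, score_b, alpha: float = 0.05) -> DelongResult:
    """DeLong comparison of two correlated AUROCs on the same subjects."""
    y = np.asarray(y).astype(int)
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    if not (y.size == score_a.size == score_b.size):
        raise ValueError("scores must be paired on the same subjects")
    auc_a, v10a, v01a = _placements(y, score_a)
    auc_b, v10b, v01b = _placements(y, score_b)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    se = float(np.sqrt(max(var_diff, 0.0)))
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = diff / se
        p = 2 * stats.norm.sf(abs(z))
    zq = stats.norm.ppf(1 - alpha / 2)
    return DelongResult(auc_a, auc_b, float(diff), se, float(z), float(p),
                        (diff - zq * se, diff + zq * se))


def categorical_nri(event, class_old, class_new, alpha: float = 0.05) -> NriResult:
    """Categorical net reclassification improvement between two classifiers.

    ``class_old`` / ``class_new`` are per-subject binary indicators (1 = the
    high-risk category, e.g. predicted prefrail/frail); ``event`` is the
    reference condition (e.g. FI-defined prefrailty/frailty).  Up-classified
    means moving from 0 to 1 between old and new.
    """
    event = np.asarray(event).astype(int)
    old = np.asarray(class_old).astype(int)
    new = np.asarray(class_new).astype(int)
    if not (event.size == old.size == new.size):
        raise ValueError("event, class_old and class_new must be equal length")
    up = (new > old)
    down = (new < old)
    ev, nev = event == 1, event == 0
    n_e, n_ne = int(ev.sum()), int(nev.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("need both events and non-events")
    e_up, e_down = int(np.sum(up & ev)), int(np.sum(down & ev))
    ne_up, ne_down = int(np.sum(up & nev)), int(np.sum(down & nev))
    nri_e = (e_up - e_down) / n_e
    nri_ne = (ne_down - ne_up) / n_ne
    overall = nri_e + nri_ne
    # Pencina-type asymptotic SEs
    pe_u, pe_d = e_up / n_e, e_down / n_e
    pn_u, pn_d = ne_up / n_ne, ne_down / n_ne
    se_e = np.sqrt(max(pe_u + pe_d - (pe_u - pe_d) ** 2, 0.0) / n_e)
    se_ne = np.sqrt(max(pn_u + pn_d - (pn_d - pn_u) ** 2, 0.0) / n_ne)
    se_o = np.sqrt(se_e**2 + se_ne**2)
    zq = stats.norm.ppf(1 - alpha / 2)
    return NriResult(
        float(nri_e), float(nri_ne), float(overall),
        e_up, e_down, n_e, ne_up, ne_down, n_ne,
        (nri_e - zq * se_e, nri_e + zq * se_e),
        (nri_ne - zq * se_ne, nri_ne + zq * se_ne),
        (overall - zq * se_o, overall + zq * se_o),
    )
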