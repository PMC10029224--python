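"""End-to-end study pipeline: simulate/load -> impute -> score -> fit ->
validate -> compare -> prognosis -> report.

The report mirrors the usual model-performance table: per model the Bayes R²
and LOO-R² with intervals, the pairwise ELPD difference against the
best-performing model with its SE, quadratic weighted kappa against the
FI-defined classes, AUROC for FI-defined prefrailty/frailty, and the NRI of
the model-based over the count-based PFP; plus one-year falls and
hospitalization logistic comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, prognosis, validation
from .cohort import default_params, generate_cohort, read_cohort
from .distributions import shrink_boundary
from .model import BetaFrailtyRegressor, classify_model_pfp
from .preprocess import impute_single
from .scoring import CLASSES, FI_ROBUST_MAX, classify_fi, score_table

logger = logging.getLogger(__name__)

MODEL_KINDS = ("referent", "gait_speed", "full_pfp")


@dataclass
class RunConfig:
    seed: int = 0
    input: str | None = None       # CSV path; None -> simulate
    n_participants: int = 998
    models: tuple = MODEL_KINDS
    chains: int = 4
    iterations: int = 1000         # quick default; the full study budget is 3000
    outdir: str | None = None
    plot: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self),
                          default=lambda o: list(o) if isinstance(o, tuple) else o)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def prepare_table(config: RunConfig) -> pd.DataFrame:
    """Simulate or load, restrict to non-missing FI, impute, score."""
    if config.input is None:
        params = default_params(seed=config.seed, n_participants=config.n_participants)
        raw = generate_cohort(params)
    else:
        raw = read_cohort(config.input)
    scored0 = score_table(impute_single(raw, seed=config.seed))
    n0 = len(scored0)
    scored = scored0[np.isfinite(scored0["fi"].to_numpy(dtype=float))].reset_index(drop=True)
    logger.info("cohort: %d rows, %d dropped for missing FI", n0, n0 - len(scored))
    return scored


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable report."""
    stage = "prepare"
    report: dict = {"config": json.loads(config.to_json())}
    try:
        scored = prepare_table(config)
        n = len(scored)
        y = shrink_boundary(scored["fi"].to_numpy(dtype=float), n)
        fi_class = [classify_fi(v) for v in scored["fi"]]
        event = (scored["fi"].to_numpy(dtype=float) > FI_ROBUST_MAX).astype(int)

        stage = "fit"
        fits: dict[str, BetaFrailtyRegressor] = {}
        for kind in config.models:
            logger.info("fitting %s model (%d chains x %d iterations)",
                        kind, config.chains, config.iterations)
            m = BetaFrailtyRegressor(spec=kind, chains=config.chains,
                                     iterations=config.iterations, seed=config.seed)
            m.fit(scored, y)
            fits[kind] = m
            logger.info("%s: max R-hat %.3f, min ESS %.0f, converged=%s",
                        kind, m.diagnostics_["max_rhat"],
                        m.diagnostics_["min_ess_bulk"], m.converged_)

        stage = "validate"
        loos = {k: validation.loo_for_model(m) for k, m in fits.items()}
        best = max(loos, key=lambda k: loos[k].elpd_loo)
        perf = {}
        for kind, m in fits.items():
            r2_mean, r2_ci, _ = validation.bayes_r2(m)
            diff = validation.elpd_compare(loos[kind], loos[best])
            perf[kind] = {
                "r2": r2_mean, "r2_ci": list(r2_ci),
                "loo_r2": loos[kind].loo_r2,
                "loo_r2_ci": list(loos[kind].loo_r2_interval),
                "elpd_loo": loos[kind].elpd_loo,
                "elpd_diff": diff.diff, "elpd_diff_se": diff.se,
                "max_pareto_k": float(np.max(loos[kind].pareto_k)),
                "n_pareto_k_high": loos[kind].n_high_k,
                "max_rhat": fits[kind].diagnostics_["max_rhat"],
                "min_ess_bulk": fits[kind].diagnostics_["min_ess_bulk"],
                "converged": fits[kind].converged_,
            }
        report["best_model"] = best
        report["model_performance"] = perf

        stage = "compare"
        preds = {k: m.predict() for k, m in fits.items()}
        scores = {k: preds[k] for k in fits}
        scores["count_pfp"] = scored["pfp_count"].to_numpy(dtype=float)
        classes = {k: classify_model_pfp(fits[k].predict_fi()) for k in fits}
        classes["count_pfp"] = list(scored["pfp_class"])
        comp = {}
        for name in list(fits) + ["count_pfp"]:
            tab = metrics.confusion_table(fi_class, classes[name], CLASSES)
            kap = metrics.weighted_kappa(tab)
            auc = metrics.auroc(event, scores[name])
            comp[name] = {"kappa": kap.kappa, "kappa_ci": list(kap.ci),
                          "auroc": auc.auc, "auroc_ci": list(auc.ci)}
        if "full_pfp" in fits:
            dl = metrics.delong_test(event, scores["full_pfp"], scores["count_pfp"])
            comp["delong_full_vs_count"] = {"diff": dl.diff, "z": dl.z, "p": dl.p}
            old = (scored["pfp_count"].to_numpy() >= 1).astype(int)
            new = (preds["full_pfp"] > FI_ROBUST_MAX).astype(int)
            nri = metrics.categorical_nri(event, old, new)
            comp["nri_full_vs_count"] = {
                "event_nri": nri.event_nri, "event_ci": list(nri.event_ci),
                "nonevent_nri": nri.nonevent_nri, "nonevent_ci": list(nri.nonevent_ci),
                "overall_nri": nri.overall_nri, "overall_ci": list(nri.overall_ci),
                "event_up": nri.event_up, "event_down": nri.event_down,
                "n_events": nri.n_events, "nonevent_up": nri.nonevent_up,
                "nonevent_down": nri.nonevent_down, "n_nonevents": nri.n_nonevents,
            }
        report["classification"] = comp

        stage = "calibration"
        if "full_pfp" in fits:
            gx, gy = validation.calibration_curve(scored["fi"].to_numpy(dtype=float),
                                                  preds["full_pfp"])
            report["calibration_full_pfp"] = {"predicted": gx.tolist(),
                                              "smoothed_observed": gy.tolist()}

        stage = "prognosis"
        prog = {}
        if "full_pfp" in fits:
            for outcome in ("fall_1y", "hosp_1y"):
                if outcome not in scored.columns:
                    continue
                yv = scored[outcome].to_numpy(dtype=float)
                keep = np.isfinite(yv)
                yo = yv[keep]
                count = scored["pfp_count"].to_numpy(dtype=float)[keep]
                modelp = preds["full_pfp"][keep]
                f_count = prognosis.fit_logistic(yo, count, ["pfp_count"])
                f_model = prognosis.fit_logistic(yo, modelp, ["model_pfp"])
                f_both = prognosis.fit_logistic(
                    yo, np.column_stack([count, modelp]), ["pfp_count", "model_pfp"])
                chi2, df, p = prognosis.lr_test(f_count, f_both)
                dl = metrics.delong_test(yo, f_model.fitted, f_count.fitted)
                prog[outcome] = {
                    "n": int(keep.sum()),
                    "incidence": float(yo.mean()),
                    "auc_count": dl.auc_b, "auc_model": dl.auc_a, "delong_p": dl.p,
                    "lr_chi2": chi2, "lr_df": df, "lr_p": p,
                    "explained_fraction_model": prognosis.explained_fraction(f_count, f_both),
                }
        report["prognosis"] = prog
        report["n"] = n
    except Exception as err:  # pragma: no cover - stage bookkeeping
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if config.outdir is not None:
        persist_report(report, config)
    return report


def format_report(report: dict) -> str:
    """Human-readable table mirroring the model-performance layout."""
    lines = ["Model performance and classification accuracy", "=" * 56]
    perf = report.get("model_performance", {})
    for kind in MODEL_KINDS:
        if kind not in perf:
            continue
        p = perf[kind]
        lines.append(f"[{kind}]")
        lines.append(f"  R2              {p['r2']:.2f} ({p['r2_ci'][0]:.2f} to {p['r2_ci'][1]:.2f})")
        lines.append(f"  LOO-R2          {p['loo_r2']:.2f} "
                     f"({p['loo_r2_ci'][0]:.2f} to {p['loo_r2_ci'][1]:.2f})")
        lines.append(f"  ELPD_diff (SE)  {p['elpd_diff']:.1f} ({p['elpd_diff_se']:.1f})")
        comp = report.get("classification", {}).get(kind)
        if comp:
            lines.append(f"  kappa_w         {comp['kappa']:.2f}")
            lines.append(f"  AUROC           {comp['auroc']:.2f}")
    comp = report.get("classification", {})
    if "count_pfp" in comp:
        lines.append("[count_pfp]")
        lines.append(f"  kappa_w         {comp['count_pfp']['kappa']:.2f}")
        lines.append(f"  AUROC           {comp['count_pfp']['auroc']:.2f}")
    nri = comp.get("nri_full_vs_count")
    if nri:
        lines.append("[NRI model-based vs count-based]")
        for key in ("event_nri", "nonevent_nri", "overall_nri"):
            lines.append(f"  {key:<15} {nri[key]:+.2f}")
    for outcome, p in report.get("prognosis", {}).items():
        lines.append(f"[{outcome}] AUC model {p['auc_model']:.2f} vs count {p['auc_count']:.2f}; "
                     f"LR chi2={p['lr_chi2']:.1f} (p={p['lr_p']:.3g}); "
                     f"explained fraction {p['explained_fraction_model']:.2f}")
    return "\n".join(lines)


def persist_report(report: dict, config: RunConfig) -> None:
    import pathlib

    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(format_report(report) + "\n")
    (out / "config.json").write_text(config.to_json())
    if config.plot and "calibration_full_pfp" in report:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cal = report["calibration_full_pfp"]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(cal["predicted"], cal["smoothed_observed"], "b--", label="lowess")
        lim = [min(cal["predicted"]), max(cal["predicted"])]
        ax.plot(lim, lim, "k-", lw=1, label="identity")
        ax.set_xlabel("Predicted FI")
        ax.set_ylabel("Observed FI (smoothed)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "calibration.svg")
        plt.close(fig)
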