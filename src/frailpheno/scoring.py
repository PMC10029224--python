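"""Frailty index and count-based physical frailty phenotype scoring.

The frailty index (FI) is the deficit-accumulation measure: the proportion of
health deficits present out of a fixed 36-item list, each item scored in
[0, 1].  The count-based physical frailty phenotype (PFP) dichotomizes five
criterion measures (slowness, weakness, shrinking, low physical activity,
exhaustion) and sums the flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_DEFICITS = 36
#: minimum number of observed items for a valid FI (standard deficit-accumulation practice)
MIN_ITEMS = 30

#: FI class cut-points: robust <= 0.10 < prefrail <= 0.21 < frail
FI_ROBUST_MAX = 0.10
FI_PREFRAIL_MAX = 0.21

GAIT_SLOW_CUTPOINT = 1.0  # m/s
GRIP_WEAK_MEN = 28.0  # kg
GRIP_WEAK_WOMEN = 18.0  # kg
BMI_SHRINKING = 18.5  # kg/m^2, boundary inclusive by default
WALK_LOW_ACTIVITY = 2.0  # h/week
CESD_EXHAUSTION_LEVEL = 2  # "a moderate amount of the time" on a 0-3 scale

CLASSES = ("robust", "prefrail", "frail")

DEFICIT_COLUMNS = [f"deficit_{i:02d}" for i in range(1, N_DEFICITS + 1)]


@dataclass
class FrailtyAssessment:
    """One subject's frailty scores under both operational definitions."""

    fi: float | None
    fi_class: str | None
    slowness: int
    weakness: int
    shrinking: int
    low_activity: int
    exhaustion: int
    pfp_count: int
    pfp_class: str
    bmi: float

    @property
    def criteria(self) -> tuple[int, int, int, int, int]:
        return (self.slowness, self.weakness, self.shrinking, self.low_activity, self.exhaustion)


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) over squared height (m)."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(~np.isfinite(weight) | (weight <= 0)):
        raise ValueError("weight must be positive and finite")
    if np.any(~np.isfinite(height) | (height <= 0)):
        raise ValueError("height must be positive and finite")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def compute_fi(deficits, min_items: int = MIN_ITEMS) -> float:
    """Frailty index: sum of observed item scores over the number observed.

    Parameters
    ----------
    deficits : array-like, length 36
        Item scores in [0, 1]; NaN marks a missing item.
    min_items : int
        Fewer observed items than this yields a missing FI (NaN).
    """
    x = np.asarray(deficits, dtype=float)
    if x.shape != (N_DEFICITS,):
        raise ValueError(f"expected {N_DEFICITS} deficit items, got shape {x.shape}")
    obs = ~np.isnan(x)
    if np.any((x[obs] < 0) | (x[obs] > 1)):
        raise ValueError("deficit item scores must lie in [0, 1]")
    if obs.sum() < min_items:
        return float("nan")
    return float(x[obs].sum() / obs.sum())


def classify_fi(fi: float) -> str:
    """Map an FI value to robust (<=0.10), prefrail (>0.10-0.21) or frail (>0.21)."""
    if not np.isfinite(fi) or fi < 0 or fi > 1:
        raise ValueError(f"fi must lie in [0, 1], got {fi!r}")
    if fi <= FI_ROBUST_MAX:
        return "robust"
    if fi <= FI_PREFRAIL_MAX:
        return "prefrail"
    return "frail"


def classify_pfp_count(count: int) -> str:
    """Count-based PFP classes: robust (0), prefrail (1-2), frail (3-5)."""
    if count not in range(6):
        raise ValueError(f"pfp_count must be an integer in 0..5, got {count!r}")
    if count == 0:
        return "robust"
    if count <= 2:
        return "prefrail"
    return "frail"


def _require(value, name: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"missing criterion input: {name} (impute before scoring)")
    return float(value)


def score_count_pfp(
    *,
    sex: str,
    gait_speed: float,
    grip_strength: float,
    weight: float,
    height: float,
    walk_time: float,
    cesd_q1: float,
    cesd_q2: float,
    deficits=None,
    strict_shrinking: bool = False,
) -> FrailtyAssessment:
    """Score the five dichotomized PFP criteria for one participant.

    Cut-points: gait speed < 1.0 m/s (slowness); grip < 28 kg men / < 18 kg
    women (weakness); BMI <= 18.5 kg/m^2 (shrinking; ``strict_shrinking``
    switches to a strict inequality); walking < 2 h/week (low activity);
    either CES-D item answered at level >= 2 (exhaustion).
    """
    if sex not in ("woman", "man"):
        raise ValueError(f"sex must be 'woman' or 'man', got {sex!r}")
    gait_speed = _require(gait_speed, "gait_speed")
    grip_strength = _require(grip_strength, "grip_strength")
    weight = _require(weight, "weight")
    height = _require(height, "height")
    walk_time = _require(walk_time, "walk_time")
    cesd_q1 = _require(cesd_q1, "cesd_q1")
    cesd_q2 = _require(cesd_q2, "cesd_q2")

    bmi = compute_bmi(weight, height)
    slowness = int(gait_speed < GAIT_SLOW_CUTPOINT)
    grip_cut = GRIP_WEAK_MEN if sex == "man" else GRIP_WEAK_WOMEN
    weakness = int(grip_strength < grip_cut)
    shrinking = int(bmi < BMI_SHRINKING if strict_shrinking else bmi <= BMI_SHRINKING)
    low_activity = int(walk_time < WALK_LOW_ACTIVITY)
    exhaustion = int(cesd_q1 >= CESD_EXHAUSTION_LEVEL or cesd_q2 >= CESD_EXHAUSTION_LEVEL)
    count = slowness + weakness + shrinking + low_activity + exhaustion

    fi = fi_class = None
    if deficits is not None:
        fi = compute_fi(deficits)
        fi_class = classify_fi(fi) if np.isfinite(fi) else None
        if not np.isfinite(fi):
            fi = None

    return FrailtyAssessment(
        fi=fi,
        fi_class=fi_class,
        slowness=slowness,
        weakness=weakness,
        shrinking=shrinking,
        low_activity=low_activity,
        exhaustion=exhaustion,
        pfp_count=count,
        pfp_class=classify_pfp_count(count),
        bmi=bmi,
    )


def score_table(table: pd.DataFrame, strict_shrinking: bool = False) -> pd.DataFrame:
    """Append fi, fi_class, bmi, the five flags, pfp_count and pfp_class.

    Rows must have non-missing criterion inputs (run imputation first); the
    deficit columns may contain missing items, handled by the FI rule.
    """
    out = table.copy()
    n = len(out)
    fi = np.full(n, np.nan)
    has_deficits = all(c in out.columns for c in DEFICIT_COLUMNS)
    if has_deficits:
        deficits = out[DEFICIT_COLUMNS].to_numpy(dtype=float)
        for i in range(n):
            fi[i] = compute_fi(deficits[i])
    cols = {k: np.zeros(n, dtype=int) for k in
            ("slowness", "weakness", "shrinking", "low_activity", "exhaustion", "pfp_count")}
    bmi = np.full(n, np.nan)
    pfp_class = np.empty(n, dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        a = score_count_pfp(
            sex=row.sex, gait_speed=row.gait_speed, grip_strength=row.grip_strength,
            weight=row.weight, height=row.height, walk_time=row.walk_time,
            cesd_q1=row.cesd_q1, cesd_q2=row.cesd_q2, strict_shrinking=strict_shrinking,
        )
        for k in ("slowness", "weakness", "shrinking", "low_activity", "exhaustion", "pfp_count"):
            cols[k][i] = getattr(a, k)
        bmi[i] = a.bmi
        pfp_class[i] = a.pfp_class
    if has_deficits:
        out["fi"] = fi
        out["fi_class"] = [classify_fi(v) if np.isfinite(v) else "" for v in fi]
    out["bmi"] = bmi
    for k, v in cols.items():
        out[k] = v
    out["pfp_class"] = pfp_class
    return out
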