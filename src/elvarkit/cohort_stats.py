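"""ROC cutoff selection and Kaplan-Meier stratification for ELVAR cohorts.

A lower effective-ventilation ratio means more interstitial involvement,
so for outcome prediction *low* scores indicate the positive (event)
class; :func:`roc_analysis` therefore takes an explicit direction.  The
best cutoff maximises the Youden index J = sensitivity + specificity − 1
over midpoints between consecutive distinct scores, with a deterministic
tie-break.  Stratified survival uses the standard product-limit estimator
(via lifelines) on the two strata either side of the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "RocResult",
    "KMCurve",
    "StratifiedKM",
    "roc_analysis",
    "km_stratify",
]


@dataclass
class RocResult:
    thresholds: np.ndarray  # candidate cutoffs on the original score scale
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    youden_j: float
    direction: str


def _validate_direction(direction: str) -> bool:
    if direction not in ("low-positive", "high-positive"):
        raise ValueError("direction must be 'low-positive' or 'high-positive'")
    return direction == "low-positive"


def roc_analysis(scores, labels, direction: str = "low-positive") -> RocResult:
    """Empirical ROC with Youden-optimal cutoff.

    Parameters
    ----------
    scores:
        Continuous scores (e.g. ELVAR values).
    labels:
        Boolean/0-1 array, True for the positive (event) class.
    direction:
        ``"low-positive"`` when low scores indicate the positive class
        (the ELVAR convention), else ``"high-positive"``.

    Candidate cutoffs are the midpoints between consecutive distinct
    scores; a subject is called positive when its score falls strictly on
    the positive side of the cutoff.  AUC is the trapezoidal area under
    the empirical curve.  Ties in J break toward higher specificity, then
    toward the lower cutoff value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    low_positive = _validate_direction(direction)

    distinct = np.unique(scores)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    # sentinels so the curve reaches (0,0) and (1,1)
    span = max(distinct[-1] - distinct[0], 1.0)
    cutoffs = np.concatenate(([distinct[0] - span], midpoints, [distinct[-1] + span]))

    sens = np.empty_like(cutoffs)
    spec = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        pred_pos = scores < c if low_positive else scores > c
        sens[i] = np.sum(pred_pos & labels) / n_pos
        spec[i] = np.sum(~pred_pos & ~labels) / n_neg

    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    # lexicographic argmax: J, then specificity, then lower cutoff
    best = 0
    for i in range(1, len(cutoffs)):
        if (j[i], spec[i], -cutoffs[i]) > (j[best], spec[best], -cutoffs[best]):
            best = i
    return RocResult(
        thresholds=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_cutoff=float(cutoffs[best]),
        youden_j=float(j[best]),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier stratification
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate for one stratum."""

    label: str
    n: int
    n_events: int
    times: np.ndarray  # step-change times, starting at 0
    survival: np.ndarray  # S(t) at those times; S(0) = 1

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass
class StratifiedKM:
    cutoff: float
    below: KMCurve
    above: KMCurve
    horizons_months: tuple[float, ...] = (3.0, 12.0)
    survival_at_horizons: dict = field(default_factory=dict)
    mortality_at_horizons: dict = field(default_factory=dict)


def _fit_km(sub: pd.DataFrame, label: str) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(sub["event_time_months"], event_observed=sub["event_flag"].astype(bool))
    sf = kmf.survival_function_
    return KMCurve(
        label=label,
        n=len(sub),
        n_events=int(sub["event_flag"].sum()),
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def km_stratify(
    table: pd.DataFrame,
    cutoff: float,
    horizons_months: tuple[float, ...] = (3.0, 12.0),
) -> StratifiedKM:
    """Stratify a cohort at an ELVAR cutoff and estimate survival per stratum.

    The *below* stratum is ``elvar < cutoff`` (the high-risk side under
    the ELVAR convention), *above* is ``elvar >= cutoff``.  Besides the
    product-limit curves, raw mortality proportions at each horizon
    (event with event_time <= horizon, closed boundary) are reported.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    required = {"elvar", "event_time_months", "event_flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")

    below_df = table[table["elvar"] < cutoff]
    above_df = table[table["elvar"] >= cutoff]
    for name, df in (("below-cutoff", below_df), ("at/above-cutoff", above_df)):
        if len(df) == 0:
            raise ValueError(f"stratum {name!r} is empty")

    below = _fit_km(below_df, "below-cutoff")
    above = _fit_km(above_df, "at/above-cutoff")

    survival = {}
    mortality = {}
    for t in horizons_months:
        survival[t] = {"below": below.survival_at(t), "above": above.survival_at(t)}
        mortality[t] = {
            "below": float(
                ((below_df["event_flag"]) & (below_df["event_time_months"] <= t)).mean()
            ),
            "above": float(
                ((above_df["event_flag"]) & (above_df["event_time_months"] <= t)).mean()
            ),
        }
    return StratifiedKM(
        cutoff=cutoff,
        below=below,
        above=above,
        horizons_months=tuple(horizons_months),
        survival_at_horizons=survival,
        mortality_at_horizons=mortality,
    )
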