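"""Benchmarking of slope predictions against observed kidney-function decline.

Covers overall and CKD-stage-stratified RMSE, future (endpoint) eGFR
prediction error, robust agreement lines with bootstrap confidence
intervals, within-patient repeatability across sampling time points,
rapid-progressor ROC analysis, and cross-cohort marker intensity
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .renal import ckd_stage

__all__ = [
    "ROCResult",
    "rmse",
    "rmse_by_stage",
    "predict_endpoint_egfr",
    "agreement_line",
    "repeatability",
    "roc_auc",
    "marker_compare",
]

RAPID_PROGRESSOR_CUTOFF = -3.0  # mL/min/1.73m2/year; observed slope below = rapid


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def rmse(observed, predicted) -> float:
    """Root mean squared prediction error."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def rmse_by_stage(
    observed,
    predicted,
    baseline_egfr,
    grouping: list[tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """RMSE within CKD-stage groups (default: stage 1 vs stages 2-4)."""
    grouping = grouping or [(1,), (2, 3, 4)]
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    stages = np.asarray(ckd_stage(np.asarray(baseline_egfr, dtype=float)))
    rows = []
    for group in grouping:
        mask = np.isin(stages, group)
        if not mask.any():
            continue
        label = "-".join(str(s) for s in group)
        rows.append(
            {"stages": label, "n": int(mask.sum()),
             "rmse": rmse(o[mask], p[mask])}
        )
    return pd.DataFrame(rows)


def predict_endpoint_egfr(
    baseline_egfr, predicted_slope, elapsed_years, observed_last_egfr
) -> np.ndarray:
    """Delta eGFR = observed last eGFR - (baseline + slope * years).

    Positive values mean the model predicted a lower endpoint than observed,
    i.e. it overestimated the eGFR loss.
    """
    years = np.asarray(elapsed_years, dtype=float)
    if np.any(years < 0):
        raise ValueError("elapsed time must be non-negative")
    predicted = np.asarray(baseline_egfr, dtype=float) + np.asarray(
        predicted_slope, dtype=float
    ) * years
    return np.asarray(observed_last_egfr, dtype=float) - predicted


def agreement_line(
    observed,
    predicted,
    n_boot: int = 1000,
    seed: int = 0,
    huber_t: float = 1.345,
) -> dict:
    """Robust regression of observed on predicted with bootstrap CIs.

    Fits a Huber robust line (perfect agreement: slope 1, intercept 0) and
    case-resamples the pairs ``n_boot`` times for percentile 95% intervals.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(p) == 0:
        raise ValueError("constant predictions")

    def _fit(oo, pp):
        X = sm.add_constant(pp)
        fit = sm.RLM(oo, X, M=sm.robust.norms.HuberT(t=huber_t)).fit()
        return float(fit.params[0]), float(fit.params[1])

    intercept, slope = _fit(o, p)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2))
    n = o.size
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(p[idx]) == 0:  # degenerate resample; redraw deterministic
            idx = rng.integers(0, n, n)
        try:
            boot[i] = _fit(o[idx], p[idx])
        except Exception:
            boot[i] = (np.nan, np.nan)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_ci": (float(lo[1]), float(hi[1])),
        "intercept_ci": (float(lo[0]), float(hi[0])),
        "n_boot": n_boot,
    }


def repeatability(predictions: pd.DataFrame, tolerance: float = 1.0) -> float:
    """Fraction of within-patient prediction pairs within ``tolerance``.

    ``predictions`` needs columns patient_id and prediction (one row per
    sampling time point); all unordered within-patient pairs count.
    """
    frac_num = 0
    frac_den = 0
    for _, grp in predictions.groupby("patient_id"):
        vals = grp["prediction"].to_numpy(dtype=float)
        for a, b in combinations(vals, 2):
            frac_den += 1
            if abs(a - b) <= tolerance:
                frac_num += 1
    if frac_den == 0:
        raise ValueError("no patient with >= 2 time points")
    return frac_num / frac_den


def roc_auc(
    predicted_slopes,
    observed_slopes,
    cutoff: float = RAPID_PROGRESSOR_CUTOFF,
) -> ROCResult:
    """ROC for discriminating rapid from stable progressors.

    Rapid progressors are patients whose observed slope is strictly below
    ``cutoff`` (decline faster than 3 mL/min/1.73m2/year by default).  The
    continuous score is the negated predicted slope (more negative
    prediction = higher rapid-progression score); the ROC sweeps all score
    thresholds and the AUC is the trapezoidal area, which equals the
    Mann-Whitney probability that a random rapid progressor outscores a
    random stable one.
    """
    pred = np.asarray(predicted_slopes, dtype=float)
    obs = np.asarray(observed_slopes, dtype=float)
    labels = obs < cutoff
    if labels.all() or not labels.any():
        raise ValueError("both classes required after labeling")
    score = -pred
    order = np.argsort(-score, kind="stable")
    s_sorted = score[order]
    l_sorted = labels[order]
    # one operating point per distinct score, counting all ties at once
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(l_sorted)[distinct]
    fps = np.cumsum(~l_sorted)[distinct]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    sens = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
    )


def marker_compare(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, gene: str
) -> tuple[float, float]:
    """Welch two-sample t-test of one protein's intensity across cohorts.

    Returns (mean difference a - b, two-sided p).  Used e.g. to check that
    hemolysis markers do not differ between serum and plasma cohorts.
    """
    for name, m in (("first", matrix_a), ("second", matrix_b)):
        if gene not in m.columns:
            raise ValueError(f"gene {gene!r} absent from {name} matrix")
    a = matrix_a[gene].dropna().to_numpy(dtype=float)
    b = matrix_b[gene].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per cohort")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(p)
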