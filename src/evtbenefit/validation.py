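"""External-validation metrics: discrimination, calibration, bootstrap CIs.

Discrimination is Harrell's concordance, computed for the binary
functional-independence outcome (mRS 0-2) and for the full ordinal mRS
(patients ranked by the model's linear predictor). Calibration is the
intercept (calibration-in-the-large) and slope of a logistic recalibration
of the observed binary outcome on the logit of the predicted probability.
Confidence intervals are percentile bootstrap over patients with the model
held fixed: with B replications the bounds are the ceil(0.025 B)-th and
floor(0.975 B)-th order statistics — for B = 2000 exactly the 50th and
1950th estimates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ._glm import logistic_fit
from .model import FittedOrdinalModel

__all__ = [
    "UndefinedMetricError",
    "BootstrapFailure",
    "MetricCI",
    "ValidationReport",
    "CalibrationCurve",
    "concordance_index",
    "c_binary",
    "c_ordinal",
    "calibration_intercept_slope",
    "bootstrap_ci",
    "validate_external",
    "calibration_curve",
]

PROB_EPS = 1e-8  # clipping bound for predictions of exactly 0 or 1


class UndefinedMetricError(ValueError):
    """Metric undefined on this sample (e.g. single-class outcomes)."""


class BootstrapFailure(RuntimeError):
    """Metric was undefined on more than the tolerated share of resamples."""


# ---------------------------------------------------------------------------
# concordance


def concordance_index(
    scores,
    outcomes,
    *,
    larger_outcome_is_better: bool,
) -> float:
    """Harrell's C over all pairs with different outcomes.

    A pair is concordant when the patient with the better outcome has the
    higher score; score ties count 0.5; outcome-tied pairs are excluded.
    Grouping by outcome level and binary-searching sorted score arrays makes
    this O(L^2 n log n) for L outcome levels, equivalent to the O(n^2)
    enumeration.
    """
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes)
    if s.shape != o.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-d arrays of equal length")
    levels = np.unique(o)
    if levels.size < 2:
        raise UndefinedMetricError("concordance undefined: all outcomes identical")
    groups = [np.sort(s[o == lv]) for lv in levels]
    if not larger_outcome_is_better:
        groups = groups[::-1]  # ascending 'goodness'
    num = 0.0
    den = 0.0
    for i in range(len(groups)):  # worse-outcome group
        for j in range(i + 1, len(groups)):  # better-outcome group
            worse, better = groups[i], groups[j]
            lo = np.searchsorted(worse, better, side="left")
            hi = np.searchsorted(worse, better, side="right")
            num += float(np.sum(lo)) + 0.5 * float(np.sum(hi - lo))
            den += len(worse) * len(better)
    return num / den


def c_binary(predictions, outcomes) -> float:
    """Concordance for a binary outcome: events should score higher."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("outcomes must be 0/1")
    if uniq.size < 2:
        raise UndefinedMetricError("c_binary undefined: single-class outcomes")
    return concordance_index(p, y.astype(int), larger_outcome_is_better=True)


def c_ordinal(scores, outcomes) -> float:
    """Concordance over the full mRS: lower mRS is the better outcome."""
    y = np.asarray(outcomes, dtype=int)
    return concordance_index(np.asarray(scores, float), y, larger_outcome_is_better=False)


# ---------------------------------------------------------------------------
# calibration


def calibration_intercept_slope(predictions, outcomes) -> dict:
    """Logistic recalibration of observed outcomes on logit(prediction).

    slope: coefficient of logit(p) in ``y ~ 1 + logit(p)``;
    intercept: intercept of ``y ~ 1`` with logit(p) as a fixed offset.
    Ideal values are 1 and 0. Predictions of exactly 0 or 1 are clipped to
    [PROB_EPS, 1 - PROB_EPS] with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("calibration undefined: single-class outcomes")
    if np.any(p <= 0) or np.any(p >= 1):
        warnings.warn(
            f"predictions at 0/1 clipped to [{PROB_EPS}, 1 - {PROB_EPS}]",
            stacklevel=2,
        )
        p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
    lp = np.log(p / (1 - p))
    ones = np.ones((len(p), 1))
    slope = float(logistic_fit(np.column_stack([ones, lp]), y)[1])
    intercept = float(logistic_fit(ones, y, offset=lp)[0])
    return {"intercept": intercept, "slope": slope}


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class MetricCI:
    point: float
    lower: float
    upper: float
    B: int = 0
    seed: Optional[int] = None
    n_redrawn: int = 0
    estimates: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "B": self.B,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
        }


def bootstrap_order_indices(B: int, level: float = 0.95) -> tuple[int, int]:
    """0-based order-statistic indices of the percentile bounds."""
    a = (1.0 - level) / 2.0
    # guard against float artifacts like 0.025 * 2000 = 50.000000000000007
    lo = math.ceil(a * B - 1e-9) - 1
    hi = math.floor((1.0 - a) * B + 1e-9) - 1
    return max(lo, 0), min(hi, B - 1)


def bootstrap_ci(
    metric: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    max_undefined_frac: float = 0.05,
    keep_estimates: bool = True,
) -> MetricCI:
    """Percentile bootstrap CI of ``metric`` over patient resamples.

    Rows are resampled with replacement and the metric recomputed with the
    model fixed. Resamples on which the metric is undefined are redrawn and
    counted; more than ``max_undefined_frac * B`` of them is a reported
    failure, never a silent CI.
    """
    if B < 40:
        raise ValueError("B must be >= 40 for a meaningful percentile CI")
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    point = float(metric(cohort))
    rng = np.random.default_rng(seed)
    estimates = np.empty(B)
    n_redrawn = 0
    max_redraw = int(max_undefined_frac * B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                estimates[b] = metric(cohort.iloc[idx])
                break
            except UndefinedMetricError:
                n_redrawn += 1
                if n_redrawn > max_redraw:
                    raise BootstrapFailure(
                        f"metric undefined on more than {max_undefined_frac:.0%} "
                        f"of resamples ({n_redrawn} redraws at replicate {b + 1})"
                    )
    order = np.sort(estimates)
    lo, hi = bootstrap_order_indices(B, level)
    return MetricCI(
        point=point,
        lower=float(order[lo]),
        upper=float(order[hi]),
        B=B,
        seed=seed,
        n_redrawn=n_redrawn,
        estimates=estimates if keep_estimates else None,
    )


# ---------------------------------------------------------------------------
# report


@dataclass
class ValidationReport:
    """Discrimination and calibration of one model on one external cohort."""

    c_binary: MetricCI
    c_ordinal: MetricCI
    cal_intercept: MetricCI
    cal_slope: MetricCI
    n: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "c_binary": self.c_binary.to_dict(),
            "c_ordinal": self.c_ordinal.to_dict(),
            "cal_intercept": self.cal_intercept.to_dict(),
            "cal_slope": self.cal_slope.to_dict(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("c_binary", "c_ordinal", "cal_intercept", "cal_slope"):
            m: MetricCI = getattr(self, name)
            rows.append(
                {
                    "metric": name,
                    "point": m.point,
                    "lower": m.lower,
                    "upper": m.upper,
                    "B": m.B,
                    "seed": m.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _prediction_table(model: FittedOrdinalModel, cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "p_good": model.prob_good(cohort),
            "eta": model.linear_predictor(cohort),
            "y_good": (cohort["mrs_90d"].to_numpy().astype(int) <= 2).astype(int),
            "mrs": cohort["mrs_90d"].to_numpy().astype(int),
        }
    )


def validate_external(
    model: FittedOrdinalModel,
    cohort: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    label: str = "",
) -> ValidationReport:
    """Compute the four performance measures with bootstrap CIs.

    Predictions are made at each patient's observed treatment status; the
    binary outcome is functional independence (mRS 0-2).
    """
    tab = _prediction_table(model, cohort)
    metrics: dict[str, Callable[[pd.DataFrame], float]] = {
        "c_binary": lambda d: c_binary(d["p_good"], d["y_good"]),
        "c_ordinal": lambda d: c_ordinal(d["eta"], d["mrs"]),
        "cal_intercept": lambda d: calibration_intercept_slope(d["p_good"], d["y_good"])[
            "intercept"
        ],
        "cal_slope": lambda d: calibration_intercept_slope(d["p_good"], d["y_good"])["slope"],
    }
    results = {}
    for i, (name, fn) in enumerate(metrics.items()):
        results[name] = bootstrap_ci(fn, tab, B=B, seed=seed + i, keep_estimates=False)
    return ValidationReport(n=len(tab), label=label, **results)


# ---------------------------------------------------------------------------
# calibration curve


@dataclass
class CalibrationCurve:
    """Grouped predicted-vs-observed proportions for the binary outcome."""

    bounds: np.ndarray  # group edges on the predicted-probability scale
    mean_predicted: np.ndarray
    observed: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower": self.bounds[:-1],
                "upper": self.bounds[1:],
                "mean_predicted": self.mean_predicted,
                "observed": self.observed,
                "count": self.counts,
            }
        )


def calibration_curve(predictions, outcomes, n_groups: int = 10) -> CalibrationCurve:
    """Decile (by default) groups of predicted probability vs observed rate."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    qs = np.quantile(p, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(qs)
    if edges.size < 2:
        edges = np.array([p.min(), p.max() + 1e-12])
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    k = edges.size - 1
    counts = np.bincount(idx, minlength=k)
    mean_pred = np.full(k, np.nan)
    obs = np.full(k, np.nan)
    for gi in range(k):
        mask = idx == gi
        if mask.any():
            mean_pred[gi] = p[mask].mean()
            obs[gi] = y[mask].mean()
    return CalibrationCurve(bounds=edges, mean_predicted=mean_pred, observed=obs, counts=counts)
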