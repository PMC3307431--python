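"""Validation protocol for learning-curve extrapolation.

A curve Omega is partitioned at a threshold sample size x_s into a fitting
partition Omega_t = {(x_j, y_j) | x_j <= x_s} and a validation partition
Omega_v = {(x_j, y_j) | x_j > x_s}.  The model is fitted on Omega_t only,
extrapolated to the sizes in Omega_v, and scored there with MAE and RMSE.
Sweeping |Omega_t| from 5 upward over a set of curves yields a results
grid; the weighted and un-weighted fits are compared cell-by-cell with a
one-sided paired t-test (alternative: the baseline's mean error exceeds
the weighted method's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    FitFailureError,
    confidence_band,
    fit_unweighted,
    fit_weighted,
)
from .model import LearningCurve

__all__ = [
    "CurvePartition",
    "GoodnessOfFit",
    "ComparisonResult",
    "partition_curve",
    "grid_cell_count",
    "mean_absolute_error",
    "root_mean_squared_error",
    "evaluate_extrapolation",
    "run_fitting_grid",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass
class CurvePartition:
    """Fit / validation split of a learning curve at threshold ``x_s``."""

    fit_set: LearningCurve
    validation_set: LearningCurve | None
    x_s: float

    @property
    def n_fit(self) -> int:
        return len(self.fit_set)

    @property
    def n_validation(self) -> int:
        return 0 if self.validation_set is None else len(self.validation_set)


@dataclass
class GoodnessOfFit:
    """MAE and RMSE of extrapolated vs observed accuracy on Omega_v."""

    mae: float
    rmse: float
    n_validation: int


@dataclass
class ComparisonResult:
    """One-sided paired t-test of baseline vs weighted validation errors."""

    mean_weighted: float
    mean_baseline: float
    min_weighted: float
    max_weighted: float
    min_baseline: float
    max_baseline: float
    t_statistic: float
    p_value: float
    n_pairs: int
    zero_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_weighted": self.mean_weighted,
            "mean_baseline": self.mean_baseline,
            "min_weighted": self.min_weighted,
            "max_weighted": self.max_weighted,
            "min_baseline": self.min_baseline,
            "max_baseline": self.max_baseline,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "zero_variance": self.zero_variance,
        }


def partition_curve(curve: LearningCurve, x_s: float) -> CurvePartition:
    """Split a curve into Omega_t (x <= x_s) and Omega_v (x > x_s)."""
    if x_s < curve.x[0]:
        raise ValueError(
            f"threshold x_s={x_s} below the smallest sample size {curve.x[0]}"
        )
    fit_pts = [p for p in curve.points if p.x <= x_s]
    val_pts = [p for p in curve.points if p.x > x_s]
    fit_curve = LearningCurve(fit_pts, curve.batch_size_k, curve.label)
    val_curve = (
        LearningCurve(val_pts, curve.batch_size_k, curve.label) if val_pts else None
    )
    return CurvePartition(fit_curve, val_curve, x_s)


def grid_cell_count(caps: Sequence[int], min_fit_points: int = 5) -> int:
    """Number of (curve, |Omega_t|) cells in a fitting-size sweep.

    Each curve contributes ``cap - min_fit_points + 1`` cells, its cap being
    the largest fitting-partition size evaluated for it.
    """
    if any(cap < min_fit_points for cap in caps):
        raise ValueError("every cap must be >= min_fit_points")
    return int(sum(cap - min_fit_points + 1 for cap in caps))


def mean_absolute_error(predicted, observed) -> float:
    """MAE: mean of |y_j - y_hat_j| over the validation points."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be equal-length, nonempty")
    return float(np.mean(np.abs(o - p)))


def root_mean_squared_error(predicted, observed) -> float:
    """RMSE: square root of the mean squared residual."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be equal-length, nonempty")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def evaluate_extrapolation(fit_result, validation: LearningCurve) -> GoodnessOfFit:
    """Score a fitted model on a validation partition."""
    from .model import evaluate_model

    y_hat = evaluate_model(fit_result.params, validation.x)
    return GoodnessOfFit(
        mae=mean_absolute_error(y_hat, validation.y),
        rmse=root_mean_squared_error(y_hat, validation.y),
        n_validation=len(validation),
    )


def run_fitting_grid(
    curves: Sequence[LearningCurve],
    min_fit_points: int = 5,
    max_fit_points: int | dict | None = None,
    methods: Iterable[str] = ("weighted", "unweighted"),
    normalizer_full_curve: bool = False,
) -> pd.DataFrame:
    """Sweep the fitting-partition size over a set of curves.

    For every curve and every ``|Omega_t|`` from ``min_fit_points`` to the
    per-curve cap (curve length - 1 by default so Omega_v is nonempty, or
    the cap from ``max_fit_points`` — an int, or a dict keyed by curve
    label), fit each requested method and score MAE/RMSE on Omega_v.
    Individual fit failures become missing cells, not exceptions.

    Returns a tidy DataFrame with one row per (curve, |Omega_t|, method).
    """
    rows = []
    for curve in curves:
        if max_fit_points is None:
            cap = len(curve) - 1
        elif isinstance(max_fit_points, dict):
            cap = min(max_fit_points[curve.label], len(curve) - 1)
        else:
            cap = min(int(max_fit_points), len(curve) - 1)
        for n_fit in range(min_fit_points, cap + 1):
            x_s = curve.x[n_fit - 1]
            part = partition_curve(curve, x_s)
            for method in methods:
                row = {
                    "curve_label": curve.label,
                    "n_fit_points": n_fit,
                    "sample_size": x_s,
                    "method": method,
                    "mae": np.nan,
                    "rmse": np.nan,
                    "ci_width_first_step": np.nan,
                    "converged": False,
                }
                try:
                    if method == "weighted":
                        norm = len(curve) if normalizer_full_curve else None
                        fr = fit_weighted(part.fit_set, normalizer=norm)
                    elif method == "unweighted":
                        fr = fit_unweighted(part.fit_set)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    gof = evaluate_extrapolation(fr, part.validation_set)
                    band = confidence_band(fr, [part.validation_set.x[0]])
                    row.update(
                        mae=gof.mae,
                        rmse=gof.rmse,
                        ci_width_first_step=float(band.width[0]),
                        converged=True,
                    )
                except FitFailureError as exc:
                    logger.warning(
                        "fit failed for %s |Omega_t|=%d (%s): %s",
                        curve.label, n_fit, method, exc,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(
    weighted_errors, baseline_errors, drop_missing: bool = True
) -> ComparisonResult:
    """Paired one-sided t-test: is the baseline's mean error larger?

    ``weighted_errors`` and ``baseline_errors`` are paired by grid cell.
    Pairs with a missing value (failed fit) are dropped with a logged
    count.  All-zero differences give the degenerate result p = 1; constant
    nonzero differences give an unbounded statistic, reported as p ~ 0 with
    the ``zero_variance`` flag set in both cases.
    """
    w = np.asarray(weighted_errors, float)
    b = np.asarray(baseline_errors, float)
    if w.shape != b.shape:
        raise ValueError("error sequences must be paired (equal length)")
    if drop_missing:
        ok = np.isfinite(w) & np.isfinite(b)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("dropped %d pairs with missing cells", n_dropped)
        w, b = w[ok], b[ok]
    if len(w) < 2:
        raise ValueError("need at least 2 complete pairs")

    diff = b - w
    zero_var = bool(np.allclose(diff, diff[0]))
    if zero_var:
        if np.allclose(diff, 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if diff[0] > 0 else -np.inf
            p = 0.0 if diff[0] > 0 else 1.0
    else:
        t_stat, p = stats.ttest_rel(b, w, alternative="greater")
        t_stat, p = float(t_stat), float(p)
    return ComparisonResult(
        mean_weighted=float(w.mean()),
        mean_baseline=float(b.mean()),
        min_weighted=float(w.min()),
        max_weighted=float(w.max()),
        min_baseline=float(b.min()),
        max_baseline=float(b.max()),
        t_statistic=t_stat,
        p_value=p,
        n_pairs=len(w),
        zero_variance=zero_var,
    )
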