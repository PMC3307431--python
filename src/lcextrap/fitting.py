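"""Weighted nonlinear least-squares fitting of the inverse power law.

The estimator minimises the weighted sum of squared residuals

    S(a, b, c) = sum_j w_j * (y_j - (1 - a - b * x_j**c))**2

over the bounded box a in [0, 1), b >= 0, c in [-1, 0), using a bounded
trust-region least-squares solver with a small deterministic multistart.
Point j of the fitting partition receives the normalised weight ``j / m``
— later points (larger annotation samples) are considered more indicative
of future performance — with ``m`` defaulting to the number of fitting
points (in applications only the fitting partition is observed).  The
un-weighted variant (all weights 1) is the classical baseline.

Uncertainty uses the Gauss-Newton covariance
``Cov(beta) = s2 * (J' W J)^-1`` with ``s2`` the weighted residual variance
on ``n - 3`` degrees of freedom; prediction bands propagate it through the
model gradient (delta method) with a Student-t quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    PARAM_LOWER,
    PARAM_UPPER,
    CurvePoint,
    LearningCurve,
    PowerLawParams,
    asymptote,
    evaluate_model,
    invert_model,
    round_up_to_schedule,
)

__all__ = [
    "FitResult",
    "PredictionBand",
    "InsufficientDataError",
    "FitFailureError",
    "MIN_FIT_POINTS",
    "compute_weights",
    "default_initialization",
    "fit_weighted",
    "fit_unweighted",
    "confidence_band",
    "LearningCurveModel",
    "LearningCurveResults",
]

#: Minimum number of fitting points for the curve fit to be effective.
MIN_FIT_POINTS = 5


class InsufficientDataError(ValueError):
    """Fewer than :data:`MIN_FIT_POINTS` points supplied to a fit."""


class FitFailureError(RuntimeError):
    """The optimizer failed to converge from every start."""


def compute_weights(n_fit_points: int, normalizer: int | None = None) -> np.ndarray:
    """Normalised weights ``j / m`` for fitting points ``j = 1..n``.

    ``normalizer`` is ``m``; it defaults to ``n_fit_points`` (the
    observable case).  Weights are strictly increasing, so later curve
    points dominate the fit.  Scaling all weights by a constant does not
    change the least-squares estimate, so the choice of normaliser is
    cosmetic.
    """
    if n_fit_points < 1:
        raise ValueError("need at least one fitting point")
    if normalizer is None:
        normalizer = n_fit_points
    if normalizer < n_fit_points:
        raise ValueError("normalizer must be >= n_fit_points")
    return np.arange(1, n_fit_points + 1, dtype=float) / float(normalizer)


def _as_xy(fit_points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fit_points, LearningCurve):
        return fit_points.x, fit_points.y
    pts = list(fit_points)
    if pts and isinstance(pts[0], CurvePoint):
        x = np.array([p.x for p in pts], float)
        y = np.array([p.y for p in pts], float)
    else:
        arr = np.asarray(pts, float)
        x, y = arr[:, 0], arr[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("training sizes must be strictly increasing")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    return x, y


def default_initialization(fit_points) -> PowerLawParams:
    """Heuristic starting values for the optimiser.

    The last observed accuracy anchors the asymptote guess
    ``a0 = max(0, 1 - y_last - 0.01)``; with ``c0 = -0.5`` fixed, ``b0`` is
    solved from the last point and everything is clipped into the valid
    parameter box.
    """
    x, y = _as_xy(fit_points)
    if len(x) < 2:
        raise ValueError("need at least two points for initialization")
    a0 = max(0.0, 1.0 - y[-1] - 0.01)
    c0 = -0.5
    b0 = (1.0 - a0 - y[-1]) / x[-1] ** c0
    a0, b0, c0 = np.clip(
        [a0, b0, c0], PARAM_LOWER, np.minimum(PARAM_UPPER, [1.0, 1e6, 0.0])
    )
    if b0 <= 0:
        b0 = 1e-6
    return PowerLawParams(float(a0), float(b0), float(c0))


def _start_ladder(fit_points) -> list[np.ndarray]:
    """Deterministic multistart: heuristic start plus c0 in {-0.2, -0.8}."""
    x, y = _as_xy(fit_points)
    base = default_initialization(fit_points).as_array()
    starts = [base]
    for c0 in (-0.2, -0.8):
        a0 = base[0]
        b0 = (1.0 - a0 - y[-1]) / x[-1] ** c0
        b0 = float(np.clip(b0, 1e-6, 1e6))
        starts.append(np.array([a0, b0, c0]))
    return starts


@dataclass
class FitResult:
    """Outcome of one weighted (or un-weighted) least-squares fit."""

    params: PowerLawParams
    covariance: np.ndarray  # 3x3, Gauss-Newton
    residual_variance: float
    weights: np.ndarray
    n_points: int
    converged: bool
    objective: float  # final weighted SSR
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    cov_singular: bool = False
    start_index: int = 0  # multistart winner, for audit logs

    @property
    def df_resid(self) -> int:
        return self.n_points - 3

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "covariance": self.covariance.tolist(),
            "residual_variance": self.residual_variance,
            "n_points": self.n_points,
            "converged": bool(self.converged),
            "objective": self.objective,
            "cov_singular": bool(self.cov_singular),
        }


@dataclass
class PredictionBand:
    """Extrapolated accuracies with pointwise confidence bounds."""

    x: np.ndarray
    y_hat: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    wide_band_warning: bool = False

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_size": self.x,
                "y_hat": self.y_hat,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _model_gradient(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Gradient of f(x; a, b, c) = 1 - a - b x^c w.r.t. (a, b, c); rows = x."""
    a, b, c = theta
    xc = np.power(x, c)
    return np.column_stack([-np.ones_like(x), -xc, -b * xc * np.log(x)])


def _fit(x, y, weights, initial: PowerLawParams | None) -> FitResult:
    n = len(x)
    if n < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"curve fitting needs >= {MIN_FIT_POINTS} points, got {n}"
        )
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = np.sqrt(w)
    pts = np.column_stack([x, y])

    def residuals(theta):
        a, b, c = theta
        return sw * (y - (1.0 - a - b * np.power(x, c)))

    def jac(theta):
        return -sw[:, None] * _model_gradient(theta, x)

    starts = [initial.as_array()] if initial is not None else _start_ladder(pts)
    best, best_i = None, -1
    for i, th0 in enumerate(starts):
        th0 = np.clip(th0, PARAM_LOWER + 0, np.minimum(PARAM_UPPER, 1e6))
        try:
            sol = optimize.least_squares(
                residuals,
                th0,
                jac=jac,
                bounds=(PARAM_LOWER, PARAM_UPPER),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=5000,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or 2 * sol.cost < 2 * best.cost - 1e-15:
            best, best_i = sol, i
    if best is None:
        raise FitFailureError(
            f"optimizer failed from all {len(starts)} starts (n={n} points)"
        )

    theta = best.x
    ssr = float(2.0 * best.cost)
    dof = max(n - 3, 1)
    s2 = ssr / dof
    J = _model_gradient(theta, x)  # n x 3
    JtWJ = J.T @ (w[:, None] * J)
    singular = False
    try:
        cov = s2 * np.linalg.inv(JtWJ)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtWJ)
        singular = True
    # clip estimate into the open-parameter dataclass domain
    a, b, c = theta
    params = PowerLawParams(
        float(min(max(a, 0.0), 1.0 - 1e-12)),
        float(max(b, 0.0)),
        float(min(max(c, -1.0), -1e-12)),
    )
    return FitResult(
        params=params,
        covariance=cov,
        residual_variance=s2,
        weights=w,
        n_points=n,
        converged=True,
        objective=ssr,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        cov_singular=singular,
        start_index=best_i,
    )


def fit_weighted(
    fit_points,
    initial: PowerLawParams | None = None,
    normalizer: int | None = None,
) -> FitResult:
    """Weighted least-squares fit with weights ``j / m``.

    ``normalizer`` is the weight denominator ``m`` (defaults to the number
    of fitting points).  Requires at least :data:`MIN_FIT_POINTS` points.
    """
    x, y = _as_xy(fit_points)
    if len(x) < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"curve fitting needs >= {MIN_FIT_POINTS} points, got {len(x)}"
        )
    w = compute_weights(len(x), normalizer)
    return _fit(x, y, w, initial)


def fit_unweighted(
    fit_points, initial: PowerLawParams | None = None
) -> FitResult:
    """Baseline un-weighted least-squares fit (all weights equal to 1)."""
    x, y = _as_xy(fit_points)
    if len(x) < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"curve fitting needs >= {MIN_FIT_POINTS} points, got {len(x)}"
        )
    return _fit(x, y, np.ones(len(x)), initial)


def confidence_band(
    fit: FitResult, x_new, level: float = 0.95, clip_upper: bool = True
) -> PredictionBand:
    """Delta-method confidence band for the fitted curve at ``x_new``.

    Var(y_hat(x)) = g(x)' Cov(beta) g(x) with g the model gradient; bounds
    are ``y_hat +/- t_{n-3, (1+level)/2} * se``.  A singular covariance
    yields a wide-band warning state rather than an exception.  The upper
    bound is clipped at 1.0 (accuracy cannot exceed 1) unless
    ``clip_upper=False``.
    """
    if not fit.converged:
        raise ValueError("confidence_band requires a converged fit")
    xg = np.atleast_1d(np.asarray(x_new, float))
    if np.any(xg <= 0):
        raise ValueError("prediction sample sizes must be positive")
    theta = fit.params.as_array()
    y_hat = 1.0 - theta[0] - theta[1] * np.power(xg, theta[2])
    G = _model_gradient(theta, xg)
    var = np.einsum("ij,jk,ik->i", G, fit.covariance, G)
    var = np.maximum(var, 0.0)
    se = np.sqrt(var)
    tq = stats.t.ppf(0.5 * (1.0 + level), df=max(fit.df_resid, 1))
    lower = y_hat - tq * se
    upper = y_hat + tq * se
    if clip_upper:
        upper = np.minimum(upper, 1.0)
        lower = np.minimum(lower, upper)
    if fit.cov_singular:
        warnings.warn(
            "parameter covariance was singular; band may be unreliable (wide)",
            RuntimeWarning,
            stacklevel=2,
        )
    return PredictionBand(
        x=xg,
        y_hat=y_hat,
        lower=lower,
        upper=upper,
        level=level,
        wide_band_warning=fit.cov_singular,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class LearningCurveModel:
    """Inverse power-law model of a learning curve.

    Statsmodels-style entry point: construct from data, call :meth:`fit`,
    work with the returned :class:`LearningCurveResults`.

    Parameters
    ----------
    x : array-like
        Training sizes, strictly increasing.
    y : array-like
        Accuracies in [0, 1], one per training size.

    Examples
    --------
    >>> model = LearningCurveModel.from_curve(curve)        # doctest: +SKIP
    >>> res = model.fit()                                    # doctest: +SKIP
    >>> res.predict([2000, 5000])                            # doctest: +SKIP
    """

    def __init__(self, x, y) -> None:
        self.x, self.y = _as_xy(np.column_stack([np.asarray(x, float), np.asarray(y, float)]))

    @classmethod
    def from_curve(cls, curve: LearningCurve) -> "LearningCurveModel":
        m = cls(curve.x, curve.y)
        m.curve = curve
        return m

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x_col: str = "sample_size", y_col: str = "accuracy"
    ) -> "LearningCurveModel":
        return cls(df[x_col].to_numpy(), df[y_col].to_numpy())

    def fit(
        self,
        weighted: bool = True,
        initial: PowerLawParams | None = None,
        normalizer: int | None = None,
    ) -> "LearningCurveResults":
        """Fit by (weighted) bounded nonlinear least squares."""
        if weighted:
            fr = fit_weighted(
                np.column_stack([self.x, self.y]), initial, normalizer
            )
        else:
            fr = fit_unweighted(np.column_stack([self.x, self.y]), initial)
        return LearningCurveResults(self, fr, weighted=weighted)


class LearningCurveResults:
    """Fitted inverse power-law results.

    Carries the estimates, their Gauss-Newton covariance, residual
    diagnostics, and the derived quantities users act on: extrapolated
    accuracy with confidence bands and the sample size required for a
    target accuracy.
    """

    def __init__(self, model: LearningCurveModel, fit: FitResult, weighted: bool):
        self.model = model
        self.fit_result = fit
        self.weighted = weighted

    # -- basic accessors ----------------------------------------------------
    @property
    def params(self) -> PowerLawParams:
        return self.fit_result.params

    @property
    def cov_params(self) -> np.ndarray:
        return self.fit_result.covariance

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (a, b, c)."""
        return np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))

    @property
    def scale(self) -> float:
        return self.fit_result.residual_variance

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def nobs(self) -> int:
        return self.fit_result.n_points

    @property
    def df_resid(self) -> int:
        return self.fit_result.df_resid

    @property
    def asymptote(self) -> float:
        """Maximum achievable accuracy 1 - a."""
        return asymptote(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.predict(self.model.x)

    # -- derived quantities -------------------------------------------------
    def predict(self, x) -> np.ndarray | float:
        """Predicted accuracy at training size(s) ``x``."""
        return evaluate_model(self.params, x)

    def conf_band(self, x, level: float = 0.95) -> PredictionBand:
        """Delta-method confidence band at training sizes ``x``."""
        return confidence_band(self.fit_result, x, level=level)

    def sample_size_for(
        self, target_accuracy: float, k: int | None = None, m0: int | None = None
    ) -> float | int:
        """Training size needed to reach ``target_accuracy``.

        Returns the exact real inverse, or — when ``k`` is given — the
        recommendation rounded up to the batch schedule.
        """
        x = invert_model(self.params, target_accuracy)
        if k is None:
            return x
        return round_up_to_schedule(x, k, m0)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        p, se = self.params, self.bse
        tq = stats.t.ppf(0.975, df=max(self.df_resid, 1))
        lines = [
            "Inverse power-law learning-curve fit",
            "=" * 56,
            f"Method:       {'weighted' if self.weighted else 'unweighted'} "
            f"nonlinear least squares",
            f"No. points:   {self.nobs}    Df resid: {self.df_resid}",
            f"Objective:    {self.fit_result.objective:.6e} (weighted SSR)",
            f"Resid var:    {self.scale:.6e}",
            f"Asymptote:    {self.asymptote:.4f} (= 1 - a)",
            "-" * 56,
            f"{'param':>6} {'estimate':>12} {'std err':>12} {'[0.025':>10} {'0.975]':>10}",
        ]
        for name, est, s in zip("abc", p.as_array(), se):
            lines.append(
                f"{name:>6} {est:12.6f} {s:12.6f} {est - tq * s:10.4f} {est + tq * s:10.4f}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot(self, x_max: float | None = None, ax=None):
        """Plot the fitted curve, data and 95% band (basic diagnostics)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x_obs = self.model.x
        hi = x_max or 2.0 * x_obs[-1]
        grid = np.linspace(x_obs[0], hi, 200)
        band = self.conf_band(grid)
        ax.plot(x_obs, self.model.y, "ko", ms=4, label="observed")
        ax.plot(grid, band.y_hat, "b-", label="fitted")
        ax.fill_between(grid, band.lower, band.upper, color="r", alpha=0.2, label="95% CI")
        ax.set_xlabel("training set size")
        ax.set_ylabel("accuracy")
        ax.legend()
        return ax
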