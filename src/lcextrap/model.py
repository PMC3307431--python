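"""Inverse power-law learning-curve model.

A classifier's learning curve — accuracy as a function of the number of
annotated training instances — is modelled by the saturating inverse power
law

    Y(x) = 1 - a - b * x**c,    b >= 0,  -1 <= c < 0,

where ``a`` is the minimum achievable error (the curve's asymptote is
``1 - a``), ``b`` scales how far below the asymptote the curve starts, and
``c`` is the decay-rate exponent controlling how fast the asymptote is
approached.  This module houses the parameter vector, the curve container,
and the algebra on the model: evaluation, inversion (sample size required
for a target accuracy) and the asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PowerLawParams",
    "CurvePoint",
    "LearningCurve",
    "evaluate_model",
    "invert_model",
    "asymptote",
    "round_up_to_schedule",
    "InfeasibleTargetError",
    "DegenerateModelError",
    # numerically-safe fitting bounds for (a, b, c)
    "PARAM_LOWER",
    "PARAM_UPPER",
]

# Open endpoints of the admissible parameter region, made numerically safe
# for bounded optimisation: a in [0, 1), b >= 0, c in [-1, 0).
_EPS = 1e-8
PARAM_LOWER = np.array([0.0, 0.0, -1.0])
PARAM_UPPER = np.array([1.0 - _EPS, np.inf, -_EPS])


class InfeasibleTargetError(ValueError):
    """Target accuracy at or above the asymptote ``1 - a``: unreachable."""


class DegenerateModelError(ValueError):
    """Model has b = 0 or c >= 0 and cannot be inverted."""


@dataclass(frozen=True)
class PowerLawParams:
    """Parameter vector (a, b, c) of the inverse power law.

    Parameters
    ----------
    a : float
        Minimum achievable error; the asymptotic accuracy is ``1 - a``.
        Must lie in ``[0, 1)``.
    b : float
        Learning-rate coefficient, nonnegative.
    c : float
        Decay-rate exponent, in ``[-1, 0)``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a < 1.0):
            raise ValueError(f"a must be in [0, 1), got {self.a!r}")
        if not (self.b >= 0.0):
            raise ValueError(f"b must be nonnegative, got {self.b!r}")
        if not (-1.0 <= self.c < 0.0):
            raise ValueError(f"c must be in [-1, 0), got {self.c!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLawParams":
        return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]))


@dataclass(frozen=True)
class CurvePoint:
    """One learning-curve point: accuracy ``y`` at training size ``x``."""

    x: int
    y: float

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ValueError(f"training size x must be >= 1, got {self.x}")
        if not (0.0 <= self.y <= 1.0):
            raise ValueError(f"accuracy y must be in [0, 1], got {self.y}")


class LearningCurve:
    """Ordered sequence of (training size, accuracy) points.

    Training sizes must be strictly increasing.  When the curve is built by
    this package on a batch schedule the sizes satisfy
    ``x_j = m0 + (j - 1) * k`` exactly.

    Parameters
    ----------
    points : sequence of CurvePoint
    batch_size_k : int, optional
        Batch increment the curve was built with, if known.
    label : str
        Free-text provenance (dataset name, sampler name).
    y_spread : sequence of float, optional
        Per-point spread (standard deviation of accuracy over repetitions),
        recorded by the curve builder for reporting.
    """

    def __init__(
        self,
        points: Sequence[CurvePoint],
        batch_size_k: int | None = None,
        label: str = "",
        y_spread: Sequence[float] | None = None,
    ) -> None:
        points = list(points)
        if not points:
            raise ValueError("learning curve needs at least one point")
        xs = [p.x for p in points]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise ValueError("training sizes must be strictly increasing")
        if batch_size_k is not None and batch_size_k < 1:
            raise ValueError("batch_size_k must be a positive integer")
        if y_spread is not None and len(y_spread) != len(points):
            raise ValueError("y_spread length must match number of points")
        self.points = points
        self.batch_size_k = batch_size_k
        self.label = label
        self.y_spread = None if y_spread is None else np.asarray(y_spread, float)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, i):
        return self.points[i]

    @property
    def m(self) -> int:
        """Cardinality of the curve (number of points)."""
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return np.array([p.x for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([p.y for p in self.points], dtype=float)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        x: Iterable[float],
        y: Iterable[float],
        batch_size_k: int | None = None,
        label: str = "",
        y_spread: Sequence[float] | None = None,
    ) -> "LearningCurve":
        pts = [CurvePoint(int(round(xi)), float(yi)) for xi, yi in zip(x, y)]
        return cls(pts, batch_size_k=batch_size_k, label=label, y_spread=y_spread)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LearningCurve":
        return cls.from_arrays(df["sample_size"], df["accuracy"], **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_size": self.x.astype(int), "accuracy": self.y})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f" {self.label!r}" if self.label else ""
        return f"<LearningCurve{lab}: {self.m} points, x {int(self.x[0])}..{int(self.x[-1])}>"


def evaluate_model(params: PowerLawParams, x) -> np.ndarray | float:
    """Accuracy predicted by the inverse power law at training size(s) ``x``.

    Returns ``1 - a - b * x**c`` elementwise.  Strictly increasing in ``x``
    for ``b > 0``, ``c < 0``, approaching the asymptote ``1 - a``.

    Raises
    ------
    ValueError
        If any ``x <= 0`` (the power law is undefined there).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0):
        raise ValueError("training size x must be positive")
    out = 1.0 - params.a - params.b * np.power(xa, params.c)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def asymptote(params: PowerLawParams) -> float:
    """Maximum achievable accuracy, ``1 - a``."""
    return 1.0 - params.a


def invert_model(params: PowerLawParams, target_accuracy: float) -> float:
    """Training size at which the fitted curve reaches ``target_accuracy``.

    Solves ``1 - a - b * x**c = target`` for ``x``:

        x = ((1 - a - target) / b) ** (1 / c)

    Returns a real number; round up to the batch schedule with
    :func:`round_up_to_schedule` for a practical recommendation.

    Raises
    ------
    InfeasibleTargetError
        If ``target_accuracy >= 1 - a`` (at or above the asymptote).
    DegenerateModelError
        If ``b == 0`` or ``c >= 0`` (flat or non-saturating model).
    """
    if params.b == 0.0 or params.c >= 0.0:
        raise DegenerateModelError(
            f"cannot invert degenerate model b={params.b}, c={params.c}"
        )
    if target_accuracy >= asymptote(params):
        raise InfeasibleTargetError(
            f"target {target_accuracy} >= asymptote {asymptote(params):.6g}"
        )
    return ((1.0 - params.a - target_accuracy) / params.b) ** (1.0 / params.c)


def round_up_to_schedule(x: float, k: int, m0: int | None = None) -> int:
    """Smallest schedule size ``m0 + j*k`` (j >= 0) that is >= ``x``.

    With ``m0`` omitted the schedule is plain multiples of ``k``.  This is
    the practical companion to :func:`invert_model`: annotation happens in
    batches, so a recommended size is rounded up to the batch grid.
    """
    if k < 1:
        raise ValueError("batch size k must be >= 1")
    if m0 is None:
        m0 = k
    if x <= m0:
        return int(m0)
    # tolerate float jitter so a size already on the grid is not bumped up
    j = math.ceil((x - m0) / k - 1e-9)
    return int(m0 + j * k)
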