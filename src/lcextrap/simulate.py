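"""Synthetic inputs: noisy power-law curves and small classification data.

Two generator families make the whole pipeline testable without external
downloads:

* :func:`simulate_learning_curve` draws noisy observations around a known
  inverse power law, with either constant noise or noise whose standard
  deviation shrinks as ``x**-0.5`` — the latter emulates curve points that
  are means over many repeated train/test runs, whose sampling variance
  shrinks roughly binomially with the training size.
* :func:`simulate_dataset` builds small binary classification datasets:
  Gaussian blobs, a waveform-like task (21 continuous features formed from
  convex combinations of two of three triangular basis waves plus unit
  Gaussian noise, labelled wave-1 vs the rest), and a sparse-binary
  text-like task (word-presence features with class-dependent firing
  rates).

Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .curves import LabeledDataset
from .model import LearningCurve, PowerLawParams, evaluate_model

__all__ = [
    "CurveSimulationSpec",
    "DatasetSimulationSpec",
    "simulate_learning_curve",
    "simulate_dataset",
]


@dataclass
class CurveSimulationSpec:
    """Recipe for a noisy synthetic learning curve with known truth."""

    true_params: PowerLawParams
    batch_size_k: int = 16
    m0: int | None = None  # defaults to k
    n_points: int = 20
    noise_sd: float = 0.005
    noise_profile: Literal["constant", "decreasing"] = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m0 is None:
            self.m0 = self.batch_size_k
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_points < 1 or self.batch_size_k < 1 or self.m0 < 1:
            raise ValueError("counts must be positive")


@dataclass
class DatasetSimulationSpec:
    """Recipe for a small binary classification dataset."""

    n_instances: int = 2000
    n_features: int = 21
    class_balance: float = 0.5
    structure: Literal["blobs", "waveform", "sparse-text"] = "blobs"
    separation: float = 1.0
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")


def simulate_learning_curve(
    spec: CurveSimulationSpec,
) -> tuple[LearningCurve, dict]:
    """Noisy curve ``y_j = clip(f(x_j) + eps_j, 0, 1)`` on the batch schedule.

    With the "decreasing" profile, ``sd_j = noise_sd * sqrt(x_1 / x_j)`` so
    the stated ``noise_sd`` is the standard deviation at the first point.
    Returns the curve and a ground-truth record (true params, noiseless
    values, per-point noise sd, number of clipped points).
    """
    rng = np.random.default_rng(spec.seed)
    x = spec.m0 + spec.batch_size_k * np.arange(spec.n_points)
    y_true = evaluate_model(spec.true_params, x)
    if spec.noise_profile == "constant":
        sd = np.full(spec.n_points, spec.noise_sd, float)
    elif spec.noise_profile == "decreasing":
        sd = spec.noise_sd * np.sqrt(x[0] / x)
    else:
        raise ValueError(f"unknown noise_profile {spec.noise_profile!r}")
    y = y_true + rng.normal(0.0, 1.0, spec.n_points) * sd
    n_clipped = int(np.sum((y < 0) | (y > 1)))
    y = np.clip(y, 0.0, 1.0)
    curve = LearningCurve.from_arrays(
        x, y, batch_size_k=spec.batch_size_k, label=f"sim-seed{spec.seed}"
    )
    truth = {
        "true_params": spec.true_params,
        "y_true": y_true,
        "noise_sd": sd,
        "n_clipped": n_clipped,
    }
    return curve, truth


# -- waveform-like generator -------------------------------------------------

def _triangular_bases(n_features: int = 21) -> np.ndarray:
    """Three shifted triangular pulses of height 6 on the feature grid.

    Peaks at feature positions 1/3, 1/2 and 2/3 of the grid (the classic
    three-wave construction for a 21-feature waveform task).
    """
    t = np.arange(1, n_features + 1, dtype=float)

    def tri(center: float) -> np.ndarray:
        return np.maximum(6.0 - np.abs(t - center), 0.0)

    return np.stack([tri(7.0 * n_features / 21.0),
                     tri(11.0 * n_features / 21.0),
                     tri(15.0 * n_features / 21.0)])


def simulate_dataset(spec: DatasetSimulationSpec) -> LabeledDataset:
    """Generate a labeled binary dataset with a disjoint held-out test split.

    ``separation`` scales the class signal: 0 gives pure noise (accuracy
    stuck at chance), large values give a nearly separable problem.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_instances, spec.n_features

    if spec.structure == "blobs":
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        labels = (rng.random(n) < spec.class_balance).astype(int)
        X = rng.normal(size=(n, p))
        X += np.outer(np.where(labels == 1, 0.5, -0.5) * spec.separation, direction)
    elif spec.structure == "waveform":
        H = _triangular_bases(p) * spec.separation
        wave_class = rng.integers(0, 3, size=n)
        pairs = np.array([[0, 1], [0, 2], [1, 2]])  # bases mixed per wave class
        u = rng.random(n)
        mix = pairs[wave_class]
        X = (
            u[:, None] * H[mix[:, 0]]
            + (1.0 - u)[:, None] * H[mix[:, 1]]
            + rng.normal(size=(n, p))
        )
        labels = (wave_class == 0).astype(int)  # wave 1 vs the other two
    elif spec.structure == "sparse-text":
        labels = (rng.random(n) < spec.class_balance).astype(int)
        base_rate = rng.uniform(0.02, 0.10, size=p)
        shift = rng.choice([-1.0, 1.0], size=p) * spec.separation * 0.05
        rate1 = np.clip(base_rate + shift, 0.0, 1.0)
        rates = np.where(labels[:, None] == 1, rate1[None, :], base_rate[None, :])
        X = (rng.random((n, p)) < rates).astype(float)
    else:
        raise ValueError(f"unknown structure {spec.structure!r}")

    # guarantee two classes in the pool even at unlucky splits
    return LabeledDataset.from_arrays(
        X,
        labels,
        test_fraction=spec.test_fraction,
        rng=np.random.default_rng(rng.integers(2**31)),
        name=spec.structure,
    )
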