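import numpy as np
import pytest

from lcextrap import (
    CurveSimulationSpec,
    DatasetSimulationSpec,
    PowerLawParams,
    simulate_dataset,
    simulate_learning_curve,
)


@pytest.fixture
def true_params() -> PowerLawParams:
    return PowerLawParams(a=0.1, b=0.4, c=-0.6)


@pytest.fixture
def noiseless_curve(true_params):
    """10 exact power-law points on the x = 16*j schedule."""
    curve, _ = simulate_learning_curve(
        CurveSimulationSpec(true_params=true_params, n_points=10, noise_sd=0.0)
    )
    return curve


@pytest.fixture
def noisy_curve(true_params):
    curve, _ = simulate_learning_curve(
        CurveSimulationSpec(
            true_params=true_params, n_points=20, noise_sd=0.005, seed=7
        )
    )
    return curve


@pytest.fixture
def blobs_dataset():
    """Well-separated two-blob classification problem, 600 instances."""
    return simulate_dataset(
        DatasetSimulationSpec(
            n_instances=600, n_features=5, structure="blobs", separation=3.0, seed=3
        )
    )


def weighted_ssr(x, y, w, a, b, c):
    """Reference objective used by brute-force oracles in the tests."""
    pred = 1.0 - a - b * np.power(np.asarray(x, float), c)
    return float(np.sum(np.asarray(w) * (np.asarray(y) - pred) ** 2))
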