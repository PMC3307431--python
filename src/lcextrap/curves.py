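"""Build empirical learning curves from a labeled dataset.

Classifiers (a linear-kernel support-vector machine by default) are trained
at increasing training-set sizes on a batch schedule
``x_j = m0 + (j - 1) * k`` and evaluated on a fixed held-out test set; the
accuracy at each size, averaged over repeated randomized runs, forms the
learning curve.  Four batch-selection strategies are provided:

RANDOM
    passive uniform sampling without replacement;
DIST
    margin sampling — the pool instances closest to the SVM hyperplane
    (smallest absolute decision value);
DIV
    diversity sampling — greedy selection maximising the minimum cosine
    distance to the already-selected instances, to reduce redundancy;
CMB
    hybrid — shortlist the 3k nearest-to-margin candidates, then pick k of
    them by greedy diversity.

The first batch of every strategy is drawn uniformly at random: before any
model exists there is no margin to sample against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .model import CurvePoint, LearningCurve

__all__ = [
    "LabeledDataset",
    "SamplingRun",
    "UntrainedModelError",
    "SAMPLER_NAMES",
    "batch_schedule",
    "random_sampler",
    "distance_sampler",
    "diversity_sampler",
    "combined_sampler",
    "default_classifier",
    "build_learning_curve",
]

SAMPLER_NAMES = ("RANDOM", "DIST", "DIV", "CMB")


class UntrainedModelError(RuntimeError):
    """Margin-based sampling requested before any model was trained.

    Draw the first batch at random to bootstrap the active learner.
    """


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and a pool / test split.

    ``pool_idx`` are the instances available for (simulated) annotation;
    ``test_idx`` is the disjoint held-out evaluation set.
    """

    features: np.ndarray
    labels: np.ndarray
    pool_idx: np.ndarray
    test_idx: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.pool_idx = np.asarray(self.pool_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if np.intersect1d(self.pool_idx, self.test_idx).size:
            raise ValueError("pool and test sets must be disjoint")
        if np.unique(self.labels).size != 2:
            raise ValueError("labels must be binary (exactly two classes)")
        if np.unique(self.labels[self.pool_idx]).size < 2:
            raise ValueError("pool must contain both classes")

    @property
    def n_pool(self) -> int:
        return len(self.pool_idx)

    @classmethod
    def from_arrays(
        cls,
        features,
        labels,
        test_fraction: float = 0.25,
        rng: np.random.Generator | int | None = 0,
        name: str = "",
    ) -> "LabeledDataset":
        """Randomly split instances into a training pool and a test set."""
        rng = np.random.default_rng(rng)
        n = len(labels)
        perm = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        return cls(features, labels, perm[n_test:], perm[:n_test], name=name)

    @classmethod
    def from_delimited(cls, path, sep: str = ",", **kwargs) -> "LabeledDataset":
        """Read a dense delimited file: one row per instance, last column = label."""
        df = pd.read_csv(path, sep=sep)
        X = df.iloc[:, :-1].to_numpy(dtype=float)
        y = df.iloc[:, -1].to_numpy()
        return cls.from_arrays(X, y, **kwargs)

    @classmethod
    def from_sparse_triplets(
        cls, path, labels_path, sep: str = ",", **kwargs
    ) -> "LabeledDataset":
        """Read sparse text-like features from (row, col, value) triplets."""
        trip = pd.read_csv(path, sep=sep)
        rows = trip.iloc[:, 0].to_numpy(int)
        cols = trip.iloc[:, 1].to_numpy(int)
        vals = trip.iloc[:, 2].to_numpy(float)
        y = pd.read_csv(labels_path, sep=sep).iloc[:, -1].to_numpy()
        X = np.zeros((len(y), cols.max() + 1))
        X[rows, cols] = vals
        return cls.from_arrays(X, y, **kwargs)


@dataclass
class SamplingRun:
    """Configuration for one learning-curve construction experiment."""

    method: str = "RANDOM"
    initial_size_m0: int = 16
    batch_size_k: int = 16
    n_repetitions: int = 100
    seed: int = 0
    shortlist_factor: int = 3  # CMB: margin shortlist = factor * k
    diversity_aggregate: str = "min"  # or "mean"

    def __post_init__(self) -> None:
        if self.method not in SAMPLER_NAMES:
            raise ValueError(f"method must be one of {SAMPLER_NAMES}")
        if self.initial_size_m0 < 2:
            raise ValueError("initial size m0 must be >= 2")
        if self.batch_size_k < 1:
            raise ValueError("batch size k must be >= 1")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "initial_size_m0": self.initial_size_m0,
            "batch_size_k": self.batch_size_k,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "shortlist_factor": self.shortlist_factor,
            "diversity_aggregate": self.diversity_aggregate,
        }


def batch_schedule(k: int, n_batches: int, m0: int | None = None) -> np.ndarray:
    """Training sizes ``m0, m0+k, m0+2k, ...`` (``{k, 2k, ...}`` when m0 = k)."""
    if k < 1 or n_batches < 1:
        raise ValueError("k and n_batches must be >= 1")
    if m0 is None:
        m0 = k
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    return m0 + k * np.arange(n_batches)


# ---------------------------------------------------------------------------
# Batch samplers.  All operate on positional indices into the pool and are
# deterministic given their inputs (RANDOM given its rng state).
# ---------------------------------------------------------------------------


def random_sampler(
    candidates: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform selection of ``k`` candidates without replacement."""
    candidates = np.asarray(candidates)
    if k > len(candidates):
        raise ValueError(f"cannot draw {k} from {len(candidates)} candidates")
    return rng.choice(candidates, size=k, replace=False)


def distance_sampler(
    candidates: np.ndarray, decision_values: np.ndarray, k: int
) -> np.ndarray:
    """``k`` candidates with smallest absolute SVM decision value.

    ``decision_values`` holds the signed distance w.x + b0 for each
    candidate, in candidate order.  Ties resolve to lower candidate index
    (stable sort).
    """
    candidates = np.asarray(candidates)
    if decision_values is None:
        raise UntrainedModelError(
            "no trained model: draw the first batch with random_sampler"
        )
    d = np.abs(np.asarray(decision_values, float))
    if len(d) != len(candidates):
        raise ValueError("one decision value per candidate required")
    k = min(k, len(candidates))
    order = np.argsort(d, kind="stable")
    return candidates[order[:k]]


def _cosine_dist_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance 1 - cos(A_i, B_j); zero-norm rows warned and
    treated as maximally distant (distance 1, the cosine of orthogonality)."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        warnings.warn(
            "zero-norm vector excluded from cosine computation", RuntimeWarning
        )
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    sim = (A / na[:, None]) @ (B / nb[:, None]).T
    return 1.0 - np.clip(sim, -1.0, 1.0)


def diversity_sampler(
    candidates: np.ndarray,
    X_candidates: np.ndarray,
    X_selected: np.ndarray,
    k: int,
    aggregate: str = "min",
) -> np.ndarray:
    """Greedy diversity selection by cosine distance.

    Picks ``k`` candidates one at a time, each maximising the aggregate
    (min by default, optionally mean) cosine distance to the union of the
    current training set and the candidates already picked this batch.
    Ties resolve to lower candidate index.
    """
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    candidates = np.asarray(candidates)
    if len(X_selected) == 0:
        raise ValueError("diversity sampling needs a nonempty training set")
    k = min(k, len(candidates))
    D = _cosine_dist_matrix(np.asarray(X_candidates, float), np.asarray(X_selected, float))
    if aggregate == "min":
        score = D.min(axis=1)
    else:
        sums = D.sum(axis=1)
        counts = np.full(len(candidates), D.shape[1], float)
        score = sums / counts
    picked: list[int] = []
    available = np.ones(len(candidates), dtype=bool)
    for _ in range(k):
        masked = np.where(available, score, -np.inf)
        best = int(np.argmax(masked))  # argmax takes first on ties
        picked.append(best)
        available[best] = False
        # update scores against the newly picked candidate
        d_new = _cosine_dist_matrix(
            np.asarray(X_candidates, float),
            np.asarray(X_candidates[best], float)[None, :],
        )[:, 0]
        if aggregate == "min":
            score = np.minimum(score, d_new)
        else:
            sums = sums + d_new
            counts = counts + 1
            score = sums / counts
    return candidates[np.array(picked, int)]


def combined_sampler(
    candidates: np.ndarray,
    X_candidates: np.ndarray,
    decision_values: np.ndarray,
    X_selected: np.ndarray,
    k: int,
    shortlist_factor: int = 3,
    aggregate: str = "min",
) -> np.ndarray:
    """Hybrid margin + diversity selection.

    Shortlists the ``shortlist_factor * k`` candidates nearest the margin,
    then greedily diversifies ``k`` of them by cosine distance.  The
    selection is always a subset of the margin shortlist.
    """
    candidates = np.asarray(candidates)
    k = min(k, len(candidates))
    n_short = min(shortlist_factor * k, len(candidates))
    short = distance_sampler(np.arange(len(candidates)), decision_values, n_short)
    picked = diversity_sampler(
        short, np.asarray(X_candidates)[short], X_selected, k, aggregate
    )
    return candidates[picked]


# ---------------------------------------------------------------------------
# Classifier and curve construction
# ---------------------------------------------------------------------------


class _ConstantClassifier:
    """Predicts the single class seen in a one-class training batch."""

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)

    def decision_function(self, X):
        return np.zeros(len(X))


def default_classifier() -> SVC:
    """Linear-kernel SVM with complexity constant 1 and tolerance 1e-3.

    No feature normalisation or standardisation is applied.
    """
    return SVC(kernel="linear", C=1.0, tol=1e-3)


def _train(X, y, classifier_factory: Callable):
    classes = np.unique(y)
    if len(classes) < 2:
        return _ConstantClassifier(classes[0])
    clf = classifier_factory()
    clf.fit(X, y)
    return clf


def build_learning_curve(
    dataset: LabeledDataset,
    run: SamplingRun,
    n_batches: int,
    classifier_factory: Callable | None = None,
) -> LearningCurve:
    """Construct a learning curve by repeated incremental sampling.

    For each repetition, ``m0`` seed instances are drawn at random, then the
    configured sampler adds ``k`` pool instances per batch; a classifier is
    trained at each size and scored on the held-out test set.  The curve
    point ``y_j`` is the mean test accuracy over repetitions; the per-point
    spread (standard deviation over repetitions) is attached to the curve.
    """
    if classifier_factory is None:
        classifier_factory = default_classifier
    m0, k = run.initial_size_m0, run.batch_size_k
    need = m0 + (n_batches - 1) * k
    if need > dataset.n_pool:
        raise ValueError(
            f"schedule needs {need} pool instances, pool has {dataset.n_pool}"
        )
    if len(dataset.test_idx) == 0:
        raise ValueError("test set is empty")

    X, y = dataset.features, dataset.labels
    X_test, y_test = X[dataset.test_idx], y[dataset.test_idx]
    sizes = batch_schedule(k, n_batches, m0)
    acc = np.zeros((run.n_repetitions, n_batches))
    rng_master = np.random.default_rng(run.seed)

    for rep in range(run.n_repetitions):
        rng = np.random.default_rng(rng_master.integers(2**31))
        pool = dataset.pool_idx.copy()
        selected = random_sampler(np.arange(len(pool)), m0, rng)
        sel_mask = np.zeros(len(pool), dtype=bool)
        sel_mask[selected] = True
        clf = _train(X[pool[sel_mask]], y[pool[sel_mask]], classifier_factory)
        acc[rep, 0] = float(np.mean(clf.predict(X_test) == y_test))
        for j in range(1, n_batches):
            cand = np.flatnonzero(~sel_mask)
            if run.method == "RANDOM":
                new = random_sampler(cand, k, rng)
            elif run.method == "DIST":
                dv = clf.decision_function(X[pool[cand]])
                new = distance_sampler(cand, dv, k)
            elif run.method == "DIV":
                new = diversity_sampler(
                    cand, X[pool[cand]], X[pool[sel_mask]], k, run.diversity_aggregate
                )
            else:  # CMB
                dv = clf.decision_function(X[pool[cand]])
                new = combined_sampler(
                    cand,
                    X[pool[cand]],
                    dv,
                    X[pool[sel_mask]],
                    k,
                    run.shortlist_factor,
                    run.diversity_aggregate,
                )
            sel_mask[new] = True
            train_idx = pool[sel_mask]
            assert not np.intersect1d(train_idx, dataset.test_idx).size, (
                "training instances leaked into the test set"
            )
            clf = _train(X[train_idx], y[train_idx], classifier_factory)
            acc[rep, j] = float(np.mean(clf.predict(X_test) == y_test))

    y_mean = acc.mean(axis=0)
    y_sd = acc.std(axis=0, ddof=1) if run.n_repetitions > 1 else np.zeros(n_batches)
    label = f"{dataset.name or 'dataset'}-{run.method}"
    return LearningCurve.from_arrays(
        sizes, np.clip(y_mean, 0.0, 1.0), batch_size_k=k, label=label, y_spread=y_sd
    )
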