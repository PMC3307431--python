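"""File formats: curve CSV, fit JSON, band CSV, grid CSV, manifest JSON.

Curve files are comma-delimited UTF-8 with the header
``sample_size,accuracy`` and accuracies as fractions; files whose accuracy
column exceeds 1.5 are auto-detected as percentages and rescaled (logged).
An optional JSON sidecar (``<stem>.meta.json``) records batch size and
label.  All writes are atomic (write to a temp file, then rename), so an
interrupted run never leaves a truncated table.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, PredictionBand
from .model import LearningCurve, PowerLawParams

__all__ = [
    "read_curve",
    "write_curve",
    "write_fit_json",
    "read_fit_json",
    "write_band_csv",
    "write_grid_csv",
    "write_json",
    "atomic_write_text",
]

logger = logging.getLogger(__name__)


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_curve(path) -> LearningCurve:
    """Read a learning curve from a 2-column delimited file.

    Raises a parse error naming the offending line on malformed input.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed curve file {path}: {exc}") from exc
    if not {"sample_size", "accuracy"}.issubset(df.columns):
        raise ValueError(
            f"{path}: header must contain 'sample_size' and 'accuracy' "
            f"(line 1: {','.join(map(str, df.columns))})"
        )
    for i, v in enumerate(df["accuracy"], start=2):
        try:
            fv = float(v)
        except (TypeError, ValueError):
            fv = float("nan")
        if not np.isfinite(fv):
            raise ValueError(f"{path}: non-numeric accuracy on line {i}")
    acc = df["accuracy"].astype(float).to_numpy()
    if np.any(acc > 1.5):
        logger.info("%s: accuracies > 1.5 interpreted as percentages", path)
        acc = acc / 100.0
    k, label, spread = None, "", None
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        k = meta.get("batch_size_k")
        label = meta.get("label", "")
        spread = meta.get("y_spread")
    return LearningCurve.from_arrays(
        df["sample_size"].to_numpy(), acc, batch_size_k=k, label=label, y_spread=spread
    )


def write_curve(curve: LearningCurve, path, sidecar: bool = True) -> None:
    path = Path(path)
    atomic_write_text(path, curve.to_frame().to_csv(index=False))
    if sidecar:
        meta = {
            "batch_size_k": curve.batch_size_k,
            "label": curve.label,
        }
        if curve.y_spread is not None:
            meta["y_spread"] = [float(v) for v in curve.y_spread]
        atomic_write_text(_sidecar(path), json.dumps(meta, indent=2) + "\n")


def write_fit_json(fit: FitResult, path) -> None:
    atomic_write_text(Path(path), json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n")


def read_fit_json(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(
        params=PowerLawParams.from_dict(d["params"]),
        covariance=np.asarray(d["covariance"], float),
        residual_variance=float(d["residual_variance"]),
        weights=np.array([]),
        n_points=int(d["n_points"]),
        converged=bool(d["converged"]),
        objective=float(d["objective"]),
        cov_singular=bool(d.get("cov_singular", False)),
    )


def write_band_csv(band: PredictionBand, path) -> None:
    atomic_write_text(Path(path), band.to_frame().to_csv(index=False))


def write_grid_csv(grid: pd.DataFrame, path) -> None:
    atomic_write_text(Path(path), grid.to_csv(index=False))


def write_json(obj: dict, path) -> None:
    atomic_write_text(Path(path), json.dumps(obj, indent=2, sort_keys=True) + "\n")
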