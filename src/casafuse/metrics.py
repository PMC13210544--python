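"""Accuracy metrics (R², MAE, MAPE, RMSE) and random-point validation.

MAPE is reported as a percentage; pairs whose observed value is exactly
zero are excluded (the relative error is undefined there) and the exclusion
count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import RasterGrid, check_compatible

__all__ = [
    "PairedSample",
    "EvalReport",
    "r_squared",
    "mae",
    "mape",
    "rmse",
    "evaluate",
    "sample_validation_points",
]

log = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """Observed/predicted value pairs."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed and predicted must have equal length")

    @property
    def n(self) -> int:
        return self.observed.size


@dataclass
class EvalReport:
    r2: float
    mae: float
    mape_percent: float
    rmse: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mae": self.mae,
            "mape_percent": self.mape_percent,
            "rmse": self.rmse,
            "n": self.n,
        }


def r_squared(s: PairedSample) -> float:
    """Coefficient of determination 1 − SSres/SStot (may be negative)."""
    if s.n < 2:
        raise ValueError("R^2 needs at least 2 samples")
    y, yhat = s.observed, s.predicted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(s: PairedSample) -> float:
    """Mean absolute error."""
    if s.n == 0:
        raise ValueError("empty sample")
    return float(np.mean(np.abs(s.observed - s.predicted)))


def mape(s: PairedSample) -> float:
    """Mean absolute percentage error (%), excluding zero-observed pairs."""
    if s.n == 0:
        raise ValueError("empty sample")
    nonzero = s.observed != 0
    dropped = int(s.n - nonzero.sum())
    if dropped:
        log.info("mape: excluded %d pair(s) with observed value 0", dropped)
    if not np.any(nonzero):
        raise ValueError("MAPE undefined: all observed values are 0")
    y = s.observed[nonzero]
    yhat = s.predicted[nonzero]
    return float(100.0 * np.mean(np.abs(y - yhat) / np.abs(y)))


def rmse(s: PairedSample) -> float:
    """Root mean square error."""
    if s.n == 0:
        raise ValueError("empty sample")
    return float(np.sqrt(np.mean((s.observed - s.predicted) ** 2)))


def evaluate(s: PairedSample) -> EvalReport:
    return EvalReport(
        r2=r_squared(s), mae=mae(s), mape_percent=mape(s), rmse=rmse(s), n=s.n
    )


def sample_validation_points(
    reference: RasterGrid,
    test: RasterGrid,
    n_points: int,
    seed: int,
) -> PairedSample:
    """Uniform random sample (without replacement) of jointly valid pixels.

    Mirrors the usual fusion-validation protocol of scattering random
    points over the scene and pairing reference with test values.
    """
    check_compatible(reference, test)
    joint = reference.valid_mask & test.valid_mask
    idx = np.flatnonzero(joint)
    if idx.size < n_points:
        raise ValueError(
            f"only {idx.size} jointly valid pixels, requested {n_points}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_points, replace=False)
    flat_ref = reference.values.ravel()[chosen]
    flat_test = test.values.ravel()[chosen]
    return PairedSample(observed=flat_ref, predicted=flat_test)
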