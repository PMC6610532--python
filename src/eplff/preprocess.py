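"""Glomerular-layer preprocessing.

Two stages precede the spiking network:

1. *Sensor scaling* — each sensor's response is divided by its maximum
   response over a validation set, equalizing the dynamic ranges of
   heterogeneous sensors.  The scale is fitted once and then frozen; later
   (possibly degraded) batches are rescaled through the same factors, which
   magnifies weakened sensors back into the network's expected range.

2. *Unsupervised concentration tolerance* — the periglomerular/external
   tufted circuit divides each scaled response by the sum over all sensors.
   The output is invariant to multiplying the input by any positive factor,
   removing most concentration-driven variance while preserving the
   response *pattern*.  The pre-normalization sum is retained, because it
   is the quantity concentration estimation reads out.

Both are exposed as scikit-learn transformers (:class:`SensorScaler`,
:class:`ConcentrationTolerance`) and as plain functions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import SensorSample

logger = logging.getLogger(__name__)


@dataclass
class PreprocessedInput:
    """Result of the full preprocessing chain for one sample."""

    scaled: np.ndarray
    normalized: np.ndarray
    total_scaled: float


def _as_matrix(samples_or_array) -> np.ndarray:
    if isinstance(samples_or_array, np.ndarray):
        return np.atleast_2d(np.asarray(samples_or_array, dtype=float))
    rows = [
        s.features if isinstance(s, SensorSample) else np.asarray(s, dtype=float)
        for s in samples_or_array
    ]
    return np.stack(rows)


class SensorScaler(TransformerMixin, BaseEstimator):
    """Per-sensor max scaling fitted on a validation set.

    ``transform`` divides each feature by the fitted per-sensor maximum;
    out-of-range inputs may exceed 1 (no clipping).  Attributes:

    scale_ : ndarray of shape (n_sensors,)
        Per-sensor maximum response over the fit data.
    """

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a sensor scale on an empty validation set")
        scale = X.max(axis=0)
        dead = np.flatnonzero(scale <= 0)
        if dead.size:
            raise ValueError(
                "sensor(s) with no positive validation reading: "
                + ", ".join(str(int(i) + 1) for i in dead)
            )
        self.scale_ = scale
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = _as_matrix(X)
        if X.shape[1] != self.scale_.shape[0]:
            raise ValueError(
                f"expected {self.scale_.shape[0]} sensors, got {X.shape[1]}"
            )
        return X / self.scale_

    def to_json(self, path: str | Path, fitted_from: str = "") -> None:
        check_is_fitted(self, "scale_")
        Path(path).write_text(
            json.dumps({"s": self.scale_.tolist(), "fitted_from": fitted_from})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorScaler":
        data = json.loads(Path(path).read_text())
        obj = cls()
        obj.scale_ = np.asarray(data["s"], dtype=float)
        obj.n_features_in_ = obj.scale_.shape[0]
        return obj


class ConcentrationTolerance(TransformerMixin, BaseEstimator):
    """Stateless sum-normalization (the PG/ET circuit outcome).

    Rows are divided by their sum; an all-zero row maps to zeros with a
    warning (blank samples flow through to a none-of-the-above outcome).
    """

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return np.stack([concentration_tolerance(row) for row in X])


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_sensor_scale(validation_samples: Iterable) -> np.ndarray:
    """Per-sensor maximum over the validation samples (the frozen scale S)."""
    return SensorScaler().fit(_as_matrix(validation_samples)).scale_


def apply_sensor_scale(sample, scale: np.ndarray) -> np.ndarray:
    x = sample.features if isinstance(sample, SensorSample) else np.asarray(sample, float)
    scale = np.asarray(scale, dtype=float)
    if x.shape != scale.shape:
        raise ValueError(f"feature/scale dimension mismatch: {x.shape} vs {scale.shape}")
    return x / scale


def concentration_tolerance(scaled: np.ndarray) -> np.ndarray:
    """Divide by the sum over sensors; invariant to positive rescaling of
    the input.  All-zero input returns zeros with a warning."""
    scaled = np.asarray(scaled, dtype=float)
    if np.any(scaled < 0):
        raise ValueError("concentration tolerance expects non-negative input")
    total = scaled.sum()
    if total == 0:
        warnings.warn("zero-sum sensor input; returning zeros", stacklevel=2)
        return np.zeros_like(scaled)
    return scaled / total


def preprocess(sample, scale: np.ndarray) -> PreprocessedInput:
    """Sensor scaling followed by concentration tolerance; the
    pre-normalization total is kept for concentration estimation."""
    scaled = apply_sensor_scale(sample, scale)
    total = float(scaled.sum())
    if total == 0:
        warnings.warn("zero-sum sensor input; returning zeros", stacklevel=2)
        normalized = np.zeros_like(scaled)
    else:
        normalized = scaled / total
    return PreprocessedInput(scaled=scaled, normalized=normalized, total_scaled=total)
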