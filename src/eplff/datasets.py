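"""Chemosensor-array dataset handling.

Reads the UCI gas-sensor-array drift files (sparse ``label;concentration
idx:value`` text lines, 8 recorded features per sensor for 16 polymer
sensors), reduces each sample to the per-sensor steady-state response, and
builds the validation / few-shot-training / test splits used by the online
learning protocols.  A plain CSV dialect
(``sensor_01..sensor_NN,label,concentration,batch``) is supported for
synthetic data so every downstream stage is testable without a download.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: batch_id used for generated data that does not belong to a drift-file batch.
SYNTHETIC = "synthetic"

#: label used for samples whose class is not known.
UNKNOWN = "unknown"

#: Numeric odorant coding of the UCI drift-dataset distribution.  The
#: training ORDER used by the online protocols is a separate concept
#: (see :data:`DEFAULT_CLASS_ORDER`).
DEFAULT_LABEL_TABLE: Mapping[int, str] = {
    1: "ethanol",
    2: "ethylene",
    3: "ammonia",
    4: "acetaldehyde",
    5: "acetone",
    6: "toluene",
}

#: Odorant training order of the online-learning protocol.
DEFAULT_CLASS_ORDER: tuple[str, ...] = (
    "ammonia",
    "acetaldehyde",
    "acetone",
    "ethylene",
    "ethanol",
    "toluene",
)


class DriftFileFormatError(ValueError):
    """Raised for malformed sparse drift-file lines or out-of-range indices."""


@dataclass
class SensorSample:
    """One array reading: feature vector + odorant label + concentration."""

    features: np.ndarray
    label: str = UNKNOWN
    concentration: float | None = None
    batch_id: int | str = SYNTHETIC

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be >= 0 when present")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]


@dataclass
class Batch:
    """An ordered collection of samples sharing a batch id."""

    batch_id: int | str
    samples: list[SensorSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.batch_id != self.batch_id:
                raise ValueError(
                    f"sample batch_id {s.batch_id!r} != batch {self.batch_id!r}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def feature_matrix(self) -> np.ndarray:
        return np.stack([s.features for s in self.samples])

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def concentrations(self) -> np.ndarray:
        return np.array(
            [np.nan if s.concentration is None else s.concentration for s in self.samples]
        )


@dataclass
class ProtocolSplit:
    """Validation / per-class few-shot training / test partition of a batch."""

    validation: list[SensorSample]
    per_class_training: dict[str, list[SensorSample]]
    test: list[SensorSample]

    def training_samples(self) -> list[SensorSample]:
        return [s for shots in self.per_class_training.values() for s in shots]


# ---------------------------------------------------------------------------
# Sparse drift-file format
# ---------------------------------------------------------------------------

def parse_drift_line(
    line: str,
    n_features: int,
    label_table: Mapping[int, str],
    line_no: int,
) -> SensorSample:
    parts = line.split()
    head = parts[0]
    if ";" not in head:
        raise DriftFileFormatError(
            f"line {line_no}: expected 'label;concentration' header, got {head!r}"
        )
    label_txt, _, conc_txt = head.partition(";")
    try:
        label_code = int(label_txt)
        concentration = float(conc_txt)
    except ValueError as exc:
        raise DriftFileFormatError(f"line {line_no}: bad header {head!r}") from exc
    features = np.zeros(n_features)
    for tok in parts[1:]:
        idx_txt, _, val_txt = tok.partition(":")
        try:
            idx = int(idx_txt)
            val = float(val_txt)
        except ValueError as exc:
            raise DriftFileFormatError(
                f"line {line_no}: bad feature token {tok!r}"
            ) from exc
        if not 1 <= idx <= n_features:
            raise DriftFileFormatError(
                f"line {line_no}: feature index {idx} outside 1..{n_features}"
            )
        features[idx - 1] = val
    label = label_table.get(label_code, str(label_code))
    return SensorSample(features=features, label=label, concentration=concentration)


def parse_drift_file(
    path: str | Path,
    n_sensors: int = 16,
    features_per_sensor: int = 8,
    batch_id: int | str | None = None,
    label_table: Mapping[int, str] = DEFAULT_LABEL_TABLE,
) -> Batch:
    """Parse one ``batchN.dat`` drift file into a :class:`Batch`.

    The full ``n_sensors * features_per_sensor`` feature vector is retained;
    reduction to the steady-state feature is done by
    :func:`extract_steady_state`.  Missing sparse indices default to 0.
    """
    path = Path(path)
    if batch_id is None:
        digits = "".join(ch for ch in path.stem if ch.isdigit())
        batch_id = int(digits) if digits else path.stem
    n_features = n_sensors * features_per_sensor
    samples: list[SensorSample] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            sample = parse_drift_line(line, n_features, label_table, line_no)
            sample.batch_id = batch_id
            samples.append(sample)
    if not samples:
        logger.warning("drift file %s contained no samples", path)
        warnings.warn(f"drift file {path} contained no samples", stacklevel=2)
    return Batch(batch_id=batch_id, samples=samples)


def write_drift_file(batch: Batch, path: str | Path, label_table: Mapping[int, str] = DEFAULT_LABEL_TABLE) -> None:
    """Serialize a batch back to the sparse drift-file format (round-trips
    with :func:`parse_drift_file` up to float formatting)."""
    inverse = {v: k for k, v in label_table.items()}
    with open(path, "w") as fh:
        for s in batch:
            code = inverse.get(s.label, s.label)
            conc = 0.0 if s.concentration is None else s.concentration
            toks = [f"{code};{conc:.6f}"]
            toks += [
                f"{i + 1}:{v:.12g}" for i, v in enumerate(s.features) if v != 0.0
            ]
            fh.write(" ".join(toks) + "\n")


def default_steady_state_rule(features_per_sensor: int = 8) -> Callable[[int], int]:
    """Sensor ``k`` (1-based) -> flat 1-based feature index of its
    steady-state response; the first feature of each per-sensor block."""

    def rule(k: int) -> int:
        return features_per_sensor * (k - 1) + 1

    return rule


def extract_steady_state(
    sample: SensorSample,
    feature_index_rule: Callable[[int], int] | None = None,
    n_sensors: int = 16,
    features_per_sensor: int = 8,
) -> SensorSample:
    """Reduce a full multi-feature sample to the 16 steady-state responses.

    ``feature_index_rule`` maps sensor index k (1-based) to a flat 1-based
    feature index; the default selects the first feature of each
    8-feature sensor block (the steady-state response level of the
    dataset's documentation).
    """
    if feature_index_rule is None:
        feature_index_rule = default_steady_state_rule(features_per_sensor)
    idx = np.array([feature_index_rule(k) for k in range(1, n_sensors + 1)])
    if idx.min() < 1 or idx.max() > sample.n_features:
        raise IndexError(
            f"steady-state rule selects indices outside 1..{sample.n_features}"
        )
    return replace(sample, features=sample.features[idx - 1].copy())


def extract_steady_state_batch(batch: Batch, **kwargs) -> Batch:
    return Batch(
        batch_id=batch.batch_id,
        samples=[extract_steady_state(s, **kwargs) for s in batch],
    )


def clamp_negative_features(batch: Batch) -> Batch:
    """Clamp negative steady-state readings to 0 (downstream input currents
    must be non-negative); the number of clamped values is logged."""
    n_clamped = 0
    samples = []
    for s in batch:
        neg = s.features < 0
        n_clamped += int(neg.sum())
        samples.append(replace(s, features=np.where(neg, 0.0, s.features)))
    if n_clamped:
        logger.info(
            "clamped %d negative feature values to 0 in batch %r",
            n_clamped,
            batch.batch_id,
        )
    return Batch(batch_id=batch.batch_id, samples=samples)


# ---------------------------------------------------------------------------
# CSV dialect (synthetic data)
# ---------------------------------------------------------------------------

def batch_to_frame(batch: Batch) -> pd.DataFrame:
    n = batch.samples[0].n_features if batch.samples else 0
    cols = [f"sensor_{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame(batch.feature_matrix() if batch.samples else [], columns=cols)
    df["label"] = batch.labels()
    df["concentration"] = batch.concentrations()
    df["batch"] = batch.batch_id
    return df


def write_csv(batch: Batch, path: str | Path) -> None:
    batch_to_frame(batch).to_csv(path, index=False)


def read_csv(path: str | Path) -> Batch:
    df = pd.read_csv(path)
    sensor_cols = [c for c in df.columns if c.startswith("sensor_")]
    batch_id = df["batch"].iloc[0] if len(df) else SYNTHETIC
    try:
        batch_id = int(batch_id)
    except (TypeError, ValueError):
        pass
    samples = [
        SensorSample(
            features=row[sensor_cols].to_numpy(dtype=float),
            label=str(row["label"]),
            concentration=None if pd.isna(row["concentration"]) else float(row["concentration"]),
            batch_id=batch_id,
        )
        for _, row in df.iterrows()
    ]
    return Batch(batch_id=batch_id, samples=samples)


# ---------------------------------------------------------------------------
# Protocol splits
# ---------------------------------------------------------------------------

def make_protocol_split(
    batch: Batch,
    shots_per_class: int,
    validation_fraction: float = 0.0,
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
    seed: int | np.random.Generator = 0,
) -> ProtocolSplit:
    """Build the online-protocol partition of one batch.

    The validation set (class-stratified, ``validation_fraction`` of the
    batch) feeds the sensor-scale fit; per class in ``class_order``,
    ``shots_per_class`` training shots are drawn uniformly from the
    remaining samples of that class (concentration uncontrolled); everything
    else is test data.  Classes listed but absent from the batch are skipped
    with a warning.  Deterministic under ``seed``.
    """
    if not 1 <= shots_per_class <= 10:
        raise ValueError("shots_per_class must be in 1..10")
    if not 0 <= validation_fraction < 1:
        raise ValueError("validation_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(batch):
        by_class.setdefault(s.label, []).append(i)

    n_val_total = int(round(validation_fraction * len(batch)))
    val_idx: list[int] = []
    if n_val_total > 0:
        # class-stratified draw so every odorant informs the sensor-scale fit
        labels = sorted(by_class)
        quota = {
            lab: int(round(validation_fraction * len(by_class[lab]))) for lab in labels
        }
        for lab in labels:
            pick = rng.choice(by_class[lab], size=min(quota[lab], len(by_class[lab])), replace=False)
            val_idx.extend(int(i) for i in pick)
    val_set = set(val_idx)

    per_class: dict[str, list[SensorSample]] = {}
    train_set: set[int] = set()
    for lab in class_order:
        avail = [i for i in by_class.get(lab, []) if i not in val_set]
        if lab not in by_class:
            warnings.warn(
                f"class {lab!r} absent from batch {batch.batch_id!r}; skipped",
                stacklevel=2,
            )
            continue
        if len(avail) < shots_per_class:
            raise ValueError(
                f"class {lab!r} has {len(avail)} samples available, "
                f"fewer than shots_per_class={shots_per_class}"
            )
        pick = rng.choice(avail, size=shots_per_class, replace=False)
        per_class[lab] = [batch.samples[int(i)] for i in pick]
        train_set.update(int(i) for i in pick)

    test = [
        s
        for i, s in enumerate(batch)
        if i not in val_set and i not in train_set
    ]
    return ProtocolSplit(
        validation=[batch.samples[i] for i in sorted(val_set)],
        per_class_training=per_class,
        test=test,
    )


def split_manifest(split: ProtocolSplit) -> dict:
    """JSON-serializable summary of a protocol split."""
    return {
        "n_validation": len(split.validation),
        "n_test": len(split.test),
        "training": {lab: len(v) for lab, v in split.per_class_training.items()},
    }


def write_split_manifest(split: ProtocolSplit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(split_manifest(split), indent=2))
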