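"""Nearest-template classification and concentration estimation.

Classification compares a test sample's GC binary code against every
stored training template and takes the label of the nearest one.  The
default distance is the Hamming distance normalized over the *union
support* of the two codes (Jaccard distance): with thousands of mostly
silent GCs, normalizing by vector length would keep every distance far
below the 0.5 confidence threshold and the none-of-the-above rule could
never trigger.  The length-normalized variant remains available
(``metric="hamming_length"``), and a binary-cosine overlap metric serves
as an independent criterion (classification flags *none of the above*
when the best overlap falls below the threshold instead of above it).

Concentration is estimated after classification through a per-odorant
quadratic calibration C = a x^2 + b, where x is the *sum of sensor-scaled
responses* — the quantity the concentration-tolerance normalization
divides out, and hence the only place concentration information survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .network import GCBinaryVector
from .preprocess import preprocess

#: classifier outcome when no stored template is close enough.
NONE_OF_THE_ABOVE = "none_of_the_above"


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a.bits if isinstance(a, GCBinaryVector) else a, dtype=bool)
    b = np.asarray(b.bits if isinstance(b, GCBinaryVector) else b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"code length mismatch: {a.shape} vs {b.shape}")
    return a, b


def hamming_distance(a, b, normalization: str = "union") -> float:
    """Hamming distance between binary GC codes, in [0, 1].

    ``normalization="union"`` (default) divides the disagreement count by
    the size of the union support |a OR b| (Jaccard distance);
    ``"length"`` divides by the vector length.  Two all-zero codes are at
    distance 1 by convention (with a warning): a blank code carries no
    identity evidence.
    """
    a, b = _check_pair(a, b)
    xor = np.logical_xor(a, b).sum()
    if normalization == "union":
        union = np.logical_or(a, b).sum()
        if union == 0:
            warnings.warn("both codes all-zero; distance defined as 1", stacklevel=2)
            return 1.0
        return float(xor / union)
    if normalization == "length":
        if a.size == 0 or (not a.any() and not b.any()):
            warnings.warn("both codes all-zero; distance defined as 1", stacklevel=2)
            return 1.0
        return float(xor / a.size)
    raise ValueError(f"unknown normalization {normalization!r}")


def overlap(a, b) -> float:
    """Binary cosine overlap |a AND b| / sqrt(|a| |b|), in [0, 1]."""
    a, b = _check_pair(a, b)
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        warnings.warn("all-zero code; overlap defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / np.sqrt(na * nb))


@dataclass
class TemplateStore:
    """Ordered (label, code) templates learned during training shots;
    training order breaks nearest-neighbor ties."""

    entries: list[tuple[str, GCBinaryVector, int]] = field(default_factory=list)

    def add(self, label: str, code: GCBinaryVector) -> None:
        shot_index = sum(1 for lab, _, _ in self.entries if lab == label)
        self.entries.append((label, code, shot_index))

    def clear(self) -> None:
        self.entries.clear()

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab, _, _ in self.entries:
            if lab not in seen:
                seen.append(lab)
        return seen

    def __len__(self) -> int:
        return len(self.entries)

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label,shot_index,bits\n")
            for lab, code, shot in self.entries:
                fh.write(f"{lab},{shot},{''.join(map(str, code.bits))}\n")

    @classmethod
    def load_csv(cls, path) -> "TemplateStore":
        store = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                lab, shot, bits = line.strip().split(",")
                store.entries.append(
                    (lab, GCBinaryVector(np.array([int(c) for c in bits]), lab), int(shot))
                )
        return store


@dataclass
class ClassificationResult:
    predicted: str
    best_distance: float
    best_template: int | None = None

    @property
    def is_nota(self) -> bool:
        return self.predicted == NONE_OF_THE_ABOVE


def classify(
    code,
    store: TemplateStore,
    threshold: float = 0.5,
    metric: str = "hamming",
) -> ClassificationResult:
    """Nearest stored template; *none of the above* when the best Hamming
    distance exceeds ``threshold`` (or best overlap falls below it).
    Ties go to the earliest-trained template."""
    if len(store) == 0:
        return ClassificationResult(NONE_OF_THE_ABOVE, 1.0, None)
    if metric in ("hamming", "hamming_union"):
        dists = [hamming_distance(code, c) for _, c, _ in store.entries]
        reject = min(dists) > threshold
        best = int(np.argmin(dists))
    elif metric == "hamming_length":
        dists = [hamming_distance(code, c, normalization="length") for _, c, _ in store.entries]
        reject = min(dists) > threshold
        best = int(np.argmin(dists))
    elif metric == "overlap":
        sims = [overlap(code, c) for _, c, _ in store.entries]
        reject = max(sims) < threshold
        best = int(np.argmax(sims))
        dists = [1.0 - s for s in sims]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if reject:
        return ClassificationResult(NONE_OF_THE_ABOVE, float(dists[best]), best)
    return ClassificationResult(store.entries[best][0], float(dists[best]), best)


@dataclass
class AccuracySummary:
    """Accuracy over trained-class samples; NOTA rate on untrained classes
    is bookkept separately (rejecting an untrained odorant is correct)."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    n_trained_samples: int
    nota_rate_untrained: float | None = None
    n_untrained_samples: int = 0
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)


def evaluate(
    test_samples: Iterable,
    network,
    scale: np.ndarray,
    store: TemplateStore,
    metric: str = "hamming",
    threshold: float = 0.5,
) -> AccuracySummary:
    """Classify every test sample; report per-class / overall accuracy over
    the trained classes (NOTA counts as an error there) and the NOTA rate
    on samples of untrained classes."""
    from .network import infer  # local import: evaluate is also used standalone

    trained = set(store.labels())
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    confusion: dict[tuple[str, str], int] = {}
    nota_untrained = 0
    n_untrained = 0
    for sample in test_samples:
        code = infer(network, sample, scale)
        result = classify(code, store, threshold=threshold, metric=metric)
        truth = sample.label
        confusion[(truth, result.predicted)] = confusion.get((truth, result.predicted), 0) + 1
        if truth in trained:
            total[truth] = total.get(truth, 0) + 1
            if result.predicted == truth:
                correct[truth] = correct.get(truth, 0) + 1
        else:
            n_untrained += 1
            if result.is_nota:
                nota_untrained += 1
    per_class = {lab: correct.get(lab, 0) / n for lab, n in total.items()}
    n_trained_samples = sum(total.values())
    overall = sum(correct.values()) / n_trained_samples if n_trained_samples else float("nan")
    return AccuracySummary(
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        n_trained_samples=n_trained_samples,
        nota_rate_untrained=(nota_untrained / n_untrained) if n_untrained else None,
        n_untrained_samples=n_untrained,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Concentration estimation
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationModel:
    """Per-odorant quadratic calibration C = a x^2 + b (x = summed
    sensor-scaled response, C in ppmv).  Labels with fewer than two
    distinct training x values are unavailable."""

    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)

    def available(self, label: str) -> bool:
        return label in self.coefficients

    def predict(self, label: str, total_scaled: float) -> float | None:
        if label not in self.coefficients:
            return None
        a, b = self.coefficients[label]
        c = a * total_scaled**2 + b
        if c < 0:
            warnings.warn(
                f"negative concentration prediction for {label!r}; floored at 0",
                stacklevel=2,
            )
            return 0.0
        return float(c)


def fit_concentration_model(
    label: str,
    training_samples: Sequence,
    scale: np.ndarray,
    model: ConcentrationModel | None = None,
) -> ConcentrationModel:
    """Least-squares fit of C = a x^2 + b over the label's training shots;
    marked unavailable when fewer than two distinct x values exist."""
    model = model or ConcentrationModel()
    xs, cs = [], []
    for s in training_samples:
        if s.concentration is None:
            continue
        xs.append(preprocess(s, scale).total_scaled)
        cs.append(s.concentration)
    xs_arr = np.asarray(xs)
    if np.unique(xs_arr).size < 2:
        warnings.warn(
            f"concentration model unavailable for {label!r}: "
            "needs >= 2 distinct training responses",
            stacklevel=2,
        )
        model.coefficients.pop(label, None)
        return model
    design = np.column_stack([xs_arr**2, np.ones_like(xs_arr)])
    coef, *_ = np.linalg.lstsq(design, np.asarray(cs), rcond=None)
    model.coefficients[label] = (float(coef[0]), float(coef[1]))
    return model


def estimate_concentration(
    sample,
    predicted_label: str,
    model: ConcentrationModel,
    scale: np.ndarray,
) -> float | None:
    """Predicted ppmv for a classified sample, or None when the prediction
    was *none of the above* or no calibration exists for the label."""
    if predicted_label == NONE_OF_THE_ABOVE or not model.available(predicted_label):
        return None
    total = preprocess(sample, scale).total_scaled
    return model.predict(predicted_label, total)


def mean_absolute_error(
    predictions: Sequence[float | None],
    actuals: Sequence[float],
) -> float:
    """Mean |C_pred - C_actual| over pairs with an available prediction."""
    if len(predictions) != len(actuals):
        raise ValueError("predictions and actuals must align")
    pairs = [(p, a) for p, a in zip(predictions, actuals) if p is not None]
    if not pairs:
        raise ValueError("no pairs with available predictions")
    return float(np.mean([abs(p - a) for p, a in pairs]))
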