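"""Experiment protocols: online few-shot learning, reset learning for
drift mitigation, GC-count scaling, and concentration estimation.

The online protocol trains one odorant class at a time (all of its shots)
and after each class evaluates every test sample belonging to any class
trained so far; the resulting stage-accuracy sequence shows whether newly
learned classes erase earlier ones.  Reset learning handles sensor drift
by resetting all MC->GC weights to w_0, clearing the template store and
rapidly retraining on the new batch — with the sensor scale and every
other parameter frozen from the first batch's validation fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import (
    AccuracySummary,
    ConcentrationModel,
    TemplateStore,
    estimate_concentration,
    evaluate,
    fit_concentration_model,
    mean_absolute_error,
    classify,
)
from .datasets import Batch, ProtocolSplit, make_protocol_split
from .network import EPLffNetwork, build_network, infer, train_shot
from .preprocess import fit_sensor_scale

logger = logging.getLogger(__name__)


@dataclass
class StageResult:
    stage: int
    trained_classes: list[str]
    summary: AccuracySummary


@dataclass
class OnlineResult:
    stages: list[StageResult]
    store: TemplateStore
    network: EPLffNetwork

    @property
    def stage_accuracies(self) -> list[float]:
        return [s.summary.overall_accuracy for s in self.stages]

    @property
    def final_accuracy(self) -> float:
        return self.stages[-1].summary.overall_accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            rows.append(
                {
                    "stage": s.stage,
                    "n_trained_classes": len(s.trained_classes),
                    "last_class": s.trained_classes[-1],
                    "accuracy": s.summary.overall_accuracy,
                    "nota_rate_untrained": s.summary.nota_rate_untrained,
                }
            )
        return pd.DataFrame(rows)


def run_online_protocol(
    network: EPLffNetwork,
    split: ProtocolSplit,
    scale: np.ndarray,
    class_order: Sequence[str] | None = None,
    metric: str = "hamming",
    threshold: float = 0.5,
    store: TemplateStore | None = None,
) -> OnlineResult:
    """Sequential class-by-class training with stage-wise evaluation.

    For each class in order: train all of its shots (plasticity on), then
    evaluate every test sample of the classes trained so far.  Untrained
    classes are not scored at intermediate stages (their correct outcome,
    *none of the above*, is bookkept as ``nota_rate_untrained``).
    """
    if class_order is None:
        class_order = list(split.per_class_training)
    store = store if store is not None else TemplateStore()
    stages: list[StageResult] = []
    trained: list[str] = []
    for stage, label in enumerate(class_order, start=1):
        shots = split.per_class_training.get(label)
        if shots is None:
            continue
        for sample in shots:
            train_shot(network, sample, scale, store)
        trained.append(label)
        test_now = [s for s in split.test if s.label in set(trained) or s.label not in set(class_order)]
        summary = evaluate(test_now, network, scale, store, metric=metric, threshold=threshold)
        logger.info(
            "stage %d (%s): accuracy %.4f over %d samples",
            stage,
            label,
            summary.overall_accuracy,
            summary.n_trained_samples,
        )
        stages.append(StageResult(stage=stage, trained_classes=list(trained), summary=summary))
    return OnlineResult(stages=stages, store=store, network=network)


@dataclass
class ResetLearningResult:
    per_batch: dict[int | str, OnlineResult]

    def accuracy_row(self) -> dict[int | str, float]:
        return {b: r.final_accuracy for b, r in self.per_batch.items()}


def run_reset_learning(
    network: EPLffNetwork,
    batches: Sequence[Batch],
    shots_per_class: int,
    class_order: Sequence[str],
    validation_fraction: float = 0.1,
    metric: str = "hamming",
    threshold: float = 0.5,
    seed: int = 0,
    scale: np.ndarray | None = None,
) -> ResetLearningResult:
    """Reset-and-retrain across drifting batches.

    The sensor scale is fitted once, from the first batch's validation
    split, and frozen for every later batch.  Before each batch the
    MC->GC weights are reset to w_0 and the template store cleared; the
    online protocol then runs on that batch alone.
    """
    results: dict[int | str, OnlineResult] = {}
    for i, batch in enumerate(batches):
        vf = validation_fraction if i == 0 else 0.0
        split = make_protocol_split(
            batch,
            shots_per_class=shots_per_class,
            validation_fraction=vf,
            class_order=class_order,
            seed=seed + i,
        )
        if i == 0 and scale is None:
            if not split.validation:
                raise ValueError(
                    "no validation split to fit the sensor scale from; "
                    "pass a prefitted scale or a positive validation_fraction"
                )
            scale = fit_sensor_scale(split.validation)
            logger.info("sensor scale fitted from batch %r validation set", batch.batch_id)
        network.reset()
        results[batch.batch_id] = run_online_protocol(
            network,
            split,
            scale,
            class_order=class_order,
            metric=metric,
            threshold=threshold,
            store=TemplateStore(),
        )
    return ResetLearningResult(per_batch=results)


def evaluate_without_reset(
    trained: OnlineResult,
    batch: Batch,
    scale: np.ndarray,
    metric: str = "hamming",
    threshold: float = 0.5,
) -> AccuracySummary:
    """Score a later batch with the earlier batch's network and templates
    kept as-is (the no-reset arm of the drift comparison)."""
    return evaluate(
        list(batch),
        trained.network,
        scale,
        trained.store,
        metric=metric,
        threshold=threshold,
    )


def reset_learning_matrix(
    batches: Sequence[Batch],
    shots_list: Sequence[int],
    class_order: Sequence[str],
    network_factory: Callable[[], EPLffNetwork],
    validation_fraction: float = 0.1,
    metric: str = "hamming",
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy matrix (rows: shots setting, columns: batch), the shape of
    a multi-shot reset-learning sweep."""
    rows = {}
    for shots in shots_list:
        net = network_factory()
        res = run_reset_learning(
            net,
            batches,
            shots_per_class=shots,
            class_order=class_order,
            validation_fraction=validation_fraction,
            metric=metric,
            seed=seed,
        )
        rows[shots] = res.accuracy_row()
    df = pd.DataFrame(rows).T
    df.index.name = "shots"
    return df


def gc_sweep(
    n_gc_list: Sequence[int],
    split: ProtocolSplit,
    scale: np.ndarray,
    class_order: Sequence[str],
    n_sensors: int,
    cp: float = 0.4,
    seed: int = 0,
    metric: str = "hamming",
    build_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One-shot online protocol at each GC count; returns the
    accuracy-after-k-classes table (rows: n_gc)."""
    if any(n <= 0 for n in n_gc_list):
        raise ValueError("n_gc values must be positive")
    build_kwargs = build_kwargs or {}
    rows = []
    for n_gc in n_gc_list:
        net = build_network(n_sensors, n_gc=n_gc, cp=cp, seed=seed, **build_kwargs)
        res = run_online_protocol(net, split, scale, class_order=class_order, metric=metric)
        row = {"n_gc": n_gc}
        for s in res.stages:
            row[f"{len(s.trained_classes)}_classes"] = s.summary.overall_accuracy
        rows.append(row)
    return pd.DataFrame(rows).set_index("n_gc")


@dataclass
class ConcentrationResult:
    mae: float
    n_predicted: int
    n_missing: int
    predictions: list[float | None] = field(default_factory=list)
    actuals: list[float] = field(default_factory=list)


def run_concentration_protocol(
    online: OnlineResult,
    split: ProtocolSplit,
    scale: np.ndarray,
    metric: str = "hamming",
    threshold: float = 0.5,
) -> ConcentrationResult:
    """Fit per-odorant quadratic calibrations from the training shots, then
    estimate each test sample's concentration *after* classifying it; MAE
    is computed over samples with an available prediction."""
    model = ConcentrationModel()
    for label, shots in split.per_class_training.items():
        fit_concentration_model(label, shots, scale, model)
    predictions: list[float | None] = []
    actuals: list[float] = []
    n_missing = 0
    trained = set(online.store.labels())
    for sample in split.test:
        if sample.label not in trained or sample.concentration is None:
            continue
        code = infer(online.network, sample, scale)
        result = classify(code, online.store, threshold=threshold, metric=metric)
        pred = estimate_concentration(sample, result.predicted, model, scale)
        if pred is None:
            n_missing += 1
        predictions.append(pred)
        actuals.append(sample.concentration)
    mae = mean_absolute_error(predictions, actuals)
    return ConcentrationResult(
        mae=mae,
        n_predicted=len(actuals) - n_missing,
        n_missing=n_missing,
        predictions=predictions,
        actuals=actuals,
    )
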