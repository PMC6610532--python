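"""scikit-learn estimator facade over the EPLff network.

``EPLffClassifier`` wraps network construction, the train/infer lifecycle
and nearest-template classification behind fit / partial_fit / predict, so
the model composes with sklearn pipelines and model selection::

    pipe = make_pipeline(SensorScaler(), EPLffClassifier(n_gc=1200))
    pipe.fit(X_train, y_train)        # X rows are raw sensor responses
    pipe.predict(X_test)              # labels, or "none_of_the_above"

The classifier consumes *sensor-scaled* responses (use
:class:`~eplff.preprocess.SensorScaler` upstream) and applies the
concentration-tolerance normalization internally, since that normalization
is part of the model rather than a data-dependent preprocessing fit.

Training is online and order-sensitive: ``fit`` presents samples in the
order given, one plasticity cycle each, exactly as the few-shot protocol
does.  ``partial_fit`` adds further shots (including new classes) without
revisiting old data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classify import NONE_OF_THE_ABOVE, TemplateStore, classify
from .datasets import SensorSample
from .network import (
    DEFAULT_INPUT_GAIN,
    DEFAULT_THETA_JITTER,
    build_network,
    infer,
    train_shot,
)


class EPLffClassifier(ClassifierMixin, BaseEstimator):
    """Spiking olfactory-bulb classifier with a none-of-the-above outcome.

    Parameters
    ----------
    n_gc : int
        Granule-cell count (code length).
    cp : float
        MC->GC connection probability.
    metric : {"hamming", "hamming_length", "overlap"}
        Template similarity criterion.
    threshold : float
        Confidence bound: best Hamming distance above it (or best overlap
        below it) yields :data:`~eplff.classify.NONE_OF_THE_ABOVE`.
    input_gain : float
        Scales the normalized input into MC currents.
    mc_params, gc_params, kernel, clock, stdp : frozen dataclasses or None
        Cell/synapse/clock/plasticity constants; None selects the
        calibrated defaults.
    theta_jitter : (float, float)
        Uniform per-GC threshold heterogeneity band.
    random_state : int or None
        Seed for topology and thresholds.

    Attributes
    ----------
    network_ : EPLffNetwork
    store_ : TemplateStore
    classes_ : ndarray of trained labels, in training order
    """

    def __init__(
        self,
        n_gc: int = 4800,
        cp: float = 0.4,
        metric: str = "hamming",
        threshold: float = 0.5,
        input_gain: float = DEFAULT_INPUT_GAIN,
        n_cycles: int = 1,
        mc_params=None,
        gc_params=None,
        kernel=None,
        clock=None,
        stdp=None,
        theta_jitter: tuple[float, float] = DEFAULT_THETA_JITTER,
        random_state: int | None = None,
    ):
        self.n_gc = n_gc
        self.cp = cp
        self.metric = metric
        self.threshold = threshold
        self.input_gain = input_gain
        self.n_cycles = n_cycles
        self.mc_params = mc_params
        self.gc_params = gc_params
        self.kernel = kernel
        self.clock = clock
        self.stdp = stdp
        self.theta_jitter = theta_jitter
        self.random_state = random_state

    # -- internals --------------------------------------------------------
    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if np.any(X < 0):
            raise ValueError("sensor responses must be non-negative")
        return X

    def _build(self, n_sensors: int) -> None:
        from .spiking import DEFAULT_GC_PARAMS, DEFAULT_MC_PARAMS

        kwargs = {}
        if self.kernel is not None:
            kwargs["kernel"] = self.kernel
        if self.clock is not None:
            kwargs["clock"] = self.clock
        if self.stdp is not None:
            kwargs["stdp"] = self.stdp
        self.network_ = build_network(
            n_sensors,
            n_gc=self.n_gc,
            cp=self.cp,
            seed=0 if self.random_state is None else self.random_state,
            mc_params=self.mc_params or DEFAULT_MC_PARAMS,
            gc_params=self.gc_params or DEFAULT_GC_PARAMS,
            input_gain=self.input_gain,
            theta_jitter=self.theta_jitter,
            n_cycles=self.n_cycles,
            **kwargs,
        )
        self.store_ = TemplateStore()
        self._scale = np.ones(n_sensors)  # identity: X is already scaled
        self.n_features_in_ = n_sensors

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        """Train from scratch, presenting (X[i], y[i]) in the given order."""
        X = self._validate(X)
        self._build(X.shape[1])
        return self.partial_fit(X, y)

    def partial_fit(self, X, y, classes=None):
        """Add training shots online; new labels become new classes."""
        X = self._validate(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if not hasattr(self, "network_"):
            self._build(X.shape[1])
        for row, label in zip(X, y):
            sample = SensorSample(features=row, label=str(label))
            train_shot(self.network_, sample, self._scale, self.store_)
        self.classes_ = np.array(self.store_.labels(), dtype=object)
        return self

    def gc_codes(self, X) -> np.ndarray:
        """GC binary code matrix (n_samples, n_gc) for scaled inputs."""
        check_is_fitted(self, "network_")
        X = self._validate(X)
        return np.stack(
            [infer(self.network_, SensorSample(features=row), self._scale).bits for row in X]
        )

    def predict(self, X):
        """Nearest-template labels; ``"none_of_the_above"`` when no stored
        template is within the confidence threshold."""
        check_is_fitted(self, "store_")
        codes = self.gc_codes(X)
        return np.array(
            [
                classify(c, self.store_, threshold=self.threshold, metric=self.metric).predicted
                for c in codes
            ],
            dtype=object,
        )

    def decision_distance(self, X) -> np.ndarray:
        """Best template distance per sample (lower = more confident)."""
        check_is_fitted(self, "store_")
        codes = self.gc_codes(X)
        return np.array(
            [
                classify(c, self.store_, threshold=self.threshold, metric=self.metric).best_distance
                for c in codes
            ]
        )

    def reset(self) -> "EPLffClassifier":
        """Reset learning: weights back to w_0, templates cleared (the
        drift-mitigation move); topology and thresholds are kept."""
        check_is_fitted(self, "network_")
        self.network_.reset()
        self.store_.clear()
        self.classes_ = np.array([], dtype=object)
        return self

    def score(self, X, y):
        """Accuracy over the given samples (NOTA counts as an error)."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))


__all__ = ["EPLffClassifier", "NONE_OF_THE_ABOVE"]
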