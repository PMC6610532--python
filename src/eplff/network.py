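"""EPLff network assembly and the train / infer lifecycle.

One column per sensor: a mitral cell (MC) driven by the preprocessed
response of its sensor, projecting with connection probability ``cp`` onto
a shared population of granule cells (GCs).  GC spike thresholds are
heterogeneous (uniform jitter around a base value), which spreads the
effective coincidence requirement across the population and implements a
soft k-winners-take-all readout.  The GC spiked/not-spiked binary vector
from a plasticity-frozen cycle is the representation used for
classification; plasticity is active only during training presentations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plasticity import STDPParams, apply_stdp, reset_weight_matrix
from .preprocess import preprocess
from .spiking import (
    DEFAULT_GC_PARAMS,
    DEFAULT_MC_PARAMS,
    CycleResult,
    GammaClock,
    NeuronParams,
    SynapseKernel,
    simulate_cycle,
)

#: multiplies the unit-norm input direction (see :func:`_mc_currents`) into
#: MC input currents; calibrated so a typical profile's strongest sensors
#: fire in the first few ms of the cycle while sub-20% sensors stay silent.
DEFAULT_INPUT_GAIN = 6.5

#: per-GC threshold jitter band (uniform), as multiples of the base v_th.
#: The wide band spreads coincidence requirements from ~2 near-synchronous
#: presynaptic spikes up to strong many-way coincidence, so the active code
#: fraction varies only slowly with overall drive (the emergent soft
#: k-winners-take-all) instead of saturating or vanishing.
DEFAULT_THETA_JITTER: tuple[float, float] = (0.55, 5.0)


@dataclass
class GCBinaryVector:
    """Length-n_gc 0/1 spike/no-spike code; the unit of classification."""

    bits: np.ndarray
    source_label: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("code bits must be 0 or 1")

    @property
    def n_gc(self) -> int:
        return self.bits.shape[0]

    @property
    def active_fraction(self) -> float:
        return float(self.bits.mean()) if self.bits.size else 0.0


@dataclass
class EPLffNetwork:
    """Sparse MC -> GC topology with plastic weights and fixed cell params."""

    n_sensors: int
    n_gc: int
    adjacency: np.ndarray  # (n_mc, n_gc) bool
    weights: np.ndarray  # (n_mc, n_gc) float, zero off-edges
    gc_v_th: np.ndarray  # (n_gc,)
    mc_params: NeuronParams = DEFAULT_MC_PARAMS
    gc_params: NeuronParams = DEFAULT_GC_PARAMS
    kernel: SynapseKernel = field(default_factory=SynapseKernel)
    clock: GammaClock = field(default_factory=GammaClock)
    stdp: STDPParams = field(default_factory=STDPParams)
    input_gain: float = DEFAULT_INPUT_GAIN
    n_cycles: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.adjacency.shape != (self.n_sensors, self.n_gc):
            raise ValueError("adjacency shape mismatch")
        if self.weights.shape != self.adjacency.shape:
            raise ValueError("weights shape mismatch")
        if np.any(self.weights[~self.adjacency] != 0):
            raise ValueError("weights present off the adjacency edges")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def reset(self) -> "EPLffNetwork":
        """All synapses back to w_0 (topology and thresholds untouched)."""
        self.weights = reset_weight_matrix(self.weights, self.adjacency, self.stdp.w_0)
        return self

    def run_cycle(self, mc_inputs: np.ndarray, **kwargs) -> CycleResult:
        return simulate_cycle(
            mc_inputs,
            self.weights,
            mc_params=self.mc_params,
            gc_v_th=self.gc_v_th,
            gc_params=self.gc_params,
            kernel=self.kernel,
            clock=self.clock,
            n_cycles=self.n_cycles,
            **kwargs,
        )

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        header = {
            "n_sensors": self.n_sensors,
            "n_gc": self.n_gc,
            "rng_seed": self.rng_seed,
            "input_gain": self.input_gain,
            "n_cycles": self.n_cycles,
            "mc_params": vars(self.mc_params),
            "gc_params": vars(self.gc_params),
            "kernel": vars(self.kernel),
            "clock": vars(self.clock),
            "stdp": vars(self.stdp),
        }
        (d / "header.json").write_text(json.dumps(header, indent=2))
        mc_idx, gc_idx = np.nonzero(self.adjacency)
        with open(d / "weights.csv", "w") as fh:
            fh.write("mc_id,gc_id,weight\n")
            for m, g in zip(mc_idx, gc_idx):
                fh.write(f"{m},{g},{self.weights[m, g]:.17g}\n")
        np.savetxt(d / "thresholds.csv", self.gc_v_th, delimiter=",")

    @classmethod
    def load(cls, directory: str | Path) -> "EPLffNetwork":
        d = Path(directory)
        header = json.loads((d / "header.json").read_text())
        n_mc, n_gc = header["n_sensors"], header["n_gc"]
        adjacency = np.zeros((n_mc, n_gc), dtype=bool)
        weights = np.zeros((n_mc, n_gc))
        trip = np.loadtxt(d / "weights.csv", delimiter=",", skiprows=1, ndmin=2)
        for m, g, w in trip:
            adjacency[int(m), int(g)] = True
            weights[int(m), int(g)] = w
        gc_v_th = np.loadtxt(d / "thresholds.csv", delimiter=",")
        return cls(
            n_sensors=n_mc,
            n_gc=n_gc,
            adjacency=adjacency,
            weights=weights,
            gc_v_th=gc_v_th,
            mc_params=NeuronParams(**header["mc_params"]),
            gc_params=NeuronParams(**header["gc_params"]),
            kernel=SynapseKernel(**header["kernel"]),
            clock=GammaClock(**header["clock"]),
            stdp=STDPParams(**header["stdp"]),
            input_gain=header["input_gain"],
            n_cycles=header["n_cycles"],
            rng_seed=header["rng_seed"],
        )


def build_network(
    n_sensors: int,
    n_gc: int = 4800,
    cp: float = 0.4,
    seed: int = 0,
    mc_params: NeuronParams = DEFAULT_MC_PARAMS,
    gc_params: NeuronParams = DEFAULT_GC_PARAMS,
    kernel: SynapseKernel | None = None,
    clock: GammaClock | None = None,
    stdp: STDPParams | None = None,
    input_gain: float = DEFAULT_INPUT_GAIN,
    theta_jitter: tuple[float, float] = DEFAULT_THETA_JITTER,
    n_cycles: int = 1,
) -> EPLffNetwork:
    """Random MC -> GC topology: each pair connected independently with
    probability ``cp`` at uniform initial weight w_0; per-GC thresholds
    drawn uniformly in ``theta_jitter`` x the base threshold."""
    if not 0 < cp <= 1:
        raise ValueError("cp must be in (0, 1]")
    if n_gc < 1:
        raise ValueError("n_gc must be >= 1")
    kernel = kernel or SynapseKernel()
    clock = clock or GammaClock()
    stdp = stdp or STDPParams()
    rng = np.random.default_rng(seed)
    adjacency = rng.random((n_sensors, n_gc)) < cp
    weights = np.where(adjacency, stdp.w_0, 0.0)
    lo, hi = theta_jitter
    gc_v_th = gc_params.v_th * rng.uniform(lo, hi, size=n_gc)
    return EPLffNetwork(
        n_sensors=n_sensors,
        n_gc=n_gc,
        adjacency=adjacency,
        weights=weights,
        gc_v_th=gc_v_th,
        mc_params=mc_params,
        gc_params=gc_params,
        kernel=kernel,
        clock=clock,
        stdp=stdp,
        input_gain=input_gain,
        n_cycles=n_cycles,
        rng_seed=seed,
    )


def _mc_currents(network: EPLffNetwork, sample, scale: np.ndarray) -> np.ndarray:
    """Constant MC input currents for one presentation.

    The concentration-tolerant normalized vector fixes the input
    *direction*; rescaling it to unit L2 norm before applying the gain
    equalizes overall drive across odorants (a contrast normalization).
    Without it, broadly tuned profiles — whose sum-normalized entries are
    individually small — would drive far fewer spikes than peaked profiles
    of identical signal quality.  Both steps are scale-invariant, so
    concentration tolerance is preserved.
    """
    pre = preprocess(sample, scale)
    direction = pre.normalized
    norm = float(np.linalg.norm(direction))
    if norm > 0:
        direction = direction / norm
    return direction * network.input_gain


def train_shot(
    network: EPLffNetwork,
    sample,
    scale: np.ndarray,
    store=None,
) -> tuple[EPLffNetwork, GCBinaryVector]:
    """One training presentation: a plasticity-ON gamma cycle updates the
    weights, then a plasticity-OFF cycle on the same input records the GC
    binary template, which is appended to ``store`` (if given) under the
    sample's label."""
    currents = _mc_currents(network, sample, scale)
    learn = network.run_cycle(currents)
    network.weights = apply_stdp(
        learn.mc_spike_times,
        learn.gc_first_spike,
        network.weights,
        network.stdp,
        adjacency=network.adjacency,
        period=network.clock.period,
        n_cycles=network.n_cycles,
    )
    frozen = network.run_cycle(currents)
    label = getattr(sample, "label", None)
    code = GCBinaryVector(bits=frozen.gc_code, source_label=label)
    if store is not None:
        store.add(label, code)
    return network, code


def infer(network: EPLffNetwork, sample, scale: np.ndarray) -> GCBinaryVector:
    """Plasticity-OFF presentation; the network is left unchanged."""
    currents = _mc_currents(network, sample, scale)
    result = network.run_cycle(currents)
    return GCBinaryVector(bits=result.gc_code, source_label=getattr(sample, "label", None))
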