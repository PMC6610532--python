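"""Leaky integrate-and-fire dynamics under a gamma-band shunting clock.

Mitral cells (MCs) receive constant preprocessed sensor input and are
periodically shunted by a 40 Hz sinusoid, so that stronger inputs cross
threshold at earlier phases of each gamma cycle (*spike precedence
coding*).  Granule cells (GCs) are driven by double-exponential AMPA-like
conductances from their presynaptic MCs and report a binary spiked /
not-spiked code per stimulus.

Integration is forward Euler at a 0.01 ms update period.  Membrane
variables use a dimensionless convention: the reset potential is 0, the
membrane resistance of the dynamics is r_m (divided by the shunt for MCs),
and only the synaptic reversal potential carries units (+70 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class GammaClock:
    """Sinusoidal shunting inhibition: r_shunt(t) = -A cos(2 pi f t / 1000) + B."""

    f: float = 40.0  # Hz
    dt: float = 0.01  # ms
    amplitude: float = 3.8
    offset: float = 5.0

    def __post_init__(self) -> None:
        if self.offset - self.amplitude <= 0:
            raise ValueError("r_shunt must stay positive over the cycle")
        if self.dt <= 0 or self.f <= 0:
            raise ValueError("dt and f must be positive")

    @property
    def period(self) -> float:
        """Gamma period in ms."""
        return 1000.0 / self.f

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    def r_shunt(self, t) -> np.ndarray | float:
        return -self.amplitude * np.cos(2.0 * np.pi * self.f * np.asarray(t) / 1000.0) + self.offset


def gamma_shunt(t, clock: GammaClock = GammaClock()) -> np.ndarray | float:
    """Shunt magnitude at time ``t`` (ms)."""
    return clock.r_shunt(t)


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants.  ``is_mc`` selects the shunted drive R = r_m / r_shunt(t)
    (mitral cells); otherwise R = r_m (granule cells)."""

    c_m: float
    r_m: float
    v_th: float
    v_reset: float = 0.0
    is_mc: bool = False

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.r_m <= 0:
            raise ValueError("c_m and r_m must be positive")
        if self.v_th <= self.v_reset:
            raise ValueError("v_th must exceed v_reset")

    @property
    def tau(self) -> float:
        """Membrane time constant r_m * c_m (ms)."""
        return self.r_m * self.c_m


#: MC defaults: tau = 5 ms; with the calibrated input gain the strongest
#: sensor's MC fires within the first ~2 ms of the cycle, mid-range inputs
#: fire progressively later, and inputs below ~20% of the maximum stay
#: silent as the shunt rises.
DEFAULT_MC_PARAMS = NeuronParams(c_m=5.0, r_m=1.0, v_th=0.5, is_mc=True)

#: GC defaults: tau = 2 ms; v_th is the *base* threshold, jittered per GC
#: (see the network's theta_jitter).  One unit-weight spike peaks the
#: membrane at ~0.45 x this base, so even the most excitable GCs need at
#: least two near-coincident presynaptic spikes.
DEFAULT_GC_PARAMS = NeuronParams(c_m=2.0, r_m=1.0, v_th=0.5, is_mc=False)


@dataclass(frozen=True)
class SynapseKernel:
    """Double-exponential AMPA-like conductance.

    g(t) = g_max * tau1*tau2/(tau1 - tau2) * (exp(-(t-ti)/tau1) - exp(-(t-ti)/tau2))

    vanishes at the presynaptic spike time and decays back to 0; its peak
    sits at tau1*tau2/(tau1-tau2) * ln(tau1/tau2) after the spike.
    """

    g_max: float = 0.01
    tau1: float = 2.0  # ms (decay)
    tau2: float = 1.0  # ms (rise)
    E_n: float = 70.0  # mV, excitatory reversal potential

    def __post_init__(self) -> None:
        if self.tau1 == self.tau2:
            raise ValueError("tau1 and tau2 must differ (double-exponential kernel)")
        if self.g_max < 0 or self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("g_max, tau1, tau2 must be positive")

    @property
    def peak_time(self) -> float:
        t1, t2 = self.tau1, self.tau2
        return t1 * t2 / (t1 - t2) * np.log(t1 / t2)

    def evaluate(self, dt_since_spike) -> np.ndarray | float:
        """Unit-weight conductance ``dt_since_spike`` ms after a spike
        (0 for negative arguments)."""
        d = np.asarray(dt_since_spike, dtype=float)
        t1, t2 = self.tau1, self.tau2
        val = self.g_max * t1 * t2 / (t1 - t2) * (np.exp(-d / t1) - np.exp(-d / t2))
        return np.where(d < 0, 0.0, val)


@dataclass
class SpikeRecord:
    """Spike times (ms) of one neuron within a presentation."""

    neuron_id: int
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    @property
    def first(self) -> float:
        return float(self.spike_times[0]) if self.spike_times.size else np.inf


# ---------------------------------------------------------------------------
# Single-neuron stepping
# ---------------------------------------------------------------------------

def step_lif(
    v: float,
    I: float,
    params: NeuronParams,
    t: float,
    clock: GammaClock,
    dt: float | None = None,
) -> tuple[float, bool]:
    """One forward-Euler step of dv/dt = (-v + I R) / tau.

    Returns the updated potential and whether the neuron spiked (in which
    case the potential has been reset).
    """
    if dt is None:
        dt = clock.dt
    if not (np.isfinite(v) and np.isfinite(I)):
        raise ValueError("non-finite membrane potential or current")
    R = params.r_m / clock.r_shunt(t) if params.is_mc else params.r_m
    v_new = v + dt * (-v + I * R) / params.tau
    if v_new >= params.v_th:
        return params.v_reset, True
    return v_new, False


def mc_spike_phase(
    input_current: float,
    params: NeuronParams = DEFAULT_MC_PARAMS,
    clock: GammaClock = GammaClock(),
    n_cycles: int = 1,
    spikes_per_cycle: int | None = 1,
) -> SpikeRecord:
    """Simulate one MC at constant input under the gamma shunt; empty record
    if threshold is never reached."""
    times = _simulate_mc_population(
        np.array([float(input_current)]), params, clock, n_cycles, spikes_per_cycle
    )[0]
    return SpikeRecord(neuron_id=0, spike_times=times)


def gc_conductance(
    t: float,
    pre_spike_times: Sequence[float],
    weights: Sequence[float],
    kernel: SynapseKernel,
) -> float:
    """Total weighted conductance at time ``t`` from past presynaptic spikes."""
    total = 0.0
    for ti, w in zip(pre_spike_times, weights, strict=True):
        if w < 0:
            raise ValueError("synaptic weights must be non-negative")
        if ti <= t:
            total += w * float(kernel.evaluate(t - ti))
    return total


# ---------------------------------------------------------------------------
# Vectorized population simulation
# ---------------------------------------------------------------------------

def _simulate_mc_population(
    inputs: np.ndarray,
    params: NeuronParams,
    clock: GammaClock,
    n_cycles: int,
    spikes_per_cycle: int | None = 1,
) -> list[np.ndarray]:
    """Forward-Euler simulation of all MCs (constant input each) under the
    shunt; returns per-MC spike-time arrays.

    ``spikes_per_cycle`` caps how often each MC may fire within one gamma
    cycle (the phase code assigns one spike phase per cycle); after the
    cap the cell is held at reset until the next cycle begins.  ``None``
    removes the cap.
    """
    n = inputs.shape[0]
    steps_per_cycle = clock.steps_per_cycle
    n_steps = steps_per_cycle * n_cycles
    dt = clock.dt
    t_grid = np.arange(n_steps) * dt
    drive = params.r_m / clock.r_shunt(t_grid)  # R(t), shared by all MCs
    v = np.zeros(n)
    inv_tau = dt / params.tau
    fired_this_cycle = np.zeros(n, dtype=np.int64)
    spikes: list[list[float]] = [[] for _ in range(n)]
    for k in range(n_steps):
        if k % steps_per_cycle == 0:
            fired_this_cycle[:] = 0
        v += inv_tau * (-v + inputs * drive[k])
        crossed = v >= params.v_th
        if spikes_per_cycle is not None:
            refractory = fired_this_cycle >= spikes_per_cycle
            v[refractory] = params.v_reset
            crossed &= ~refractory
        if crossed.any():
            t_spike = t_grid[k] + dt
            for i in np.flatnonzero(crossed):
                spikes[i].append(t_spike)
            fired_this_cycle[crossed] += 1
            v[crossed] = params.v_reset
    return [np.array(s) for s in spikes]


@dataclass
class CycleResult:
    """Outcome of one presentation: spike times and the GC binary code."""

    mc_spike_times: list[np.ndarray]
    gc_first_spike: np.ndarray  # (n_gc,), inf where silent
    gc_spike_counts: np.ndarray  # (n_gc,) int
    gc_spike_times: list[np.ndarray] | None = None

    @property
    def gc_code(self) -> np.ndarray:
        """Binary spiked/not-spiked vector over GCs."""
        return (self.gc_spike_counts > 0).astype(np.int8)

    def mc_records(self) -> list[SpikeRecord]:
        return [SpikeRecord(i, t) for i, t in enumerate(self.mc_spike_times)]

    def gc_records(self) -> list[SpikeRecord]:
        if self.gc_spike_times is None:
            raise ValueError("GC spike trains were not recorded")
        return [SpikeRecord(i, t) for i, t in enumerate(self.gc_spike_times)]


def _mc_kernel_series(
    mc_spike_times: list[np.ndarray],
    kernel: SynapseKernel,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Unit-weight conductance time series of each MC, (n_mc, n_steps)."""
    n_mc = len(mc_spike_times)
    K = np.zeros((n_mc, t_grid.shape[0]))
    for m, times in enumerate(mc_spike_times):
        for ti in times:
            start = int(np.searchsorted(t_grid, ti))
            K[m, start:] += kernel.evaluate(t_grid[start:] - ti)
    return K


def simulate_cycle(
    mc_inputs: np.ndarray,
    weights: np.ndarray,
    mc_params: NeuronParams = DEFAULT_MC_PARAMS,
    gc_v_th: np.ndarray | None = None,
    gc_params: NeuronParams = DEFAULT_GC_PARAMS,
    kernel: SynapseKernel = SynapseKernel(),
    clock: GammaClock = GammaClock(),
    n_cycles: int = 1,
    mc_spikes_per_cycle: int | None = 1,
    record_gc_trains: bool = False,
    _time_block: int = 640,
) -> CycleResult:
    """Simulate MCs then GCs for ``n_cycles`` gamma cycles.

    ``mc_inputs``: constant input current per MC (one per sensor column);
    ``weights``: (n_mc, n_gc) excitatory weight matrix; ``gc_v_th``:
    per-GC spike thresholds (defaults to ``gc_params.v_th`` for all).
    """
    mc_inputs = np.asarray(mc_inputs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != mc_inputs.shape[0]:
        raise ValueError(
            f"weights shape {weights.shape} incompatible with "
            f"{mc_inputs.shape[0]} MC inputs"
        )
    n_gc = weights.shape[1]
    if gc_v_th is None:
        gc_v_th = np.full(n_gc, gc_params.v_th)
    gc_v_th = np.asarray(gc_v_th, dtype=float)
    if gc_v_th.shape != (n_gc,):
        raise ValueError("gc_v_th must have one threshold per GC")
    if np.any(mc_inputs < 0):
        raise ValueError("MC input currents must be non-negative")

    n_steps = clock.steps_per_cycle * n_cycles
    dt = clock.dt
    t_grid = np.arange(n_steps) * dt

    mc_spikes = _simulate_mc_population(
        mc_inputs, mc_params, clock, n_cycles, mc_spikes_per_cycle
    )

    gc_first = np.full(n_gc, np.inf)
    gc_counts = np.zeros(n_gc, dtype=np.int64)
    gc_trains: list[list[float]] | None = [[] for _ in range(n_gc)] if record_gc_trains else None

    if not any(t.size for t in mc_spikes):
        return CycleResult(
            mc_spike_times=mc_spikes,
            gc_first_spike=gc_first,
            gc_spike_counts=gc_counts,
            gc_spike_times=[np.empty(0)] * n_gc if record_gc_trains else None,
        )

    K = _mc_kernel_series(mc_spikes, kernel, t_grid)

    v = np.zeros(n_gc)
    inv_tau = dt / gc_params.tau
    r_m = gc_params.r_m
    E_n = kernel.E_n
    # conductance matrix materialized blockwise to bound memory at large n_gc
    for start in range(0, n_steps, _time_block):
        stop = min(start + _time_block, n_steps)
        G = weights.T @ K[:, start:stop]  # (n_gc, block)
        for j in range(stop - start):
            I = G[:, j] * (E_n - v)
            v += inv_tau * (-v + I * r_m)
            crossed = v >= gc_v_th
            if crossed.any():
                t_spike = t_grid[start + j] + dt
                idx = np.flatnonzero(crossed)
                first_mask = np.isinf(gc_first[idx])
                gc_first[idx[first_mask]] = t_spike
                gc_counts[idx] += 1
                if gc_trains is not None:
                    for i in idx:
                        gc_trains[i].append(t_spike)
                v[crossed] = gc_params.v_reset
    return CycleResult(
        mc_spike_times=mc_spikes,
        gc_first_spike=gc_first,
        gc_spike_counts=gc_counts,
        gc_spike_times=[np.array(s) for s in gc_trains] if gc_trains is not None else None,
    )


def export_spike_csv(records: Sequence[SpikeRecord], path) -> None:
    """Two-column (neuron_id, time_ms) CSV of spike events, for debugging."""
    with open(path, "w") as fh:
        fh.write("neuron_id,time_ms\n")
        for rec in records:
            for t in rec.spike_times:
                fh.write(f"{rec.neuron_id},{t:.5f}\n")
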