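"""Spike timing-dependent plasticity of the MC -> GC excitatory synapses.

Updates are gated by postsynaptic GC spikes.  A presynaptic MC spike that
precedes the GC spike within the same gamma cycle potentiates the synapse
exponentially in the timing difference; an MC spike that follows the GC
spike — or an entirely silent MC — depresses it (a silent MC incurs the
full decrement).  Weights live in [0, w_max].

At the default (saturating) learning rate a single pairing drives a weight
all the way to its bound, so after one training cycle every synapse holds
one of at most three values: 0, w_0 or w_max.  With the default
w_max = w_0 setting, learning reduces to long-term depression — the
configuration that online learning favors, since potentiation beyond the
initial weight is unnecessary when classification reads a binary code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class STDPParams:
    """STDP constants.

    ``eta`` is the learning rate; the default is saturating: one causal
    pairing anywhere in a 25 ms gamma cycle reaches w_max, one acausal or
    unpaired GC spike reaches 0.  ``a_plus``/``a_minus`` are the
    potentiation/depression amplitudes, ``tau_plus``/``tau_minus`` the
    timing constants (ms).  ``w_0`` is the initial weight, ``w_max`` the
    ceiling; ``w_max == w_0`` (default) gives the depression-only regime.
    """

    eta: float = 1000.0
    a_plus: float = 1.0
    a_minus: float = 1.0
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    w_max: float = 1.0
    w_0: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.w_0 <= self.w_max:
            raise ValueError("need 0 <= w_0 <= w_max")
        if min(self.eta, 0.0) < 0 or self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("eta must be >= 0; amplitudes positive")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("timing constants must be positive")

    def is_saturating(self, cycle_period: float = 25.0) -> bool:
        """Whether a single worst-case pairing within one cycle saturates."""
        pot = self.eta * self.a_plus * np.exp(-cycle_period / self.tau_plus)
        dep = self.eta * self.a_minus * np.exp(-cycle_period / self.tau_minus)
        return bool(pot >= self.w_max and dep >= self.w_max)


#: marker for "the presynaptic MC never spiked in this cycle"
ABSENT = None


def stdp_delta(
    pre_time: float | None,
    post_time: float,
    w: float,
    params: STDPParams,
) -> float:
    """Updated weight for one synapse given one GC spike.

    ``pre_time`` is the presynaptic MC's first spike in the GC spike's
    gamma cycle, or :data:`ABSENT`/inf if the MC was silent (full
    decrement).
    """
    if not 0 <= w <= params.w_max:
        raise ValueError(f"weight {w} outside [0, {params.w_max}]")
    absent = pre_time is ABSENT or not np.isfinite(pre_time)
    if not absent and pre_time < post_time:
        dw = params.eta * params.a_plus * np.exp(-(post_time - pre_time) / params.tau_plus)
        return min(w + dw, params.w_max)
    if absent:
        dw = params.eta * params.a_minus
    else:
        dw = params.eta * params.a_minus * np.exp(-abs(pre_time - post_time) / params.tau_minus)
    return max(w - dw, 0.0)


def _first_spike_per_cycle(
    mc_spike_times: list[np.ndarray], n_cycles: int, period: float
) -> np.ndarray:
    """(n_mc, n_cycles) array of each MC's first spike time per gamma cycle
    (inf where silent).  A spike recorded exactly on a cycle boundary
    belongs to the cycle it terminates."""
    n_mc = len(mc_spike_times)
    first = np.full((n_mc, n_cycles), np.inf)
    for m, times in enumerate(mc_spike_times):
        for t in times:
            c = min(int(np.ceil(t / period)) - 1, n_cycles - 1)
            c = max(c, 0)
            if t < first[m, c]:
                first[m, c] = t
    return first


def apply_stdp(
    mc_spike_times: list[np.ndarray],
    gc_first_spike: np.ndarray,
    weights: np.ndarray,
    params: STDPParams,
    adjacency: np.ndarray | None = None,
    period: float = 25.0,
    n_cycles: int = 1,
) -> np.ndarray:
    """Apply the STDP rule after one presentation; returns a new matrix.

    Every GC that spiked updates all of its incoming synapses via
    :func:`stdp_delta`, pairing with each MC's first spike in the gamma
    cycle of the GC's own first spike.  Silent GCs leave their synapses
    untouched.
    """
    weights = np.asarray(weights, dtype=float)
    gc_first_spike = np.asarray(gc_first_spike, dtype=float)
    if weights.shape != (len(mc_spike_times), gc_first_spike.shape[0]):
        raise ValueError("weights shape inconsistent with spike records")
    if np.any(weights < 0) or np.any(weights > params.w_max):
        raise ValueError("weights outside [0, w_max] on entry")
    if adjacency is None:
        adjacency = np.ones_like(weights, dtype=bool)

    active = np.flatnonzero(np.isfinite(gc_first_spike))
    new_w = weights.copy()
    if active.size == 0:
        return new_w

    t_g = gc_first_spike[active]  # (n_active,)
    cyc = np.clip(np.ceil(t_g / period).astype(int) - 1, 0, n_cycles - 1)
    mc_first = _first_spike_per_cycle(mc_spike_times, n_cycles, period)
    t_m = mc_first[:, cyc]  # (n_mc, n_active)

    causal = t_m < t_g[None, :]
    silent = np.isinf(t_m)
    with np.errstate(invalid="ignore"):
        pot = params.eta * params.a_plus * np.exp(-(t_g[None, :] - t_m) / params.tau_plus)
        dep_timed = params.eta * params.a_minus * np.exp(
            -np.abs(np.where(silent, 0.0, t_m) - t_g[None, :]) / params.tau_minus
        )
    dep = np.where(silent, params.eta * params.a_minus, dep_timed)

    w_cols = new_w[:, active]
    updated = np.where(
        causal,
        np.minimum(w_cols + pot, params.w_max),
        np.maximum(w_cols - dep, 0.0),
    )
    mask = adjacency[:, active]
    new_w[:, active] = np.where(mask, updated, w_cols)
    return new_w


def reset_weight_matrix(
    weights: np.ndarray, adjacency: np.ndarray, w_0: float
) -> np.ndarray:
    """Every existing synapse back to w_0; non-edges stay 0."""
    return np.where(adjacency, w_0, 0.0)


def reset_weights(network) -> "object":
    """Reset a network's synaptic weights to their untrained value w_0,
    leaving topology and thresholds untouched.  Mutates and returns the
    network; the caller clears any learned template store."""
    network.weights = reset_weight_matrix(
        network.weights, network.adjacency, network.stdp.w_0
    )
    return network
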