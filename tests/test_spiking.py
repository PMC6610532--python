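import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eplff.spiking import (
    DEFAULT_GC_PARAMS,
    DEFAULT_MC_PARAMS,
    GammaClock,
    NeuronParams,
    SynapseKernel,
    gamma_shunt,
    gc_conductance,
    mc_spike_phase,
    simulate_cycle,
    step_lif,
)


class TestGammaClock:
    def test_shunt_extremes(self):
        clock = GammaClock()
        assert gamma_shunt(0.0, clock) == pytest.approx(1.2)
        assert gamma_shunt(12.5, clock) == pytest.approx(8.8)
        assert gamma_shunt(25.0, clock) == pytest.approx(1.2)

    def test_period(self):
        assert GammaClock().period == pytest.approx(25.0)
        assert GammaClock().steps_per_cycle == 2500

    def test_validation(self):
        with pytest.raises(ValueError):
            GammaClock(amplitude=6.0, offset=5.0)  # shunt would cross zero
        with pytest.raises(ValueError):
            GammaClock(dt=0.0)


class TestNeuronParams:
    def test_tau(self):
        assert NeuronParams(c_m=5.0, r_m=2.0, v_th=1.0).tau == pytest.approx(10.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            NeuronParams(c_m=0.0, r_m=1.0, v_th=1.0)
        with pytest.raises(ValueError):
            NeuronParams(c_m=1.0, r_m=1.0, v_th=0.0, v_reset=0.0)


class TestStepLif:
    def test_relaxes_toward_ir(self):
        params = NeuronParams(c_m=2.0, r_m=1.0, v_th=10.0)
        clock = GammaClock()
        v = 0.0
        for k in range(5000):
            v, spiked = step_lif(v, 0.4, params, t=k * clock.dt, clock=clock)
            assert not spiked
        assert v == pytest.approx(0.4, rel=1e-3)

    def test_spike_resets(self):
        params = NeuronParams(c_m=2.0, r_m=1.0, v_th=0.1)
        v, spiked = step_lif(0.099, 100.0, params, t=0.0, clock=GammaClock())
        assert spiked and v == params.v_reset

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            step_lif(np.nan, 1.0, DEFAULT_GC_PARAMS, 0.0, GammaClock())


class TestMcSpikePhase:
    def test_zero_input_silent(self):
        assert mc_spike_phase(0.0).spike_times.size == 0

    def test_one_spike_per_cycle_cap(self):
        rec = mc_spike_phase(8.0, n_cycles=3)
        assert rec.spike_times.size == 3
        cycles = np.floor((rec.spike_times - 1e-9) / 25.0)
        assert np.array_equal(np.unique(cycles), [0, 1, 2])

    def test_uncapped_fires_more(self):
        capped = mc_spike_phase(8.0, spikes_per_cycle=1)
        free = mc_spike_phase(8.0, spikes_per_cycle=None)
        assert free.spike_times.size > capped.spike_times.size

    def test_stronger_input_fires_earlier(self):
        weak = mc_spike_phase(2.0).first
        strong = mc_spike_phase(6.0).first
        assert strong < weak


class TestSynapseKernel:
    def test_peak_time_formula(self):
        k = SynapseKernel()
        t = np.linspace(0, 10, 10001)
        g = k.evaluate(t)
        assert t[np.argmax(g)] == pytest.approx(k.peak_time, abs=1e-2)

    def test_zero_before_spike(self):
        assert SynapseKernel().evaluate(-0.5) == 0.0
        assert SynapseKernel().evaluate(0.0) == pytest.approx(0.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            SynapseKernel(tau1=2.0, tau2=2.0)
        with pytest.raises(ValueError):
            SynapseKernel(g_max=-1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(0.01, 50.0))
    def test_nonnegative(self, d):
        assert SynapseKernel().evaluate(d) >= 0.0


class TestGcConductance:
    def test_weighted_sum(self):
        k = SynapseKernel()
        g = gc_conductance(3.0, [1.0, 2.0], [2.0, 1.0], k)
        expected = 2.0 * k.evaluate(2.0) + 1.0 * k.evaluate(1.0)
        assert g == pytest.approx(float(expected))

    def test_future_spikes_ignored(self):
        k = SynapseKernel()
        assert gc_conductance(1.0, [5.0], [1.0], k) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            gc_conductance(1.0, [0.5], [-1.0], SynapseKernel())


class TestSimulateCycle:
    def test_shapes_and_binary_code(self):
        rng = np.random.default_rng(0)
        w = (rng.random((4, 30)) < 0.5) * 1.0
        res = simulate_cycle(np.array([6.0, 4.0, 2.0, 0.0]), w, gc_v_th=np.full(30, 0.3))
        assert res.gc_first_spike.shape == (30,)
        assert res.gc_spike_counts.shape == (30,)
        assert set(np.unique(res.gc_code)) <= {0, 1}
        assert np.all(np.isfinite(res.gc_first_spike) == (res.gc_code == 1))

    def test_no_mc_spikes_silent_gcs(self):
        res = simulate_cycle(np.zeros(3), np.ones((3, 5)))
        assert all(t.size == 0 for t in res.mc_spike_times)
        assert res.gc_spike_counts.sum() == 0

    def test_deterministic(self):
        w = np.ones((2, 10))
        a = simulate_cycle(np.array([5.0, 3.0]), w)
        b = simulate_cycle(np.array([5.0, 3.0]), w)
        np.testing.assert_array_equal(a.gc_code, b.gc_code)
        np.testing.assert_array_equal(a.gc_first_spike, b.gc_first_spike)

    def test_blockwise_equivalence(self):
        rng = np.random.default_rng(1)
        w = rng.random((3, 20))
        a = simulate_cycle(np.array([6.0, 4.0, 2.0]), w, _time_block=64)
        b = simulate_cycle(np.array([6.0, 4.0, 2.0]), w, _time_block=2500)
        np.testing.assert_array_equal(a.gc_first_spike, b.gc_first_spike)
        np.testing.assert_array_equal(a.gc_spike_counts, b.gc_spike_counts)

    def test_record_gc_trains(self):
        res = simulate_cycle(np.array([6.0]), np.ones((1, 4)), gc_v_th=np.full(4, 0.1), record_gc_trains=True)
        recs = res.gc_records()
        assert len(recs) == 4
        for i, r in enumerate(recs):
            assert r.spike_times.size == res.gc_spike_counts[i]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_cycle(np.array([1.0, 2.0]), np.ones((3, 4)))
        with pytest.raises(ValueError):
            simulate_cycle(np.array([-1.0]), np.ones((1, 2)))
        with pytest.raises(ValueError):
            simulate_cycle(np.array([1.0]), np.ones((1, 2)), gc_v_th=np.ones(3))


def test_euler_step_size_convergence():
    # halving the step repeatedly moves first-spike times by < 0.02 ms
    coarse = GammaClock(dt=0.01)
    fine = GammaClock(dt=0.001)
    for I in (2.0, 4.0, 8.0):
        t_coarse = mc_spike_phase(I, clock=coarse).first
        t_fine = mc_spike_phase(I, clock=fine).first
        assert np.isfinite(t_coarse) and np.isfinite(t_fine)
        assert abs(t_coarse - t_fine) < 0.02


def test_gc_spike_count_monotone_in_weight():
    # raising any synaptic weight never reduces a GC's spike count
    inputs = np.array([6.0, 4.0, 2.0])
    w_lo = np.full((3, 1), 0.5)
    w_hi = np.full((3, 1), 1.0)
    v_th = np.array([0.4])
    lo = simulate_cycle(inputs, w_lo, gc_v_th=v_th).gc_spike_counts[0]
    hi = simulate_cycle(inputs, w_hi, gc_v_th=v_th).gc_spike_counts[0]
    assert hi >= lo


def test_gc_spike_count_monotone_in_presynaptic_spikes():
    inputs_few = np.array([6.0, 0.0, 0.0])
    inputs_more = np.array([6.0, 5.0, 4.0])
    w = np.ones((3, 1))
    v_th = np.array([0.4])
    few = simulate_cycle(inputs_few, w, gc_v_th=v_th).gc_spike_counts[0]
    more = simulate_cycle(inputs_more, w, gc_v_th=v_th).gc_spike_counts[0]
    assert more >= few


def test_mc_defaults_document_tau():
    assert DEFAULT_MC_PARAMS.tau == pytest.approx(5.0)
    assert DEFAULT_GC_PARAMS.tau == pytest.approx(2.0)
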