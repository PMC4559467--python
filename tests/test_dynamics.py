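"""Simulation engine: exact integration, PSP calibration, refractoriness,
stimulation protocol, reproducibility."""

import numpy as np
import pytest
import scipy.sparse as sp

import drivernet as dn


def single_neuron_topology(n=1):
    return dn.Topology(n, 0)


def make_state(V, n=None):
    V = np.atleast_1d(np.asarray(V, dtype=float))
    n = n or V.size
    return dn.NetworkState(V.copy(), np.zeros(n), np.zeros(n), np.zeros(n))


class TestIntegration:
    def test_subthreshold_trajectory_matches_analytic_solution(self):
        # isolated neuron relaxing toward E_L + 5 mV: exact exponential
        topo = single_neuron_topology()
        state = make_state([-60.0])
        drive = dn.DriveSpec(depolarization=5.0)
        vs = []
        for _ in range(500):
            state, _ = dn.step_network(state, topo, drive)
            vs.append(state.V[0])
        t = np.arange(1, 501) * 0.1
        analytic = -55.0 + (-60.0 + 55.0) * np.exp(-t / 20.0)
        assert np.max(np.abs(np.array(vs) - analytic)) < 1e-6

    def test_suprathreshold_firing_period(self):
        # 11 mV drive: period ~ tau_ref + tau_m ln(11/1) ~ 50 ms -> ~20 Hz
        topo = single_neuron_topology()
        res = dn.run_simulation(topo, dn.DriveSpec(), 2000.0,
                                initial_state=make_state([-60.0]), seed=0)
        isi = np.diff(res.spikes.times)
        assert isi.mean() == pytest.approx(2.0 + 20.0 * np.log(11.0), abs=0.5)
        assert len(res.spikes) == pytest.approx(40, abs=2)

    def test_zero_drive_decays_to_leak_reversal(self):
        topo = single_neuron_topology()
        res = dn.run_simulation(topo, dn.DriveSpec(depolarization=0.0), 500.0,
                                initial_state=make_state([-52.0]), seed=0)
        assert len(res.spikes) == 0
        assert res.state.V[0] == pytest.approx(-60.0, abs=1e-4)

    def test_zero_duration_returns_initial_state(self):
        topo = single_neuron_topology()
        st = make_state([-53.0])
        res = dn.run_simulation(topo, dn.DriveSpec(), 0.0, initial_state=st)
        assert len(res.spikes) == 0
        assert res.state.V[0] == -53.0

    def test_superposition_of_psps(self):
        # linear current-based synapses: response to two inputs = sum of
        # individual responses
        def trace(w_a, w_b):
            topo = dn.Topology(3, 0)
            ee = sp.lil_matrix((3, 3))
            ee[0, 2] = w_a if w_a else 0
            ee[1, 2] = w_b if w_b else 0
            topo.w["ee"] = ee.tocsr()
            # source 0 spikes immediately; source 1 crosses ~15 ms later
            state = make_state([-49.9, -50.35, -60.0])
            drive = dn.DriveSpec(depolarization=10.2)
            vs = []
            for _ in range(600):
                state, _ = dn.step_network(
                    state, topo, drive)
                vs.append(state.V[2])
            return np.array(vs)

        base = trace(0.0, 0.0)
        va = trace(1.0, 0.0)
        vb = trace(0.0, 1.0)
        vab = trace(1.0, 1.0)
        assert np.max(np.abs((vab - base) - ((va - base) + (vb - base)))) < 1e-9

    def test_nonfinite_state_raises(self):
        topo = single_neuron_topology()
        st = make_state([np.nan])
        with pytest.raises(dn.DivergenceError):
            dn.step_network(st, topo, dn.DriveSpec())


class TestPSP:
    def test_unit_epsp_matches_published_calibration(self):
        peak = dn.psp_peak_amplitude("excitatory", 1.0)
        assert round(peak, 2) == 0.16
        assert peak == pytest.approx(0.1573, abs=5e-4)

    def test_unit_ipsp_matches_published_calibration(self):
        assert dn.psp_peak_amplitude("inhibitory", 1.0) == pytest.approx(
            -2.25, abs=1e-6)

    def test_zero_weight(self):
        assert dn.psp_peak_amplitude("excitatory", 0.0) == 0.0

    def test_linearity_in_weight(self):
        p1 = dn.psp_peak_amplitude("excitatory", 1.0)
        assert dn.psp_peak_amplitude("excitatory", 7.5) == pytest.approx(
            7.5 * p1)

    def test_degenerate_equal_time_constants(self):
        syn = dn.SynapseParams(tau_e=20.0)
        peak = dn.psp_peak_amplitude("excitatory", 1.0, synapse=syn)
        assert peak == pytest.approx(np.exp(-1.0), rel=1e-9)

    @pytest.mark.parametrize("kind,expected", [
        ("excitatory", 0.15749013123685915), ("inhibitory", -2.25)])
    def test_simulated_psp_matches_closed_form(self, kind, expected):
        topo = dn.Topology(2, 1)
        if kind == "excitatory":
            topo.w["ee"] = sp.csr_matrix(([1.0], ([0], [1])), shape=(2, 2))
            state = dn.NetworkState(np.array([-45.0, -60.0, -60.0]),
                                    np.zeros(3), np.zeros(3), np.zeros(3))
        else:
            topo.w["ie"] = sp.csr_matrix(([1.0], ([0], [1])), shape=(1, 2))
            state = dn.NetworkState(np.array([-60.0, -60.0, -45.0]),
                                    np.zeros(3), np.zeros(3), np.zeros(3))
        drive = dn.DriveSpec(depolarization=0.0)
        extreme = 0.0
        for _ in range(600):
            state, _ = dn.step_network(state, topo, drive)
            v = state.V[1] + 60.0
            extreme = max(extreme, abs(v))
        assert extreme == pytest.approx(abs(expected), rel=0.01)


class TestRefractoriness:
    def test_no_isi_below_refractory_period(self):
        topo = dn.build_random_topology(40, 10, 0.1, seed=2)
        topo = dn.init_weights(topo, "constant", {"value": 1.0}, 2)
        res = dn.run_simulation(topo, dn.DriveSpec(depolarization=13.0),
                                2000.0, seed=3)
        for times in res.spikes.by_neuron():
            if times.size > 1:
                assert np.diff(times).min() >= 2.0

    def test_spike_record_invariants(self):
        with pytest.raises(ValueError):
            dn.SpikeRecord([2.0, 1.0], [0, 1], 2, 0, 10.0)


class TestStimulation:
    def test_each_target_fires_exactly_two_close_spikes(self, small_topology):
        state = dn.NetworkState.initial(125, seed=4)
        targets = tuple(range(20))
        stim = dn.StimulusSpec(target_ids=targets)
        state, rec, ok = dn.apply_stimulus_protocol(state, small_topology,
                                                    stim)
        assert ok
        target_spikes = rec.ids[np.isin(rec.ids, targets)]
        assert target_spikes.size == 40
        for t in targets:
            times = rec.times[rec.ids == t]
            assert times.size == 2
            assert 2.0 <= times[1] - times[0] <= 2.4

    def test_empty_target_set(self, small_topology):
        state = dn.NetworkState.initial(125, seed=4)
        v0 = state.V.copy()
        state, rec, ok = dn.apply_stimulus_protocol(
            state, small_topology, dn.StimulusSpec(target_ids=()))
        assert ok and len(rec) == 0
        assert np.array_equal(state.V, v0)

    def test_refractory_target_aborts_without_state_change(self,
                                                           small_topology):
        state = dn.NetworkState.initial(125, seed=4)
        state.refractory_remaining[3] = 1.0  # spiked ~1 ms before onset
        v0 = state.V.copy()
        state, rec, ok = dn.apply_stimulus_protocol(
            state, small_topology, dn.StimulusSpec(target_ids=(1, 3, 5)))
        assert not ok and len(rec) == 0
        assert np.array_equal(state.V, v0)

    def test_weak_amplitude_rejected(self, small_topology):
        state = dn.NetworkState.initial(125, seed=4)
        with pytest.raises(ValueError):
            dn.apply_stimulus_protocol(
                state, small_topology,
                dn.StimulusSpec(target_ids=(0,), amplitude=50.0))


class TestDrive:
    def test_poisson_rate_matches_constant_drive_current(self):
        spec = dn.DriveSpec(mode="poisson")
        # 11 mV / (c_e * tau_e) = 2200 Hz
        assert spec.poisson_rate(dn.SynapseParams()) == pytest.approx(2200.0)

    def test_poisson_driven_neuron_fires(self):
        topo = single_neuron_topology()
        res = dn.run_simulation(topo, dn.DriveSpec(mode="poisson"), 5000.0,
                                seed=6)
        rate = len(res.spikes) / 5.0
        assert 8.0 < rate < 40.0  # noisy analogue of the 20 Hz constant case

    def test_divergence_guard(self):
        topo = single_neuron_topology()
        with pytest.raises(dn.DivergenceError):
            dn.run_simulation(topo, dn.DriveSpec(), 10_000.0, seed=0,
                              rate_ceiling=1.0)


class TestReproducibility:
    def test_identical_runs_bitwise(self, small_topology):
        a = dn.run_simulation(small_topology, dn.DriveSpec(), 500.0, seed=42,
                              plasticity=dn.PlasticityConfig())
        b = dn.run_simulation(small_topology, dn.DriveSpec(), 500.0, seed=42,
                              plasticity=dn.PlasticityConfig())
        assert np.array_equal(a.spikes.times, b.spikes.times)
        assert np.array_equal(a.spikes.ids, b.spikes.ids)
        assert np.array_equal(a.topology.w["ee"].data, b.topology.w["ee"].data)
        assert np.array_equal(a.state.V, b.state.V)

    def test_different_seeds_differ(self, small_topology):
        a = dn.run_simulation(small_topology, dn.DriveSpec(), 500.0, seed=1)
        b = dn.run_simulation(small_topology, dn.DriveSpec(), 500.0, seed=2)
        assert not np.array_equal(a.spikes.times, b.spikes.times)
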