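"""Network assembly, gating dynamics and signal extraction."""

import numpy as np
import pytest

from sacgen.circuit import (
    POPULATIONS,
    Scenario,
    build_network,
    burst_window,
    extract_rate_signal,
    motoneuron_commands,
    pause_window,
    scenario_from_config,
    simulate_circuit,
)
from sacgen.config import default_config
from sacgen.synapse import SynapseParams, spikes_to_pulses

CFG = default_config()


@pytest.fixture(scope="module")
def settled_net():
    """A short run covering only the fixation period (no SC/FN drive)."""
    net = build_network(Scenario(16.0, 56.0, 100), CFG)
    res = simulate_circuit(net, duration=95.0, dt=0.002)
    return net, res


class TestBuildNetwork:
    def test_scenario_table(self):
        s16 = scenario_from_config(CFG, 16)
        assert (s16.burst_duration, s16.n_active) == (56.0, 100)
        s4 = scenario_from_config(CFG, 4)
        assert (s4.burst_duration, s4.n_active) == (40.0, 48)
        with pytest.raises(KeyError):
            scenario_from_config(CFG, 13)

    def test_population_counts(self):
        net = build_network(scenario_from_config(CFG, 16), CFG)
        assert sum(1 for n in net.neurons if n.name == "OPN") == 1
        for name in POPULATIONS:
            if name == "OPN":
                continue
            for side in ("ipsi", "contra"):
                assert sum(1 for n in net.neurons
                           if n.name == name and n.side == side) == 1

    def test_required_wiring_present(self):
        net = build_network(scenario_from_config(CFG, 16), CFG)
        edges = {(c.source, c.target, c.sign) for c in net.connections}
        required = [
            ((("LLBN", "ipsi")), ("OPN", "midline"), -1),
            ((("LLBN", "ipsi")), ("IBN", "ipsi"), +1),
            ((("OPN", "midline")), ("EBN", "ipsi"), -1),
            ((("OPN", "midline")), ("EBN", "contra"), -1),
            ((("OPN", "midline")), ("IBN", "ipsi"), -1),
            ((("IBN", "ipsi")), ("EBN", "contra"), -1),
            ((("IBN", "ipsi")), ("TN", "contra"), -1),
            ((("IBN", "ipsi")), ("AN", "contra"), -1),
            ((("IBN", "ipsi")), ("ON", "ipsi"), -1),
            ((("IBN", "ipsi")), ("IN", "ipsi"), -1),
            ((("EBN", "ipsi")), ("TN", "ipsi"), +1),
            ((("EBN", "ipsi")), ("AN", "ipsi"), +1),
            ((("TN", "ipsi")), ("IN", "ipsi"), +1),
            ((("IN", "ipsi")), ("AN", "ipsi"), +1),
            ((("AN", "ipsi")), ("ON", "contra"), +1),
        ]
        for edge in required:
            assert edge in edges, f"missing {edge}"
        assert not any(c.source == c.target for c in net.connections)

    def test_inhibitory_sign_lives_on_connection(self):
        """One source can excite one target and inhibit another."""
        net = build_network(scenario_from_config(CFG, 16), CFG)
        signs = {c.sign for c in net.connections
                 if c.source == ("LLBN", "ipsi")}
        assert signs == {1, -1}


class TestGateDynamics:
    def test_opn_tonic_holds_ebn_silent(self, settled_net):
        """With the OPN unperturbed the burst neurons never fire."""
        _, res = settled_net
        opn = res.spike_train("OPN")
        assert opn.size > 8   # tonic pacemaker active
        rate = 1000.0 / np.median(np.diff(opn))
        assert 120.0 <= rate <= 220.0
        for name in ("EBN", "IBN", "LLBN"):
            for side in ("ipsi", "contra"):
                s = res.spike_train(name, side)
                assert s[s > 30.0].size == 0, f"{name}/{side} leaked"

    def test_tonic_units_fire_through_fixation(self, settled_net):
        _, res = settled_net
        for name in ("TN", "IN"):
            s = res.spike_train(name, "ipsi")
            assert s[s > 30.0].size >= 5

    def test_determinism(self):
        """Identical config and scenario give bit-identical spike trains."""
        net1 = build_network(Scenario(16.0, 56.0, 100), CFG)
        r1 = simulate_circuit(net1, duration=60.0, dt=0.002)
        net2 = build_network(Scenario(16.0, 56.0, 100), CFG)
        r2 = simulate_circuit(net2, duration=60.0, dt=0.002)
        for key in r1.spikes:
            np.testing.assert_array_equal(r1.spikes[key], r2.spikes[key])

    def test_engine_pulses_match_offline_synapse_model(self):
        """In-loop crossings equal spikes_to_pulses on the same trace."""
        net = build_network(Scenario(16.0, 56.0, 100), CFG)
        res = simulate_circuit(net, duration=60.0, dt=0.002, record_every=1)
        u = net.index("OPN", "midline")
        spec = net.neurons[u]
        train_engine = res.pulse_train("OPN")
        train_offline = spikes_to_pulses(
            res.t, res.v_axon[u],
            SynapseParams(spec.synapse.pulse_amplitude,
                          spec.synapse.detection_level,
                          spec.synapse.axonal_delay))
        assert abs(len(train_engine) - len(train_offline)) <= 1
        n = min(len(train_engine), len(train_offline))
        on_e = np.array([p.onset for p in train_engine.pulses[:n]])
        on_o = np.array([p.onset for p in train_offline.pulses[:n]])
        np.testing.assert_allclose(on_e, on_o, atol=0.01)


class TestRateExtraction:
    def test_regular_train_gives_plateau(self):
        t = np.arange(0, 50, 0.1)
        spikes = np.arange(5, 40, 1.0)   # 1 ms ISIs
        r = extract_rate_signal(spikes, t)
        assert np.all(r[(t > 6) & (t < 39)] == pytest.approx(1000.0))

    def test_empty_train_is_zero(self):
        t = np.arange(0, 10, 0.1)
        assert np.all(extract_rate_signal(np.array([]), t) == 0.0)

    def test_two_rate_train_steps(self):
        """2 ms ISIs then 5 ms ISIs -> 500 Hz then 200 Hz."""
        spikes = np.concatenate([np.arange(0, 20, 2.0), np.arange(20, 60, 5.0)])
        t = np.arange(0, 60, 0.01)
        r = extract_rate_signal(spikes, t)
        assert np.all(r[(t > 1) & (t < 17)] == pytest.approx(500.0))
        assert np.all(r[(t > 21) & (t < 54)] == pytest.approx(200.0))


class TestEventWindows:
    def test_burst_window_hand_oracle(self):
        spikes = np.concatenate([
            np.arange(0, 50, 10.0),            # slow background
            np.arange(60, 80, 2.0),            # the burst
            np.arange(90, 130, 10.0),
        ])
        on, off = burst_window(spikes, max_isi=4.0)
        assert on == pytest.approx(60.0)
        assert off == pytest.approx(78.0)

    def test_pause_window_hand_oracle(self):
        spikes = np.concatenate([np.arange(0, 50, 5.0),
                                 np.arange(90, 140, 5.0)])
        start, end = pause_window(spikes, min_gap=20.0)
        assert (start, end) == (45.0, 90.0)

    def test_no_burst_returns_nan(self):
        on, off = burst_window(np.arange(0, 100, 10.0), max_isi=4.0)
        assert np.isnan(on) and np.isnan(off)


class TestMotoneuronCommands:
    def test_zero_rate_maps_to_clipped_intercept(self, settled_net):
        """Silent motoneurons give the (non-negative) intercept tension."""
        _, res = settled_net
        t, n_ag, n_ant = motoneuron_commands(res, "ipsi")
        assert np.all(n_ag >= 0.0)
        assert np.all(n_ant >= 0.0)

    def test_plateau_rate_maps_to_pulse_magnitude(self):
        """The affine map sends the nominal peak rate to the pulse height."""
        from sacgen.circuit import SimulationResult
        # synthetic result carrying only an AN spike train at peak rate
        t = np.arange(0, 100, 0.05)
        peak_rate, base = 700.0, 100.0
        spikes = np.arange(10, 90, 1000.0 / peak_rate)
        net = build_network(Scenario(16.0, 56.0, 100), CFG)
        res = SimulationResult(
            t, np.zeros((1, t.size)), np.zeros((1, t.size)),
            {("AN", "ipsi"): spikes, ("ON", "ipsi"): np.array([])},
            {}, {}, 0.002, 100.0, net)
        _, n_ag, _ = motoneuron_commands(
            res, "ipsi", baseline_rate=base, peak_rate=peak_rate,
            fixation_tension=0.4, pulse_magnitude=0.8, smoothing_window=0.0)
        mid = (t > 20) & (t < 80)
        assert np.median(n_ag[mid]) == pytest.approx(0.8, rel=1e-3)
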