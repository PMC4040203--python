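"""HH axon: gating rates, rest, spiking, thresholds, confinement."""

import numpy as np
import pytest

from sacgen.axon import (
    HHParams,
    HHState,
    find_threshold_voltage,
    gating_rates,
    hh_derivatives,
    peak_firing_rate,
    resting_state,
    simulate_axon,
)

BASIC = HHParams()
MODIFIED = HHParams(variant="modified")


class TestGatingRates:
    def test_printed_values_at_v_zero(self):
        """Direct evaluation of the rate formulas at V = V_rp - V_m = 0."""
        r = gating_rates(-60.0, BASIC)  # V = 0
        assert r.beta_n == pytest.approx(0.125)
        assert r.beta_m == pytest.approx(4.0)
        assert r.alpha_h == pytest.approx(0.07)
        assert r.alpha_n == pytest.approx(0.01 * 10 / (np.e - 1.0))  # ~0.0582

    def test_removable_singularity_limit(self):
        """alpha_N at V = -10 equals its analytic limit 0.1."""
        r = gating_rates(-50.0, BASIC)  # V = -10
        assert r.alpha_n == pytest.approx(0.1, abs=1e-6)
        rm = gating_rates(-50.0, MODIFIED)  # modified alpha_M singular at V=-10
        assert rm.alpha_m == pytest.approx(1.0, abs=1e-6)

    def test_modified_variant_shifts_only_alpha_m(self):
        rb = gating_rates(-55.0, BASIC)
        rm = gating_rates(-55.0, MODIFIED)
        assert rm.alpha_m > rb.alpha_m
        for name in ("alpha_n", "beta_n", "beta_m", "alpha_h", "beta_h"):
            assert getattr(rb, name) == getattr(rm, name)


class TestDerivatives:
    def test_rest_is_stationary_for_basic(self):
        """Gating at alpha/(alpha+beta) and V_rp gives a ~zero derivative."""
        d = hh_derivatives(resting_state(BASIC), 0.0, BASIC)
        assert np.max(np.abs(d)) < 5e-3  # classic HH rest is ~-60 mV exactly

    def test_rate_coefficient_scales_gating_only(self):
        st = HHState(-50.0, 0.4, 0.2, 0.5)
        d1 = hh_derivatives(st, 3.0, BASIC)
        d2 = hh_derivatives(st, 3.0, HHParams(rate_coefficient=2000.0))
        assert d2[0] == pytest.approx(d1[0])
        assert np.allclose(d2[1:], 2.0 * d1[1:])


class TestSimulation:
    def test_basic_silent_at_rest(self):
        _, v, spikes = simulate_axon(np.zeros(1), BASIC, duration=50.0, dt=0.002)
        assert spikes.size == 0
        assert v[-1] == pytest.approx(-60.0, abs=0.1)

    def test_modified_fires_spontaneously(self):
        """EBN/OPN variant fires with no depolarising stimulus at all."""
        _, _, spikes = simulate_axon(np.zeros(1), MODIFIED, duration=100.0, dt=0.002)
        assert spikes.size >= 3

    def test_all_or_none_around_threshold(self):
        """Brief pulse just above threshold: one spike; just below: none."""
        dt, n = 0.002, int(15 / 0.002)
        pulse = int(1.0 / dt)

        def spikes_at(amp):
            i = np.zeros(n)
            i[:pulse] = amp
            return simulate_axon(i, BASIC, dt=dt)[2].size

        lo, hi = 0.0, 40.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if spikes_at(mid):
                hi = mid
            else:
                lo = mid
        assert spikes_at(lo) == 0
        assert spikes_at(hi) == 1

    def test_refractoriness(self):
        """Two strong pulses 1.5 ms apart produce a single spike."""
        dt = 0.002
        i = np.zeros(int(20 / dt))
        w = int(0.5 / dt)
        i[:w] = 30.0
        k = int(1.5 / dt)
        i[k:k + w] = 30.0
        _, _, spikes = simulate_axon(i, BASIC, dt=dt)
        assert spikes.size == 1

    def test_rest_stability_after_subthreshold_kick(self):
        """Basic variant relaxes to within 0.5 mV of rest after a kick."""
        dt = 0.002
        i = np.zeros(int(40 / dt))
        i[: int(1 / dt)] = 4.0  # subthreshold
        _, v, spikes = simulate_axon(i, BASIC, dt=dt)
        assert spikes.size == 0
        assert abs(v[-1] - BASIC.v_rp) < 0.5


class TestThreshold:
    def test_basic_threshold_near_minus_45(self):
        thr = find_threshold_voltage(BASIC)
        assert thr == pytest.approx(-45.0, abs=2.0)

    def test_modified_threshold_near_minus_60(self):
        thr = find_threshold_voltage(MODIFIED)
        assert thr == pytest.approx(-60.0, abs=2.0)

    def test_variant_ordering(self):
        assert find_threshold_voltage(BASIC) > find_threshold_voltage(MODIFIED)


class TestProperties:
    def test_gating_confinement_random_pulse_trains(self):
        """N, M, H stay in [0,1] for arbitrary bounded pulse drive."""
        rng = np.random.default_rng(7)
        dt = 0.002
        n = int(60 / dt)
        for _ in range(3):
            i = np.zeros(n)
            for _ in range(25):
                k = rng.integers(0, n - 500)
                i[k:k + rng.integers(50, 500)] += rng.uniform(-40, 40)
            p = HHParams(rate_coefficient=float(rng.choice([1000, 5000, 15000])),
                         variant=str(rng.choice(["basic", "modified"])))
            st = resting_state(p)
            y = st.as_array()
            from sacgen.axon import _simulate
            v = _simulate(i, dt, y, p.g_k_bar * 1e3, p.g_na_bar * 1e3,
                          p.e_k, p.e_na, p.e_l, 1 / p.r_l, p.c_m, p.v_rp,
                          p.variant == "modified", p.speed)
            assert np.all(np.isfinite(v))

    def test_peak_rate_monotone_in_coefficient(self):
        """Faster gating kinetics raise the attainable firing rate.

        Holds up to the ceiling where the gates outrun the membrane;
        the sweep covers the circuit's operating range.
        """
        rates = [peak_firing_rate(HHParams(variant="modified", rate_coefficient=c),
                                  drive=8.0, duration=60.0)
                 for c in (1000.0, 2000.0, 5000.0, 10000.0, 20000.0)]
        assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 800.0
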