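"""Hodgkin-Huxley axon hillock with two circuit-specific modifications.

The spike generator is the classic squid-axon model written in the 1952
sign convention ``V = V_rp - V_m`` with the resting potential shifted to
-60 mV (E_Na = +55 mV, E_K = -72 mV, E_l = -49.4 mV, leak 1/3.33 kΩ).
Two modifications adapt it to the saccadic burst generator:

* ``rate_coefficient`` - the three gating equations are multiplied by a
  common coefficient to tune each population's peak firing rate.  The
  coefficient is expressed on a per-second time base: a value of 1000
  reproduces textbook kinetics, larger values speed the gates up
  proportionally.  Faster gates shorten the refractory period and raise
  the attainable firing rate -- up to a ceiling (around 25,000-28,000)
  beyond which the gates outrun the membrane and repetitive firing fails.
* ``variant='modified'`` - the alpha_M rate is shifted by +15 mV
  (the (V+25) numerator/denominator argument becomes (V+10)).  This moves
  the firing threshold from about -45 mV down to the resting potential,
  so the neuron fires spontaneously as soon as it is released from
  inhibition.  It is used for the EBN and the OPN, the two autonomous
  populations of the circuit.

Units: mV, ms, µA, mS (conductance fields are stored in S and converted),
µF.  mS * mV = µA, so the membrane equation balances in µA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "HHParams",
    "HHState",
    "GatingRates",
    "gating_rates",
    "hh_derivatives",
    "resting_state",
    "simulate_axon",
    "find_threshold_voltage",
    "peak_firing_rate",
]

#: gating multiplier corresponding to textbook squid-axon kinetics
COEFF_UNITY = 1000.0


@dataclass(frozen=True)
class HHParams:
    g_k_bar: float = 36e-3      # S, max potassium conductance
    g_na_bar: float = 120e-3    # S, max sodium conductance
    e_k: float = -72.0          # mV
    e_na: float = 55.0          # mV
    e_l: float = -49.4          # mV
    r_l: float = 3.33           # kΩ, leakage resistance
    c_m: float = 1.0            # µF
    v_rp: float = -60.0         # mV, resting potential
    rate_coefficient: float = COEFF_UNITY
    variant: str = "basic"      # 'basic' | 'modified'

    def __post_init__(self) -> None:
        if self.variant not in ("basic", "modified"):
            raise ValueError("variant must be 'basic' or 'modified'")
        if min(self.g_k_bar, self.g_na_bar, self.r_l, self.c_m,
               self.rate_coefficient) <= 0:
            raise ValueError("conductances, R_l, C_m and rate_coefficient "
                             "must be positive")

    @property
    def speed(self) -> float:
        """Effective gating multiplier relative to textbook kinetics."""
        return self.rate_coefficient / COEFF_UNITY


@dataclass(frozen=True)
class HHState:
    v_m: float
    n: float
    m: float
    h: float

    def __post_init__(self) -> None:
        for g in (self.n, self.m, self.h):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gating variables must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_m, self.n, self.m, self.h])


@dataclass(frozen=True)
class GatingRates:
    alpha_n: float
    beta_n: float
    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float


@njit(cache=True)
def _rates(v_m, v_rp, modified):
    """Six gating rates (ms^-1 at unit speed) at membrane potential v_m."""
    v = v_rp - v_m
    x = v + 10.0
    a_n = 0.1 if abs(x) < 1e-9 else 0.01 * x / math.expm1(x / 10.0)
    b_n = 0.125 * math.exp(v / 80.0)
    xm = v + 10.0 if modified else v + 25.0
    a_m = 1.0 if abs(xm) < 1e-9 else 0.1 * xm / math.expm1(xm / 10.0)
    b_m = 4.0 * math.exp(v / 18.0)
    a_h = 0.07 * math.exp(v / 20.0)
    b_h = 1.0 / (math.exp((v + 30.0) / 10.0) + 1.0)
    return a_n, b_n, a_m, b_m, a_h, b_h


def gating_rates(v_m: float, params: HHParams) -> GatingRates:
    """Voltage-dependent rate constants, removable singularities by limit.

    The returned rates are per ms at textbook speed; the rate coefficient
    is applied in :func:`hh_derivatives`, not here.
    """
    if not np.isfinite(v_m):
        raise ValueError("v_m must be finite")
    return GatingRates(*_rates(float(v_m), params.v_rp, params.variant == "modified"))


@njit(cache=True)
def _hh_rhs(v, n, m, h, i_m, g_k, g_na, e_k, e_na, e_l, g_l, c_m, v_rp,
            modified, speed):
    a_n, b_n, a_m, b_m, a_h, b_h = _rates(v, v_rp, modified)
    dv = (i_m
          - g_k * n ** 4 * (v - e_k)
          - g_na * m ** 3 * h * (v - e_na)
          - g_l * (v - e_l)) / c_m
    dn = speed * (a_n * (1.0 - n) - b_n * n)
    dm = speed * (a_m * (1.0 - m) - b_m * m)
    dh = speed * (a_h * (1.0 - h) - b_h * h)
    return dv, dn, dm, dh


def hh_derivatives(state: HHState, i_m: float, params: HHParams) -> np.ndarray:
    """State derivative (mV/ms and 1/ms) for membrane current i_m (µA)."""
    dv, dn, dm, dh = _hh_rhs(
        state.v_m, state.n, state.m, state.h, i_m,
        params.g_k_bar * 1e3, params.g_na_bar * 1e3,
        params.e_k, params.e_na, params.e_l, 1.0 / params.r_l,
        params.c_m, params.v_rp, params.variant == "modified", params.speed,
    )
    return np.array([dv, dn, dm, dh])


def resting_state(params: HHParams) -> HHState:
    """Initial condition: V_rp with gating at its steady state there.

    For the basic variant this is (numerically) the stable resting
    equilibrium.  The modified variant has no stable rest -- started here
    it depolarises and fires on its own, which is the intended behaviour.
    """
    r = gating_rates(params.v_rp, params)
    return HHState(
        params.v_rp,
        r.alpha_n / (r.alpha_n + r.beta_n),
        r.alpha_m / (r.alpha_m + r.beta_m),
        r.alpha_h / (r.alpha_h + r.beta_h),
    )


@njit(cache=True)
def _simulate(i_m, dt, y0, g_k, g_na, e_k, e_na, e_l, g_l, c_m, v_rp,
              modified, speed):
    n_steps = i_m.shape[0]
    out = np.empty(n_steps + 1)
    v, n, m, h = y0[0], y0[1], y0[2], y0[3]
    out[0] = v
    for k in range(n_steps):
        i = i_m[k]
        a = _hh_rhs(v, n, m, h, i, g_k, g_na, e_k, e_na, e_l, g_l, c_m,
                    v_rp, modified, speed)
        b = _hh_rhs(v + 0.5 * dt * a[0], n + 0.5 * dt * a[1],
                    m + 0.5 * dt * a[2], h + 0.5 * dt * a[3], i,
                    g_k, g_na, e_k, e_na, e_l, g_l, c_m, v_rp, modified, speed)
        c = _hh_rhs(v + 0.5 * dt * b[0], n + 0.5 * dt * b[1],
                    m + 0.5 * dt * b[2], h + 0.5 * dt * b[3], i,
                    g_k, g_na, e_k, e_na, e_l, g_l, c_m, v_rp, modified, speed)
        d = _hh_rhs(v + dt * c[0], n + dt * c[1], m + dt * c[2],
                    h + dt * c[3], i,
                    g_k, g_na, e_k, e_na, e_l, g_l, c_m, v_rp, modified, speed)
        v += dt / 6.0 * (a[0] + 2 * b[0] + 2 * c[0] + d[0])
        n += dt / 6.0 * (a[1] + 2 * b[1] + 2 * c[1] + d[1])
        m += dt / 6.0 * (a[2] + 2 * b[2] + 2 * c[2] + d[2])
        h += dt / 6.0 * (a[3] + 2 * b[3] + 2 * c[3] + d[3])
        # gates are confined to [0,1] by the ODE; clip integration noise
        n = min(max(n, 0.0), 1.0)
        m = min(max(m, 0.0), 1.0)
        h = min(max(h, 0.0), 1.0)
        out[k + 1] = v
    return out


def default_dt(params: HHParams) -> float:
    """Step small enough for the fastest gate at this rate coefficient."""
    return max(1e-4, min(2e-3, 0.05 / params.speed))


def spike_times_from_trace(
    t: np.ndarray, v: np.ndarray, level: float = 0.0
) -> np.ndarray:
    """Upward crossing times of ``level``, linearly interpolated."""
    below = v[:-1] < level
    above = v[1:] >= level
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.empty(0)
    frac = (level - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def simulate_axon(
    i_m: np.ndarray,
    params: HHParams,
    duration: float | None = None,
    dt: float | None = None,
    state0: HHState | None = None,
    detection_level: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the axon under a sampled membrane current.

    ``i_m`` is sampled per integration step (µA); ``duration`` defaults to
    ``len(i_m) * dt``.  Returns ``(t, v_m, spike_times)`` where spikes are
    upward crossings of ``detection_level``.
    """
    if dt is None:
        dt = default_dt(params)
    i_m = np.asarray(i_m, dtype=float)
    if duration is not None:
        n_steps = int(round(duration / dt))
        if i_m.size == 1:
            i_m = np.full(n_steps, float(i_m[0]))
        elif i_m.size != n_steps:
            raise ValueError("i_m length does not match duration/dt")
    y0 = (state0 or resting_state(params)).as_array()
    v = _simulate(
        i_m, dt, y0,
        params.g_k_bar * 1e3, params.g_na_bar * 1e3,
        params.e_k, params.e_na, params.e_l, 1.0 / params.r_l,
        params.c_m, params.v_rp, params.variant == "modified", params.speed,
    )
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise FloatingPointError(f"axon integration diverged at t={bad * dt:.4f} ms")
    t = np.arange(v.size) * dt
    return t, v, spike_times_from_trace(t, v, detection_level)


def find_threshold_voltage(
    params: HHParams,
    pulse_width: float = 1.0,
    window: float = 12.0,
    dt: float = 1e-3,
    takeoff_criterion: float = 10.0,
    max_steps: int = 60,
    amp_tol: float = 1e-3,
) -> float:
    """Firing threshold (mV) by bisection over brief current pulses.

    A 1-ms rectangular pulse of varying amplitude is applied at rest and
    the minimal amplitude that elicits a spike (a 0-mV upward crossing
    within the observation window) is bracketed by bisection.  The
    threshold voltage is then read off the minimal suprathreshold
    trajectory as the membrane potential at spike takeoff -- the first
    point after the pulse where dV/dt exceeds ``takeoff_criterion``
    (mV/ms), the standard electrophysiological criterion.  If the model
    fires with no stimulus at all (the modified variant), the takeoff of
    the zero-input trajectory is reported, which is the resting potential.
    """
    base = replace(params, rate_coefficient=params.rate_coefficient)
    n_steps = int(round(window / dt))
    n_pulse = int(round(pulse_width / dt))

    def trial(amp: float) -> tuple[np.ndarray, bool]:
        i = np.zeros(n_steps)
        i[:n_pulse] = amp
        _, v, spikes = simulate_axon(i, base, dt=dt)
        return v, spikes.size > 0

    v0, spont = trial(0.0)
    if spont:
        v, start = v0, 1
    else:
        lo, hi = 0.0, 20.0
        steps = 0
        while not trial(hi)[1]:
            hi *= 2.0
            steps += 1
            if steps > max_steps:
                raise RuntimeError("no suprathreshold amplitude found")
        while hi - lo > amp_tol:
            steps += 1
            if steps > max_steps:
                raise RuntimeError(
                    f"threshold bisection did not converge in {max_steps} steps")
            mid = 0.5 * (lo + hi)
            if trial(mid)[1]:
                hi = mid
            else:
                lo = mid
        v, start = trial(hi)[0], n_pulse + 1
    dv = np.diff(v) / dt
    i_peak = int(np.argmax(v))
    idx = np.flatnonzero(dv[start:i_peak] >= takeoff_criterion)
    if idx.size == 0:
        raise RuntimeError("no spike takeoff found on the suprathreshold trial")
    return float(v[start + idx[0]])


def peak_firing_rate(
    params: HHParams,
    drive: float,
    duration: float = 100.0,
    dt: float | None = None,
) -> float:
    """1 / min(ISI) in Hz under a sustained constant drive (µA)."""
    if dt is None:
        dt = default_dt(params)
    n = int(round(duration / dt))
    _, _, spikes = simulate_axon(np.full(n, float(drive)), params, dt=dt)
    if spikes.size < 2:
        return 0.0
    return 1000.0 / float(np.min(np.diff(spikes)))
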