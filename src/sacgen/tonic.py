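"""Tonic neuron (TN) and interneuron (IN): burst integrators.

The position-holding neurons are modelled as FitzHugh-Nagumo relaxation
oscillators riding on a leak-free integrator.  Synaptic input plays two
roles: its running integral (the accumulated drive) sets the oscillator's
operating current -- and therefore the tonic firing rate that persists
after a burst has ended -- while the instantaneous current adds directly,
so that a strong inhibitory barrage (IBN input during the pulse phase)
silences spiking immediately without erasing the stored eye position.

The oscillator is the standard two-variable FHN system

    dv/dt = s * (v - v^3/3 - w + I)
    dw/dt = s * eps * (v + a - b*w)

with I = i_rest + input_gain * i_syn(t) + integral_gain * q(t) and
q(t) = integral of i_syn.  ``s`` (1/ms) scales the oscillation into the
physiological tonic range.  The fast variable is mapped affinely to a
mV-like output trace so the common synapse model can convert it to
pulses.  The equations of the original tonic-bursting formulation are not
part of this package; the standard oscillator with a configurable
parameterisation fulfils the same circuit-level contract (integrate
bursts, hold a position-proportional tonic rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "FHNParams",
    "IntegratorState",
    "RateCalibration",
    "fhn_derivatives",
    "fixed_point",
    "integrate_burst",
    "simulate_tonic",
    "tonic_rate_from_position",
    "position_from_tonic_rate",
]


@dataclass(frozen=True)
class FHNParams:
    a: float = 0.7
    b: float = 0.8
    eps: float = 0.08            # recovery timescale ratio, > 0
    speed: float = 4.0           # 1/ms, overall timescale of the oscillator
    input_gain: float = 0.05     # direct (instantaneous) input coupling, 1/µA
    integral_gain: float = 0.0   # coupling of the accumulated drive, 1/(µA·ms)
    i_rest: float = 0.0          # operating-point current at zero drive
    out_scale: float = 30.0      # mV per unit of the fast variable
    out_offset: float = -25.0    # mV
    mode: str = "tonic-spiking"  # 'tonic-spiking' | 'tonic-bursting'

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.speed <= 0:
            raise ValueError("eps and speed must be positive")

    def output_voltage(self, v: np.ndarray | float):
        """Map the fast variable to a mV-like axonal trace."""
        return self.out_scale * np.asarray(v) + self.out_offset


@dataclass
class IntegratorState:
    q: float = 0.0   # accumulated drive, µA·ms
    v: float = -1.2  # fast variable
    w: float = -0.6  # recovery variable


@dataclass(frozen=True)
class RateCalibration:
    """Affine map between eye position (deg) and tonic firing rate (Hz)."""

    baseline_rate: float = 100.0   # Hz at primary position
    rate_per_degree: float = 4.0   # Hz/deg

    def rate(self, theta: float) -> float:
        return self.baseline_rate + self.rate_per_degree * theta

    def position(self, rate: float) -> float:
        return (rate - self.baseline_rate) / self.rate_per_degree


def fhn_derivatives(
    state: np.ndarray, input_current: float, params: FHNParams
) -> np.ndarray:
    """Vector field of the oscillator at total input ``input_current`` (µA).

    The direct input gain is applied here; the integral pathway is the
    caller's business (see :func:`simulate_tonic`).
    """
    v, w = float(state[0]), float(state[1])
    i = params.i_rest + params.input_gain * input_current
    dv = params.speed * (v - v ** 3 / 3.0 - w + i)
    dw = params.speed * params.eps * (v + params.a - params.b * w)
    return np.array([dv, dw])


def fixed_point(params: FHNParams, input_current: float = 0.0) -> np.ndarray:
    """The (unique, for the default cubic) rest point at constant input."""
    i = params.i_rest + params.input_gain * input_current
    # v - v^3/3 - (v + a)/b + i = 0
    coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / params.b, i - params.a / params.b]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    v = float(real[np.argmin(np.abs(real + 1.2))])
    return np.array([v, (v + params.a) / params.b])


def integrate_burst(
    t: np.ndarray, input_current: np.ndarray, q0: float = 0.0
) -> np.ndarray:
    """Trapezoidal running integral of the net synaptic input (µA·ms).

    Returns the accumulated drive on the same grid; the final value is the
    stored quantity that sets the post-burst tonic rate.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(input_current, dtype=float)
    if t.shape != i.shape:
        raise ValueError("t and input_current must share a grid")
    out = np.empty_like(i)
    out[0] = q0
    if t.size > 1:
        out[1:] = q0 + np.cumsum(0.5 * (i[1:] + i[:-1]) * np.diff(t))
    return out


@njit(cache=True)
def _simulate(i_syn, dt, v0, w0, q0, a, b, eps, speed, gain, qgain, i_rest):
    n = i_syn.shape[0]
    v_out = np.empty(n + 1)
    q_out = np.empty(n + 1)
    v, w, q = v0, w0, q0
    v_out[0] = v
    q_out[0] = q
    for k in range(n):
        i_k = i_syn[k]
        for _ in range(2):  # RK2 (midpoint) twice per sample for stability
            i_tot = i_rest + gain * i_k + qgain * q
            dv1 = speed * (v - v ** 3 / 3.0 - w + i_tot)
            dw1 = speed * eps * (v + a - b * w)
            vm = v + 0.25 * dt * dv1
            wm = w + 0.25 * dt * dw1
            dv2 = speed * (vm - vm ** 3 / 3.0 - wm + i_tot)
            dw2 = speed * eps * (vm + a - b * wm)
            v += 0.5 * dt * dv2
            w += 0.5 * dt * dw2
        q += dt * i_k   # leak-free integrator, rectangle rule on the grid
        v_out[k + 1] = v
        q_out[k + 1] = q
    return v_out, q_out


def simulate_tonic(
    i_syn: np.ndarray,
    params: FHNParams,
    dt: float,
    state0: IntegratorState | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate oscillator + integrator under a sampled input current.

    Returns ``(t, v_out_mV, q)``: the mV-mapped fast-variable trace and
    the accumulated drive.
    """
    if state0 is None:
        # classic quiescent rest; off any driven fixed point, so an
        # oscillatory operating current starts the tonic rhythm
        state0 = IntegratorState(q=0.0, v=-1.2, w=(-1.2 + params.a) / params.b)
    i_syn = np.asarray(i_syn, dtype=float)
    v, q = _simulate(
        i_syn, dt, state0.v, state0.w, state0.q,
        params.a, params.b, params.eps, params.speed,
        params.input_gain, params.integral_gain, params.i_rest,
    )
    t = np.arange(v.size) * dt
    return t, params.output_voltage(v), q


def tonic_rate_from_position(theta: float, calibration: RateCalibration) -> float:
    """Tonic firing rate (Hz) holding the eye at ``theta`` degrees."""
    return calibration.rate(theta)


def position_from_tonic_rate(rate: float, calibration: RateCalibration) -> float:
    """Inverse of :func:`tonic_rate_from_position` on the operating range."""
    return calibration.position(rate)
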