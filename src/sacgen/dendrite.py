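"""Passive compartmental dendrite model.

A linear chain of ``n`` identical RC compartments, each with membrane
capacitance ``C_m`` (µF), membrane resistance ``R_EQ`` (kΩ) and a Thevenin
resting battery ``V_TH`` (mV), coupled through an axial resistance ``R_a``
(Ω).  The presynaptic input is a rectangular current pulse train injected
into compartment 1 only; the axon hillock taps the last compartment.  The
chain acts as a cascaded low-pass filter: the further a compartment is from
the input, the smoother (and smaller) its response, which is what supplies
each neuron's characteristic onset delay in the circuit.

Units: µA · kΩ = mV, time in ms, so C_m[µF] · dv[mV]/dt[ms] balances µA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DendriteParams",
    "Pulse",
    "StimulusTrain",
    "dendrite_derivatives",
    "simulate_dendrite",
]


@dataclass(frozen=True)
class DendriteParams:
    """Parameters of an n-compartment passive dendrite chain."""

    n_compartments: int = 14
    c_m: float = 0.45          # µF per compartment
    r_eq: float = 3.1          # kΩ per compartment
    r_a: float = 100.0         # Ω, axial resistance (shared across neuron types)
    v_th: float = -60.0        # mV, Thevenin resting potential

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        if self.c_m <= 0 or self.r_eq <= 0 or self.r_a <= 0:
            raise ValueError("C_m, R_EQ and R_a must be positive")

    @property
    def r_a_kohm(self) -> float:
        return self.r_a * 1e-3


@dataclass(frozen=True)
class Pulse:
    """One rectangular current pulse: sign * amplitude on [onset, onset+width)."""

    onset: float       # ms
    width: float       # ms
    amplitude: float   # µA, positive
    sign: int = 1      # +1 excitatory, -1 inhibitory

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be positive")


@dataclass(frozen=True)
class StimulusTrain:
    """A train of rectangular current pulses, evaluable as i_s(t).

    Pulses must be supplied in nondecreasing onset order.  Overlapping
    pulses superpose (currents add).
    """

    pulses: tuple[Pulse, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        onsets = [p.onset for p in self.pulses]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("pulse onsets must be nondecreasing")

    def __len__(self) -> int:
        return len(self.pulses)

    def current(self, t: float) -> float:
        """Instantaneous stimulus current i_s(t) in µA."""
        i = 0.0
        for p in self.pulses:
            if p.onset <= t < p.onset + p.width:
                i += p.sign * p.amplitude
        return i

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Vectorised i_s on a time grid (µA)."""
        out = np.zeros_like(t, dtype=float)
        for p in self.pulses:
            out[(t >= p.onset) & (t < p.onset + p.width)] += p.sign * p.amplitude
        return out


def dendrite_derivatives(
    v_m: np.ndarray, i_s_value: float, params: DendriteParams
) -> np.ndarray:
    """Node-equation right-hand side dv_m/dt (mV/ms) for the full chain.

    Compartment 1 receives the stimulus current; intermediate compartments
    couple to both neighbours; the last compartment couples only to its
    predecessor.
    """
    v_m = np.asarray(v_m, dtype=float)
    if v_m.shape != (params.n_compartments,):
        raise ValueError(
            f"state length {v_m.shape} does not match "
            f"n_compartments={params.n_compartments}"
        )
    ra = params.r_a_kohm
    leak = (v_m - params.v_th) / params.r_eq
    dv = -leak
    if params.n_compartments > 1:
        ax = np.diff(v_m) / ra        # current flowing j -> j+1 is -ax[j]
        dv[:-1] += ax
        dv[1:] -= ax
    dv[0] += i_s_value
    return dv / params.c_m


def simulate_dendrite(
    stim: StimulusTrain,
    params: DendriteParams,
    duration: float,
    dt: float = 0.01,
    v0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the dendrite chain with fixed-step RK4.

    The stimulus is treated as constant over each step (it is a train of
    rectangular pulses, so this is exact away from edges and first-order
    accurate at them).  Initial condition is V_TH in every compartment
    (capacitors charged to rest) unless ``v0`` is given.

    Returns ``(t, v)`` with ``v`` of shape ``(len(t), n_compartments)``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    v = np.empty((n_steps + 1, params.n_compartments))
    if v0 is None:
        vk = np.full(params.n_compartments, params.v_th, dtype=float)
    else:
        vk = np.asarray(v0, dtype=float).copy()
        if vk.shape != (params.n_compartments,):
            raise ValueError("v0 length does not match n_compartments")
    v[0] = vk
    i_s = stim.sample(t[:-1] + 0.5 * dt)  # midpoint sampling of the train
    for k in range(n_steps):
        i = i_s[k]
        k1 = dendrite_derivatives(vk, i, params)
        k2 = dendrite_derivatives(vk + 0.5 * dt * k1, i, params)
        k3 = dendrite_derivatives(vk + 0.5 * dt * k2, i, params)
        k4 = dendrite_derivatives(vk + dt * k3, i, params)
        vk = vk + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        v[k + 1] = vk
        if not np.all(np.isfinite(vk)):
            raise FloatingPointError(f"dendrite integration diverged at t={t[k+1]:.4f} ms")
    return t, v
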