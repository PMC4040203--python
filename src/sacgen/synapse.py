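"""Presynaptic terminal: action potentials to delayed current pulse trains.

The synapse is a voltage-to-frequency converter: each action potential in
the axonal trace produces one rectangular current pulse whose width is the
time the potential spends above a constant detection level, whose onset is
the upward crossing time shifted by the axonal transmission delay, and
whose amplitude is the fixed, per-neuron value (Table of membrane
parameters).  Whether the pulse excites or inhibits the postsynaptic
dendrite is a property of the connection, not of the neuron: sign=+1
excites, sign=-1 inhibits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dendrite import Pulse, StimulusTrain

__all__ = ["SynapseParams", "spikes_to_pulses"]


@dataclass(frozen=True)
class SynapseParams:
    pulse_amplitude: float        # µA, > 0
    detection_level: float = 0.0  # mV, axonal level defining the pulse width
    axonal_delay: float = 1.0     # ms, >= 0
    sign: int = 1                 # +1 excitatory / -1 inhibitory

    def __post_init__(self) -> None:
        if self.pulse_amplitude <= 0:
            raise ValueError("pulse_amplitude must be positive")
        if self.axonal_delay < 0:
            raise ValueError("axonal_delay must be non-negative")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


def _crossings(t: np.ndarray, v: np.ndarray, level: float, upward: bool):
    if upward:
        idx = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    else:
        idx = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
    if idx.size == 0:
        return np.empty(0)
    frac = (level - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def spikes_to_pulses(
    t: np.ndarray, v_m: np.ndarray, params: SynapseParams
) -> StimulusTrain:
    """Convert an axonal potential trace into a delayed pulse train.

    One pulse per action potential; crossing times are linearly
    interpolated between samples.  An action potential still above the
    detection level when the trace ends has no defined width and is
    dropped with a warning.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v_m, dtype=float)
    if t.shape != v.shape:
        raise ValueError("t and v_m must have the same shape")
    ups = _crossings(t, v, params.detection_level, upward=True)
    downs = _crossings(t, v, params.detection_level, upward=False)
    # trace may start above the level: discard the initial down-crossing
    if downs.size and (ups.size == 0 or downs[0] < ups[0]):
        downs = downs[1:]
    if ups.size > downs.size:
        warnings.warn(
            "action potential still above detection level at end of trace; "
            "dropping the final event",
            stacklevel=2,
        )
        ups = ups[: downs.size]
    pulses = tuple(
        Pulse(
            onset=up + params.axonal_delay,
            width=down - up,
            amplitude=params.pulse_amplitude,
            sign=params.sign,
        )
        for up, down in zip(ups, downs)
    )
    return StimulusTrain(pulses)
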