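"""First-order time-optimal controller: innervation to active-state tension.

The motoneuron innervation signal N(t), expressed in tension units, is
low-pass filtered into the active-state tension F(t) with a time constant
that switches with the phase of the saccade:

    agonist      dF/dt = (N - F) / tau_ag,
                 tau_ag  = tau_gac on [t1, t2),  tau_gde from t2
    antagonist   dF/dt = (N - F) / tau_ant,
                 tau_ant = tau_tde on [t1, t3),  tau_tac from t3

t1 is the end of the latent period (saccade start), t2 the start of the
agonist slide, t3 the antagonist step onset.  Before t1 the time constant
is zero (the unit-step factors in the tau expressions are all zero), i.e.
F tracks N exactly during fixation.  The filter is advanced by the exact
exponential update per sample -- not by generic ODE stepping -- so the
piecewise closed forms hold to machine precision for inputs that are
piecewise constant on the grid with switches on grid points.

Under the time-optimal strategy the agonist pulse height saturates (it
does not encode saccade magnitude); magnitude is carried by the pulse
duration and by how many of the fibers receive the pulse.  Fibers not
recruited follow the inactive-fiber program: their tension decays during
the pulse and recovers during the slide with the same two agonist time
constants, settling at the new fixation tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import PlantParams, tension_position_slope

__all__ = [
    "ControllerParams",
    "TensionTrace",
    "agonist_filter",
    "antagonist_filter",
    "steady_state_tensions",
    "inactive_fiber_program",
]


@dataclass(frozen=True)
class ControllerParams:
    tau_gac: float = 4.0    # ms, agonist activation
    tau_gde: float = 6.0    # ms, agonist deactivation (slide)
    tau_tde: float = 5.0    # ms, antagonist deactivation (pause)
    tau_tac: float = 5.0    # ms, antagonist re-activation (step)
    t1: float = 120.0       # ms, latent period end / saccade start
    t2: float = 160.0       # ms, agonist slide onset (t1 + burst duration)
    t3: float = 170.0       # ms, antagonist step onset

    def __post_init__(self) -> None:
        if min(self.tau_gac, self.tau_gde, self.tau_tde, self.tau_tac) <= 0:
            raise ValueError("all time constants must be positive")
        if not (self.t1 < self.t2 and self.t1 < self.t3):
            raise ValueError("need t1 < t2 and t1 < t3")

    def tau_agonist(self, t: float) -> float:
        if t < self.t1:
            return 0.0
        return self.tau_gac if t < self.t2 else self.tau_gde

    def tau_antagonist(self, t: float) -> float:
        if t < self.t1:
            return 0.0
        return self.tau_tde if t < self.t3 else self.tau_tac


@dataclass(frozen=True)
class TensionTrace:
    t: np.ndarray        # ms
    n: np.ndarray        # innervation input, tension units
    f: np.ndarray        # active-state tension


def _exact_filter(
    t: np.ndarray, n: np.ndarray, tau_of_t, f0: float | None
) -> np.ndarray:
    """Exact exponential update of dF/dt = (N - F)/tau(t).

    N is treated as constant over each [t_k, t_{k+1}) (sample-and-hold);
    tau is evaluated at the left edge of each interval.  tau = 0 means F
    snaps to N (the fixation regime).
    """
    t = np.asarray(t, dtype=float)
    n = np.asarray(n, dtype=float)
    if t.shape != n.shape:
        raise ValueError("t and n must share a grid")
    f = np.empty_like(n)
    f[0] = n[0] if f0 is None else f0
    for k in range(t.size - 1):
        dt = t[k + 1] - t[k]
        tau = tau_of_t(t[k])
        if tau <= 0.0:
            f[k + 1] = n[k]
        else:
            f[k + 1] = n[k] + (f[k] - n[k]) * np.exp(-dt / tau)
    return f


def agonist_filter(
    t: np.ndarray,
    n_ag: np.ndarray,
    params: ControllerParams,
    f0: float | None = None,
) -> TensionTrace:
    """Pulse-slide-step low-pass: tau_gac during the pulse, tau_gde after t2."""
    return TensionTrace(t, np.asarray(n_ag, float),
                        _exact_filter(t, n_ag, params.tau_agonist, f0))


def antagonist_filter(
    t: np.ndarray,
    n_ant: np.ndarray,
    params: ControllerParams,
    f0: float | None = None,
) -> TensionTrace:
    """Pause-step low-pass: tau_tde during the pause, tau_tac from t3."""
    return TensionTrace(t, np.asarray(n_ant, float),
                        _exact_filter(t, n_ant, params.tau_antagonist, f0))


def steady_state_tensions(
    theta_target: float,
    plant_params: PlantParams,
    fixation_tension: float = 0.4,
) -> tuple[float, float]:
    """Whole-muscle fixation tensions (N) holding the eye at ``theta_target``.

    The pair is the symmetric affine solution of the plant equilibrium:
    F_ag = F0 + k*theta, F_ant = F0 - k*theta with the slope ``k`` that
    satisfies the static force balance exactly (see
    :func:`sacgen.plant.tension_position_slope`).  Raises if either
    tension would be negative (target outside the operating range).
    """
    k = tension_position_slope(plant_params)
    f_ag = fixation_tension + k * theta_target
    f_ant = fixation_tension - k * theta_target
    if f_ag < 0 or f_ant < 0:
        raise ValueError(
            f"theta={theta_target} deg outside the range where both "
            f"fixation tensions are non-negative (|theta| <= "
            f"{fixation_tension / k:.1f} deg)")
    return f_ag, f_ant


def inactive_fiber_program(
    t: np.ndarray | float,
    params: ControllerParams,
    f_pre: float,
    f_post: float,
) -> np.ndarray:
    """Tension program of non-recruited agonist fibers.

    Exponential decay from the pre-saccade fixation tension with tau_gac
    during the pulse, exponential recovery towards the new fixation
    tension with tau_gde during the slide.  Continuous at t1 and t2.
    """
    t = np.asarray(t, dtype=float)
    f_at_t2 = f_pre * np.exp(-(params.t2 - params.t1) / params.tau_gac)
    decay = f_pre * np.exp(-(t - params.t1) / params.tau_gac)
    rise = f_post + (f_at_t2 - f_post) * np.exp(-(t - params.t2) / params.tau_gde)
    out = np.where(t < params.t1, f_pre, np.where(t < params.t2, decay, rise))
    return out if out.shape else float(out)
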