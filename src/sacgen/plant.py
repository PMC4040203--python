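"""Linear homeomorphic muscle-fiber oculomotor plant.

Two antagonist rectus muscles act on the eyeball, each built from ``n``
parallel columns of ``m`` muscle fibers in series, capped by a tendon
element at either end (so each column has ``m + 2`` viscoelastic
elements).  A tendon element is a spring ``K_se`` with parallel dashpot
``B_2``; a fiber element is a spring ``K_lt``, dashpot ``B_1`` and an
active-state tension generator ``F_j^i`` in parallel.  The element
stretch states ``y_j^i`` obey first-order equations that are each affine
in the (unknown) column tension ``T_i``; the series constraint -- element
stretch-rates along a column sum to the muscle end velocity -- closes the
system with one linear equation per column, so ``T_i`` is eliminated
algebraically at every step rather than integrated.

The net muscle forces drive the eyeball,

    T_ag - T_ant = J_p r theta'' + B_p r theta' + K_p r theta,

with ``r`` the eyeball radius.  Both muscles are pre-stretched by
3.705 mm at the primary position; rotation by ``theta`` slackens the
agonist by ``r * theta`` and stretches the antagonist by the same arc
length.

External units are ms and degrees; internally the plant integrates in
SI (s, m, N, rad).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEG",
    "MONKEY_WHOLE_MUSCLE",
    "default_plant",
    "PlantParams",
    "PlantState",
    "SaccadeMetrics",
    "fiber_parameter_scaling",
    "column_tension",
    "muscle_torques",
    "plant_derivatives",
    "initial_state",
    "equilibrium_angle",
    "tension_position_slope",
    "simulate_plant",
    "saccade_metrics",
]

DEG = np.pi / 180.0


@dataclass(frozen=True)
class PlantParams:
    """Element-level mechanical parameters (SI units).

    ``k_se``/``b_2`` describe one tendon element, ``k_lt``/``b_1`` one
    fiber element.  Use :func:`fiber_parameter_scaling` to derive these
    from whole-muscle estimates.
    """

    k_se: float          # N/m per tendon element
    b_2: float           # N·s/m per tendon element
    k_lt: float          # N/m per fiber element
    b_1: float           # N·s/m per fiber element
    j_p: float           # N·s²/m, eyeball inertia term
    b_p: float           # N·s/m, eyeball viscosity
    k_p: float           # N/m, eyeball passive elasticity
    r: float = 0.010     # m, eyeball radius (monkey)
    n: int = 1           # columns per muscle
    m: int = 100         # fibers per column
    initial_stretch: float = 3.705e-3   # m, pre-stretch at primary position

    def __post_init__(self) -> None:
        if min(self.k_se, self.b_2, self.k_lt, self.b_1,
               self.j_p, self.b_p, self.k_p, self.r) <= 0:
            raise ValueError("all mechanical parameters must be positive")
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")

    # -- whole-muscle aggregates (series-parallel reduction) ------------
    @property
    def k_se_muscle(self) -> float:
        """Aggregate series (tendon) stiffness of one muscle."""
        return self.n * self.k_se / 2.0

    @property
    def k_lt_muscle(self) -> float:
        """Aggregate fiber (length-tension) stiffness of one muscle."""
        return self.n * self.k_lt / self.m


def fiber_parameter_scaling(
    whole: PlantParams, n: int, m: int
) -> PlantParams:
    """Scale whole-muscle parameters to the element level.

    ``whole`` carries whole-muscle stiffness/viscosity in its tendon and
    fiber slots (i.e. the n = 1, m = 1, single-tendon-equivalent values).
    Elements in series are stiffer by the series count; parallel columns
    share load, so per-column element values divide by ``n``:

        k_se_elem = 2 k_se / n,   k_lt_elem = m k_lt / n,

    and likewise for the viscosities.  The aggregate static stiffness and
    viscosity of the scaled chain equal the whole-muscle values exactly.
    """
    return replace(
        whole,
        k_se=2.0 * whole.k_se / n,
        b_2=2.0 * whole.b_2 / n,
        k_lt=m * whole.k_lt / n,
        b_1=m * whole.b_1 / n,
        n=n,
        m=m,
    )


#: Whole-muscle mechanical estimates for the rectus muscle / eyeball
#: (linear homeomorphic oculomotor-plant literature; package defaults).
#: Stored in single-tendon-equivalent form: feed through
#: :func:`fiber_parameter_scaling` before simulating.
MONKEY_WHOLE_MUSCLE = PlantParams(
    k_se=125.0,      # N/m
    b_2=0.5,         # N·s/m
    k_lt=60.7,       # N/m
    b_1=2.0,         # N·s/m
    j_p=2.192e-3,    # N·s²/m
    b_p=0.327,       # N·s/m
    k_p=16.34,       # N/m
    r=0.010,         # m
    n=1,
    m=1,
)


def default_plant(n: int = 1, m: int = 100) -> PlantParams:
    """Element-scaled default plant (100 fibers per muscle)."""
    return fiber_parameter_scaling(MONKEY_WHOLE_MUSCLE, n, m)


@dataclass
class PlantState:
    """theta (rad), omega (rad/s) and element states y (2n, m+2) in m."""

    theta: float
    omega: float
    y: np.ndarray

    def copy(self) -> "PlantState":
        return PlantState(self.theta, self.omega, self.y.copy())


def _column_tensions(
    y: np.ndarray, xdot: float, f: np.ndarray, p: PlantParams, agonist: bool
) -> np.ndarray:
    """Solve the series constraint for T_i of every column of one muscle.

    ``y``: (n, m+2) element states; ``f``: (n, m) active tensions;
    ``xdot``: muscle end velocity (sum of element stretch rates, m/s).
    """
    tend = (y[:, 0] + y[:, -1]) / p.b_2
    denom = 2.0 / p.b_2 + p.m / p.b_1
    if agonist:
        num = -p.k_se * tend + (f - p.k_lt * y[:, 1:-1]).sum(axis=1) / p.b_1
        return (num - xdot) / denom
    num = p.k_se * tend + (p.k_lt * y[:, 1:-1] + f).sum(axis=1) / p.b_1
    return (xdot + num) / denom


def column_tension(
    y_column: np.ndarray,
    xdot: float,
    f_column: np.ndarray,
    params: PlantParams,
    side: str = "agonist",
) -> float:
    """Tension T_i of a single column (N).

    Each element stretch-rate is affine in T_i, so the series constraint
    sum(ydot_j) = xdot is one linear equation in T_i; this returns its
    unique solution (the denominator 2/B_2 + m/B_1 is positive for any
    positive viscosities).
    """
    y = np.asarray(y_column, dtype=float).reshape(1, -1)
    f = np.asarray(f_column, dtype=float).reshape(1, -1)
    if y.shape[1] != params.m + 2 or f.shape[1] != params.m:
        raise ValueError("column state must have m+2 elements and m tensions")
    return float(_column_tensions(y, xdot, f, params, side == "agonist")[0])


def muscle_torques(
    state: PlantState, forcing: tuple[np.ndarray, np.ndarray], params: PlantParams
) -> tuple[float, float]:
    """Net agonist and antagonist muscle forces (N).

    Computed from the printed sums over K_se y_1^i + B_2 ydot_1^i, which
    reduce exactly to the sum of column tensions.
    """
    f_ag, f_ant = forcing
    xdot = params.r * state.omega
    n = params.n
    t_ag = _column_tensions(state.y[:n], xdot, np.atleast_2d(f_ag), params, True)
    t_ant = _column_tensions(state.y[n:], xdot, np.atleast_2d(f_ant), params, False)
    return float(t_ag.sum()), float(t_ant.sum())


def plant_derivatives(
    state: PlantState,
    forcing: tuple[np.ndarray, np.ndarray],
    params: PlantParams,
) -> tuple[float, float, np.ndarray]:
    """(dtheta, domega, dy) under per-fiber active tensions.

    ``forcing`` is ``(f_ag, f_ant)``, each (n, m) or broadcastable, in N.
    """
    p = params
    f_ag = np.broadcast_to(np.asarray(forcing[0], dtype=float), (p.n, p.m))
    f_ant = np.broadcast_to(np.asarray(forcing[1], dtype=float), (p.n, p.m))
    xdot = p.r * state.omega          # both muscles: sum(ydot) = +r*omega
    y_ag, y_ant = state.y[: p.n], state.y[p.n:]
    t_i_ag = _column_tensions(y_ag, xdot, f_ag, p, True)
    t_i_ant = _column_tensions(y_ant, xdot, f_ant, p, False)

    dy = np.empty_like(state.y)
    dy[: p.n, 0] = -(t_i_ag + p.k_se * y_ag[:, 0]) / p.b_2
    dy[: p.n, -1] = -(t_i_ag + p.k_se * y_ag[:, -1]) / p.b_2
    dy[: p.n, 1:-1] = (-t_i_ag[:, None] - p.k_lt * y_ag[:, 1:-1] + f_ag) / p.b_1
    dy[p.n:, 0] = (t_i_ant - p.k_se * y_ant[:, 0]) / p.b_2
    dy[p.n:, -1] = (t_i_ant - p.k_se * y_ant[:, -1]) / p.b_2
    dy[p.n:, 1:-1] = (t_i_ant[:, None] - p.k_lt * y_ant[:, 1:-1] - f_ant) / p.b_1

    t_ag, t_ant = t_i_ag.sum(), t_i_ant.sum()
    domega = (t_ag - t_ant - p.k_p * p.r * state.theta
              - p.b_p * p.r * state.omega) / (p.j_p * p.r)
    return state.omega, float(domega), dy


def tension_position_slope(params: PlantParams) -> float:
    """d(F_ag - F_ant)/2 per degree that holds the eye in equilibrium (N/deg).

    From the static reduction of the chain: the column tension under
    uniform fiber tension F and total stretch s is
    T = c1 F - c2 * sum(y) with c1 = K_se/(K_se + K_lt) and
    c2 = K_se K_lt/(K_se + K_lt) (whole-muscle aggregates), and the
    balance c1 (F_ag - F_ant) = (K_p + 2 c2) r theta.
    """
    kse, klt = params.k_se_muscle, params.k_lt_muscle
    c1 = kse / (kse + klt)
    c2 = kse * klt / (kse + klt)
    return (params.k_p + 2.0 * c2) * params.r * DEG / (2.0 * c1)


def equilibrium_angle(
    f_ag: float, f_ant: float, params: PlantParams
) -> float:
    """Static eye position (deg) under uniform mean fiber tensions (N)."""
    kse, klt = params.k_se_muscle, params.k_lt_muscle
    c1 = kse / (kse + klt)
    c2 = kse * klt / (kse + klt)
    theta = c1 * (f_ag - f_ant) / ((params.k_p + 2.0 * c2) * params.r)
    return float(theta / DEG)


def initial_state(
    params: PlantParams, theta0_deg: float, f_ag0: float, f_ant0: float
) -> PlantState:
    """Fixation equilibrium state at ``theta0`` with uniform tensions.

    Element states are distributed per the static per-element solution,
    with the 3.705 mm pre-stretch carried by the initial tensions.
    """
    p = params
    theta = theta0_deg * DEG
    x = p.r * theta
    kse, klt = p.k_se_muscle, p.k_lt_muscle
    c1 = kse / (kse + klt)
    c2 = kse * klt / (kse + klt)
    s0 = p.initial_stretch
    t_ag = c1 * f_ag0 + c2 * (s0 - x)      # per column: T_i = T/n
    t_ant = c1 * f_ant0 + c2 * (s0 + x)
    y = np.empty((2 * p.n, p.m + 2))
    ti = t_ag / p.n
    y[: p.n, 0] = y[: p.n, -1] = -ti / p.k_se
    y[: p.n, 1:-1] = (f_ag0 / p.n - ti) / p.k_lt
    ti = t_ant / p.n
    y[p.n:, 0] = y[p.n:, -1] = ti / p.k_se
    y[p.n:, 1:-1] = (ti - f_ant0 / p.n) / p.k_lt
    return PlantState(theta, 0.0, y)


@dataclass(frozen=True)
class SaccadeMetrics:
    onset_ms: float
    duration_ms: float
    magnitude_deg: float
    peak_velocity_deg_s: float
    final_position_deg: float


def simulate_plant(
    forcing,
    params: PlantParams,
    duration: float,
    dt: float = 0.01,
    state0: PlantState | None = None,
    theta0_deg: float = 0.0,
    f_fix: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the plant with fixed-step RK4 on the network grid.

    ``forcing(t_ms)`` must return per-fiber active tensions
    ``(f_ag, f_ant)`` in N, each broadcastable to (n, m).  ``duration``
    and ``dt`` are in ms.  The initial state defaults to the fixation
    equilibrium at ``theta0_deg`` under ``f_fix`` (or under the t=0
    forcing values).  Returns ``(t_ms, theta_deg, thetadot_deg_s)``.
    """
    p = params
    if state0 is None:
        if f_fix is None:
            f0 = forcing(0.0)
            f_fix = (float(np.mean(f0[0])) * p.n * 1.0,
                     float(np.mean(f0[1])) * p.n * 1.0)
            # mean fiber tension * n columns = whole-muscle active tension
            f_fix = (f_fix[0], f_fix[1])
        state0 = initial_state(p, theta0_deg, f_fix[0], f_fix[1])
    st = state0.copy()
    n_steps = int(round(duration / dt))
    t_ms = np.arange(n_steps + 1) * dt
    theta = np.empty(n_steps + 1)
    omega = np.empty(n_steps + 1)
    theta[0], omega[0] = st.theta / DEG, st.omega / DEG
    h = dt * 1e-3  # s
    for k in range(n_steps):
        t0 = t_ms[k]
        f1 = forcing(t0)
        f2 = forcing(t0 + 0.5 * dt)
        f3 = forcing(t0 + dt)
        a = plant_derivatives(st, f1, p)
        s2 = PlantState(st.theta + 0.5 * h * a[0], st.omega + 0.5 * h * a[1],
                        st.y + 0.5 * h * a[2])
        b = plant_derivatives(s2, f2, p)
        s3 = PlantState(st.theta + 0.5 * h * b[0], st.omega + 0.5 * h * b[1],
                        st.y + 0.5 * h * b[2])
        c = plant_derivatives(s3, f2, p)
        s4 = PlantState(st.theta + h * c[0], st.omega + h * c[1],
                        st.y + h * c[2])
        d = plant_derivatives(s4, f3, p)
        st.theta += h / 6.0 * (a[0] + 2 * b[0] + 2 * c[0] + d[0])
        st.omega += h / 6.0 * (a[1] + 2 * b[1] + 2 * c[1] + d[1])
        st.y += h / 6.0 * (a[2] + 2 * b[2] + 2 * c[2] + d[2])
        theta[k + 1] = st.theta / DEG
        omega[k + 1] = st.omega / DEG
        if abs(theta[k + 1]) > 90.0:
            raise FloatingPointError(
                f"plant unstable: |theta| > 90 deg at t={t_ms[k+1]:.2f} ms")
    return t_ms, theta, omega


def saccade_metrics(
    t_ms: np.ndarray,
    theta_deg: np.ndarray,
    omega_deg_s: np.ndarray,
    velocity_threshold: float = 10.0,
) -> SaccadeMetrics:
    """Saccade onset/offset by the |velocity| threshold convention.

    Onset is the first sample with |velocity| above threshold; offset is
    the first sample after the velocity peak where |velocity| falls back
    below it (a post-saccadic glissade does not extend the duration).
    """
    speed = np.abs(omega_deg_s)
    idx = np.flatnonzero(speed > velocity_threshold)
    if idx.size == 0:
        return SaccadeMetrics(np.nan, 0.0, 0.0, float(np.max(speed)),
                              float(theta_deg[-1]))
    onset = t_ms[idx[0]]
    k_peak = int(np.argmax(speed))
    after = np.flatnonzero(speed[k_peak:] < velocity_threshold)
    k_end = k_peak + int(after[0]) if after.size else int(idx[-1])
    return SaccadeMetrics(
        onset_ms=float(onset),
        duration_ms=float(t_ms[k_end] - onset),
        magnitude_deg=float(theta_deg[k_end] - theta_deg[0]),
        peak_velocity_deg_s=float(np.max(speed)),
        final_position_deg=float(theta_deg[-1]),
    )
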