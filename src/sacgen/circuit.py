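"""The two-sided parallel-distributed saccadic burst generator.

Fifteen units -- a single midline OPN plus ipsilateral and contralateral
copies of LLBN, EBN, IBN, TN, IN, AN and ON -- are wired with signed
pulse-train synapses and driven by scripted superior-colliculus and
fastigial-nucleus waveforms.  A saccade to the right ("ipsilateral")
unfolds as: the contralateral SC drive excites the ipsilateral LLBN and
EBN; the LLBN inhibits the OPN, whose pause releases the burst neurons;
the EBN bursts (it is autonomously active once released), exciting the
TN and the motoneurons; the IBN silences the antagonist side; at the
scripted termination the ipsilateral FN end-burst raises the
contralateral IBN, which chokes the ipsilateral burst, and the OPN
resumes as the collicular drive ends.

The scripted drives are waveform generators, not spiking models: the SC
burst is a pulse train whose envelope ramps down linearly, the FN drives
are constant-rate trains gated by the timing choreography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from . import _engine
from .axon import COEFF_UNITY, HHParams, resting_state
from .dendrite import DendriteParams, Pulse, StimulusTrain
from .synapse import SynapseParams
from .tonic import FHNParams

__all__ = [
    "POPULATIONS",
    "SIDES",
    "NeuronSpec",
    "ConnectionSpec",
    "DriveScript",
    "Scenario",
    "Network",
    "SimulationResult",
    "scenario_from_config",
    "build_network",
    "simulate_circuit",
    "extract_rate_signal",
    "motoneuron_commands",
    "burst_window",
    "pause_window",
]

POPULATIONS = ("LLBN", "OPN", "EBN", "IBN", "TN", "IN", "AN", "ON")
SIDES = ("ipsi", "contra")
_FHN_POPS = ("TN", "IN")


@dataclass(frozen=True)
class Scenario:
    magnitude: float        # deg, target saccade size
    burst_duration: float   # ms, agonist pulse duration
    n_active: int           # active agonist neurons (of m fibers)

    def __post_init__(self) -> None:
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        if self.n_active < 0:
            raise ValueError("n_active must be non-negative")


def scenario_from_config(cfg: Mapping[str, Any], magnitude: float) -> Scenario:
    table = cfg["scenarios"]
    key = int(round(magnitude))
    if key not in table and str(key) not in table:
        raise KeyError(
            f"unknown scenario {magnitude} deg; configured: {sorted(table)}")
    row = table.get(key, table.get(str(key)))
    return Scenario(float(magnitude), float(row["burst_duration_ms"]),
                    int(row["n_active"]))


@dataclass(frozen=True)
class NeuronSpec:
    name: str
    side: str                       # 'ipsi' | 'contra' | 'midline' (OPN)
    dendrite: DendriteParams
    axon: HHParams | None           # None for FHN units
    fhn: FHNParams | None
    synapse: SynapseParams

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}")
        if (self.axon is None) == (self.fhn is None):
            raise ValueError("exactly one of axon/fhn must be set")


@dataclass(frozen=True)
class ConnectionSpec:
    source: tuple[str, str]
    target: tuple[str, str]
    sign: int
    synapse: SynapseParams

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-connections are not allowed")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class DriveScript:
    """Scripted external drives and timing gates (all times in ms).

    Pulse amplitudes are per postsynaptic target (synaptic strength is a
    property of the receiving membrane): the collicular burst drives the
    LLBN hard and the EBN weakly; the fastigial drives mainly recruit
    the IBN.
    """

    t1: float                   # saccade start (end of latent period)
    burst_duration: float
    n_active: int
    sc_window: tuple[float, float]
    fn_window: tuple[float, float]        # contralateral FN sustained drive
    fn_end_window: tuple[float, float]    # ipsilateral FN end-of-saccade burst
    sc_rate: float = 800.0
    sc_width: float = 0.5
    sc_amp: Mapping[str, float] = field(
        default_factory=lambda: {"LLBN": 30.0, "EBN": 2.0})
    sc_ramp_final: float = 0.65
    fn_rate: float = 200.0
    fn_width: float = 1.0
    fn_amp: Mapping[str, float] = field(
        default_factory=lambda: {"LLBN": 6.0, "EBN": 1.0, "IBN": 25.0})
    fn_end_rate: float = 200.0
    fn_end_width: float = 1.0
    fn_end_amp: Mapping[str, float] = field(
        default_factory=lambda: {"LLBN": 4.0, "EBN": 1.0, "IBN": 25.0})

    def __post_init__(self) -> None:
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        for w in (self.sc_window, self.fn_window, self.fn_end_window):
            if not (np.isfinite(w[0]) and np.isfinite(w[1]) and w[0] < w[1]):
                raise ValueError("drive windows must be finite and ordered")

    @property
    def t2(self) -> float:
        return self.t1 + self.burst_duration

    def sc_train(self, target: str) -> StimulusTrain:
        """Collicular burst: pulse train with a linear ramp-down envelope."""
        return _pulse_train(self.sc_window, self.sc_rate, self.sc_width,
                            self.sc_amp.get(target, 0.0), self.sc_ramp_final)

    def fn_train(self, target: str) -> StimulusTrain:
        return _pulse_train(self.fn_window, self.fn_rate, self.fn_width,
                            self.fn_amp.get(target, 0.0))

    def fn_end_train(self, target: str) -> StimulusTrain:
        return _pulse_train(self.fn_end_window, self.fn_end_rate,
                            self.fn_end_width, self.fn_end_amp.get(target, 0.0))


def _pulse_train(window, rate_hz, width, amplitude, ramp_final=1.0):
    if amplitude <= 0.0:
        return StimulusTrain()
    start, stop = window
    period = 1000.0 / rate_hz
    onsets = np.arange(start, stop - width, period)
    if onsets.size == 0:
        return StimulusTrain()
    frac = (onsets - start) / max(stop - start, 1e-9)
    amps = amplitude * (1.0 + (ramp_final - 1.0) * frac)
    return StimulusTrain(tuple(
        Pulse(float(o), width, float(a)) for o, a in zip(onsets, amps)))


@dataclass
class Network:
    neurons: list[NeuronSpec]
    connections: list[ConnectionSpec]
    drives: DriveScript
    config: dict = field(default_factory=dict)

    def index(self, name: str, side: str = "ipsi") -> int:
        if name == "OPN":
            side = "midline"
        for i, nsp in enumerate(self.neurons):
            if nsp.name == name and nsp.side == side:
                return i
        raise KeyError(f"no unit {name}/{side}")


# Fig-1 wiring: (source pop, source side) -> (target pop, target side, sign)
# expressed for the ipsilateral side; mirrored for the contralateral side.
# 'same' is the acting side, 'other' the opposite one.
_WIRING = [
    ("LLBN", "same", "OPN", "midline", -1),
    ("LLBN", "same", "IBN", "same", +1),
    ("OPN", "midline", "EBN", "same", -1),
    ("OPN", "midline", "IBN", "same", -1),
    ("IBN", "same", "EBN", "other", -1),
    ("IBN", "same", "TN", "other", -1),
    ("IBN", "same", "AN", "other", -1),
    ("IBN", "same", "ON", "same", -1),
    ("IBN", "same", "IN", "same", -1),
    ("EBN", "same", "TN", "same", +1),
    ("EBN", "same", "AN", "same", +1),
    ("TN", "same", "IN", "same", +1),
    ("IN", "same", "AN", "same", +1),
    ("AN", "same", "ON", "other", +1),
]


def _neuron_spec(name: str, side: str, cfg: Mapping[str, Any]) -> NeuronSpec:
    common = cfg["dendrite_common"]
    blk = cfg["neurons"][name]
    dend = DendriteParams(
        n_compartments=int(common["n_compartments"]),
        c_m=float(blk["dendrite"]["c_m"]),
        r_eq=float(blk["dendrite"]["r_eq"]),
        r_a=float(common["r_a_ohm"]),
        v_th=float(common["v_th_mv"]),
    )
    syn = SynapseParams(
        pulse_amplitude=float(blk["synapse"]["pulse_amplitude"]),
        detection_level=float(blk["synapse"].get(
            "detection_level", cfg["synapse_common"]["detection_level_mv"])),
        axonal_delay=float(cfg["synapse_common"]["axonal_delay_ms"]),
    )
    if name in _FHN_POPS:
        f = blk["fhn"]
        fhn = FHNParams(a=float(f["a"]), b=float(f["b"]), eps=float(f["eps"]),
                        speed=float(f["speed"]),
                        input_gain=float(f["input_gain"]),
                        integral_gain=float(f["integral_gain"]),
                        i_rest=float(f["i_rest"]))
        return NeuronSpec(name, side, dend, None, fhn, syn)
    ax = HHParams(variant=str(blk["axon"]["variant"]),
                  rate_coefficient=float(blk["axon"]["rate_coefficient"]))
    return NeuronSpec(name, side, dend, ax, None, syn)


def build_network(scenario: Scenario, cfg: Mapping[str, Any]) -> Network:
    """Assemble neurons, wiring and drive script for one saccade scenario."""
    neurons = [_neuron_spec("OPN", "midline", cfg)]
    for side in SIDES:
        for name in POPULATIONS:
            if name == "OPN":
                continue
            neurons.append(_neuron_spec(name, side, cfg))

    def spec_of(name, side):
        for nsp in neurons:
            if nsp.name == name and nsp.side == side:
                return nsp
        raise KeyError((name, side))

    connections: list[ConnectionSpec] = []
    for acting in SIDES:
        other = "contra" if acting == "ipsi" else "ipsi"
        for src, s_side, dst, d_side, sign in _WIRING:
            s = "midline" if src == "OPN" else (acting if s_side == "same" else other)
            d = ("midline" if dst == "OPN"
                 else acting if d_side == "same" else other)
            src_spec = spec_of(src, s)
            delay = float(cfg.get("connection_delays", {}).get(
                f"{src}->{dst}", src_spec.synapse.axonal_delay))
            level = float(cfg.get("connection_detection_levels", {}).get(
                f"{src}->{dst}", src_spec.synapse.detection_level))
            syn = SynapseParams(
                pulse_amplitude=src_spec.synapse.pulse_amplitude,
                detection_level=level,
                axonal_delay=delay,
                sign=sign,
            )
            conn = ConnectionSpec((src, s), (dst, d), sign, syn)
            if conn not in connections:
                connections.append(conn)

    t = cfg["timing"]
    d = cfg["drives"]
    t1 = float(t["latent_period_ms"])
    t2 = t1 + scenario.burst_duration
    drives = DriveScript(
        t1=t1,
        burst_duration=scenario.burst_duration,
        n_active=scenario.n_active,
        sc_window=(t1 - float(t["sc_lead_ms"]), t2 + float(t["sc_end_offset_ms"])),
        fn_window=(t1 - float(t["fn_lead_ms"]), t2 + float(t["fn_end_offset_ms"])),
        fn_end_window=(t2 + float(t["fn_burst_lead_ms"]),
                       t2 + float(t["fn_burst_lead_ms"]) + float(t["fn_burst_width_ms"])),
        sc_rate=float(d["sc"]["rate_hz"]), sc_width=float(d["sc"]["pulse_width_ms"]),
        sc_amp={k: float(v) for k, v in d["sc"]["amplitude_ua"].items()},
        sc_ramp_final=float(d["sc"]["ramp_final_fraction"]),
        fn_rate=float(d["fn"]["rate_hz"]), fn_width=float(d["fn"]["pulse_width_ms"]),
        fn_amp={k: float(v) for k, v in d["fn"]["amplitude_ua"].items()},
        fn_end_rate=float(d["fn_end"]["rate_hz"]),
        fn_end_width=float(d["fn_end"]["pulse_width_ms"]),
        fn_end_amp={k: float(v) for k, v in d["fn_end"]["amplitude_ua"].items()},
    )
    net = Network(neurons, connections, drives, dict(cfg))
    _check_structure(net)
    return net


def _check_structure(net: Network) -> None:
    opn = [n for n in net.neurons if n.name == "OPN"]
    if len(opn) != 1:
        raise ValueError("exactly one OPN required")
    for name in POPULATIONS:
        if name == "OPN":
            continue
        for side in SIDES:
            if sum(1 for n in net.neurons
                   if n.name == name and n.side == side) != 1:
                raise ValueError(f"population {name}/{side} must appear once")
    for c in net.connections:
        if c.source == c.target:
            raise ValueError("self-connection found")


@dataclass
class SimulationResult:
    """Shared-grid traces, spike trains and crossing times per unit."""

    t: np.ndarray                       # recording grid (ms)
    v_dendrite: np.ndarray              # (nu, len(t)) last-compartment potential
    v_axon: np.ndarray                  # (nu, len(t))
    spikes: dict[tuple[str, str], np.ndarray]
    crossings_up: dict[tuple[str, str], np.ndarray]
    crossings_down: dict[tuple[str, str], np.ndarray]
    dt: float
    duration: float
    network: Network

    def unit_key(self, name: str, side: str = "ipsi") -> tuple[str, str]:
        return (name, "midline" if name == "OPN" else side)

    def spike_train(self, name: str, side: str = "ipsi") -> np.ndarray:
        return self.spikes[self.unit_key(name, side)]

    def pulse_train(self, name: str, side: str = "ipsi",
                    sign: int = 1) -> StimulusTrain:
        """Reconstruct the unit's synaptic output as a StimulusTrain."""
        key = self.unit_key(name, side)
        spec = self.network.neurons[self.network.index(name, side)]
        ups = self.crossings_up[key]
        downs = self.crossings_down[key]
        n = min(ups.size, downs.size)
        syn = spec.synapse
        return StimulusTrain(tuple(
            Pulse(float(u + syn.axonal_delay), float(dn - u),
                  syn.pulse_amplitude, sign)
            for u, dn in zip(ups[:n], downs[:n]) if dn > u))


def simulate_circuit(
    network: Network, duration: float, dt: float = 0.002,
    record_every: int | None = None,
) -> SimulationResult:
    """Run the coupled network for ``duration`` ms."""
    cfg = network.config
    if record_every is None:
        record_every = int(cfg.get("simulation", {}).get("record_every", 25))
    nu = len(network.neurons)
    ncomp = network.neurons[0].dendrite.n_compartments
    n_steps = int(round(duration / dt))

    kind = np.zeros(nu, dtype=np.int64)
    vd = np.empty((nu, ncomp))
    d_cm = np.empty(nu)
    d_req = np.empty(nu)
    d_ra = np.empty(nu)
    d_vth = np.empty(nu)
    hh_state = np.zeros((nu, 4))
    hh_speed = np.ones(nu)
    fhn_state = np.zeros((nu, 3))
    f_a = np.zeros(nu)
    f_b = np.ones(nu)
    f_eps = np.full(nu, 0.08)
    f_speed = np.ones(nu)
    f_gain = np.zeros(nu)
    f_qgain = np.zeros(nu)
    f_irest = np.zeros(nu)
    f_scale = np.full(nu, 30.0)
    f_offset = np.full(nu, -25.0)
    level = np.zeros(nu)

    ref_hh = HHParams()
    for i, nsp in enumerate(network.neurons):
        d = nsp.dendrite
        vd[i] = d.v_th
        d_cm[i], d_req[i] = d.c_m, d.r_eq
        d_ra[i], d_vth[i] = d.r_a_kohm, d.v_th
        level[i] = nsp.synapse.detection_level
        if nsp.fhn is not None:
            kind[i] = 2
            f = nsp.fhn
            f_a[i], f_b[i], f_eps[i], f_speed[i] = f.a, f.b, f.eps, f.speed
            f_gain[i], f_qgain[i], f_irest[i] = (f.input_gain,
                                                 f.integral_gain, f.i_rest)
            f_scale[i], f_offset[i] = f.out_scale, f.out_offset
            fhn_state[i] = (-1.2, (-1.2 + f.a) / f.b, 0.0)
        else:
            kind[i] = 1 if nsp.axon.variant == "modified" else 0
            hh_speed[i] = nsp.axon.rate_coefficient / COEFF_UNITY
            st = resting_state(nsp.axon)
            hh_state[i] = (st.v_m, st.n, st.m, st.h)

    conn_src = np.array([network.index(*c.source) for c in network.connections],
                        dtype=np.int64)
    conn_dst = np.array([network.index(*c.target) for c in network.connections],
                        dtype=np.int64)
    conn_w = np.array([c.sign * c.synapse.pulse_amplitude
                       for c in network.connections])
    conn_delay = np.array([max(1, int(round(c.synapse.axonal_delay / dt)))
                           for c in network.connections], dtype=np.int64)
    conn_level = np.array([c.synapse.detection_level
                           for c in network.connections])

    # scripted drives sampled on the integration grid
    drive = np.zeros((nu, n_steps))
    tgrid = (np.arange(n_steps) + 0.5) * dt
    ds = network.drives
    # contralateral SC / FN excite the ipsilateral burst side (and the
    # ipsilateral FN end-burst raises the contralateral side)
    for pop in ("LLBN", "EBN", "IBN"):
        drive[network.index(pop, "ipsi")] = (
            ds.sc_train(pop).sample(tgrid) + ds.fn_train(pop).sample(tgrid))
        drive[network.index(pop, "contra")] = ds.fn_end_train(pop).sample(tgrid)

    (rec_d, rec_a, spike_t, spike_n, up_t, up_n, down_t, down_n
     ) = _engine.run_network(
        dt, n_steps, kind, vd, d_cm, d_req, d_ra, d_vth,
        hh_state, hh_speed,
        ref_hh.g_k_bar * 1e3, ref_hh.g_na_bar * 1e3, ref_hh.e_k, ref_hh.e_na,
        ref_hh.e_l, 1.0 / ref_hh.r_l, ref_hh.c_m, ref_hh.v_rp,
        fhn_state, f_a, f_b, f_eps, f_speed, f_gain, f_qgain, f_irest,
        f_scale, f_offset,
        conn_src, conn_dst, conn_w, conn_delay, conn_level, level, 0.0,
        drive, record_every,
    )
    if not (np.all(np.isfinite(rec_a)) and np.all(np.isfinite(rec_d))):
        u = int(np.argwhere(~np.isfinite(rec_a))[0][0])
        nsp = network.neurons[u]
        raise FloatingPointError(
            f"network integration failed for {nsp.name}/{nsp.side}")

    keys = [(n.name, n.side) for n in network.neurons]
    spikes = {k: spike_t[i, : spike_n[i]].copy() for i, k in enumerate(keys)}
    ups = {k: up_t[i, : up_n[i]].copy() for i, k in enumerate(keys)}
    downs = {k: down_t[i, : down_n[i]].copy() for i, k in enumerate(keys)}
    t_rec = np.arange(rec_d.shape[1]) * dt * record_every
    return SimulationResult(t_rec, rec_d, rec_a, spikes, ups, downs,
                            dt, duration, network)


def extract_rate_signal(
    spike_times: np.ndarray,
    t: np.ndarray,
    smoothing_window: float = 0.0,
) -> np.ndarray:
    """Instantaneous firing rate (Hz): reciprocal of the bracketing ISI.

    Sample-and-hold between spikes, zero where no interspike interval
    brackets the sample, optionally smoothed by a centred moving average
    of the stated window (ms).
    """
    t = np.asarray(t, dtype=float)
    s = np.sort(np.asarray(spike_times, dtype=float))
    rate = np.zeros_like(t)
    if s.size >= 2:
        isi = np.diff(s)
        idx = np.searchsorted(s, t, side="right") - 1
        inside = (idx >= 0) & (idx < isi.size)
        rate[inside] = 1000.0 / isi[idx[inside]]
    if smoothing_window > 0 and t.size > 1:
        dt = t[1] - t[0]
        w = max(1, int(round(smoothing_window / dt)))
        kernel = np.ones(w) / w
        rate = np.convolve(rate, kernel, mode="same")
    return rate


def motoneuron_commands(
    result: SimulationResult,
    side: str = "ipsi",
    baseline_rate: float = 100.0,
    peak_rate: float = 700.0,
    fixation_tension: float = 0.4,
    pulse_magnitude: float = 0.65,
    smoothing_window: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t, N_ag, N_ant) in whole-muscle tension units (N).

    The affine rate-to-tension map is anchored so the fixation-state
    tonic rate maps to the fixation tension and the nominal motoneuron
    plateau rate maps to the saturated pulse magnitude.  Agonist
    innervation is the ipsilateral AN rate; antagonist is the
    ipsilateral ON rate (the contralateral eye uses the mirrored pair).
    """
    other = "contra" if side == "ipsi" else "ipsi"
    t = result.t
    r_ag = extract_rate_signal(result.spike_train("AN", side), t, smoothing_window)
    r_ant = extract_rate_signal(result.spike_train("ON", side), t, smoothing_window)
    slope = (pulse_magnitude - fixation_tension) / (peak_rate - baseline_rate)
    intercept = fixation_tension - slope * baseline_rate

    def to_tension(r):
        return np.maximum(slope * r + intercept, 0.0)

    return t, to_tension(r_ag), to_tension(r_ant)


def burst_window(
    spikes: np.ndarray, max_isi: float = 4.0, min_spikes: int = 5
) -> tuple[float, float]:
    """(onset, offset) of the longest high-frequency run in a spike train.

    A burst is a maximal run of consecutive interspike intervals below
    ``max_isi`` ms; returns NaNs if no run has ``min_spikes`` spikes.
    """
    s = np.sort(np.asarray(spikes, dtype=float))
    if s.size < min_spikes:
        return (np.nan, np.nan)
    fast = np.diff(s) <= max_isi
    best_len, best = 0, None
    k = 0
    while k < fast.size:
        if fast[k]:
            j = k
            while j < fast.size and fast[j]:
                j += 1
            if j - k + 1 > best_len:
                best_len, best = j - k + 1, (s[k], s[j])
            k = j
        k += 1
    if best is None or best_len < min_spikes:
        return (np.nan, np.nan)
    return (float(best[0]), float(best[1]))


def pause_window(
    spikes: np.ndarray, min_gap: float = 15.0,
    t_lo: float = 0.0, t_hi: float = np.inf,
) -> tuple[float, float]:
    """(start, end) of the longest firing gap overlapping [t_lo, t_hi]."""
    s = np.sort(np.asarray(spikes, dtype=float))
    if s.size < 2:
        return (np.nan, np.nan)
    gaps = np.diff(s)
    best = None
    for k in np.flatnonzero(gaps >= min_gap):
        if s[k + 1] >= t_lo and s[k] <= t_hi:
            if best is None or gaps[k] > best[1] - best[0]:
                best = (s[k], s[k + 1])
    return (np.nan, np.nan) if best is None else (float(best[0]), float(best[1]))
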