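"""Scenario orchestration: circuit -> controller -> plant, end to end.

``run_saccade`` executes one scenario: the spiking network
produces the motoneuron burst timing and rate signals; the innervation
commands are assembled from them (pulse window and height from the
abducens burst, fixation steps from the plant-equilibrium map, exactly
how the fixation tensions are defined); the time-optimal controller
low-pass filters the commands into per-fiber active-state tensions; and
the muscle-fiber plant integrates the eye trajectory.

The number of active agonist neurons is realised as ``n_active`` fibers
receiving the motoneuron command while the remaining fibers follow the
inactive-fiber program (exponential release and recovery with the
agonist time constants).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .circuit import (
    Scenario,
    SimulationResult,
    build_network,
    burst_window,
    motoneuron_commands,
    pause_window,
    scenario_from_config,
    simulate_circuit,
)
from .config import config_fingerprint, default_config
from .controller import (
    ControllerParams,
    agonist_filter,
    antagonist_filter,
    inactive_fiber_program,
    steady_state_tensions,
)
from .plant import (
    PlantParams,
    SaccadeMetrics,
    fiber_parameter_scaling,
    initial_state,
    saccade_metrics,
    simulate_plant,
)

__all__ = ["RunReport", "plant_from_config", "run_saccade", "main_sequence",
           "neuron_demo", "choreography", "ebn_peak_firing_rate",
           "threshold_voltages"]

# population-specific burst ISI thresholds (ms) for event extraction:
# a burst is a run of ISIs shorter than these
_BURST_ISI = {"LLBN": 8.0, "EBN": 6.0, "IBN": 8.0, "AN": 4.0, "ON": 4.0}


def ebn_peak_firing_rate(
    cfg: Mapping[str, Any] | None = None,
    duration: float = 100.0,
    dt: float = 0.002,
) -> float:
    """Peak EBN firing rate (Hz) under sustained suprathreshold drive.

    Builds the excitatory burst neuron from its configured membrane row
    (dendrite chain + modified HH axon at the calibrated rate
    coefficient), drives the dendrite with the standard sustained
    excitatory pulse train, detects spikes at 0 mV upward crossings and
    reports the reciprocal of the minimum interspike interval.
    """
    from .axon import HHParams, simulate_axon
    from .circuit import _neuron_spec, _pulse_train
    from .dendrite import simulate_dendrite

    cfg = cfg or default_config()
    cal = cfg.get("calibration", {})
    amp = float(cal.get("ebn_drive_amplitude_ua", 8.0))
    rate = float(cal.get("ebn_drive_rate_hz", 800.0))
    width = float(cal.get("ebn_drive_width_ms", 0.5))
    spec = _neuron_spec("EBN", "ipsi", cfg)
    train = _pulse_train((2.0, duration), rate, width, amp)
    _, v = simulate_dendrite(train, spec.dendrite, duration, dt=dt)
    i_m = (v[:-1, -1] - spec.dendrite.v_th) / spec.dendrite.r_a_kohm
    _, _, spikes = simulate_axon(i_m, spec.axon, dt=dt)
    if spikes.size < 2:
        return 0.0
    return float(1000.0 / np.min(np.diff(spikes)))


def threshold_voltages(cfg: Mapping[str, Any] | None = None) -> dict[str, float]:
    """Firing thresholds (mV) of both axon variants by pulse bisection."""
    from .axon import HHParams, find_threshold_voltage

    return {
        "basic": find_threshold_voltage(HHParams(variant="basic")),
        "modified": find_threshold_voltage(HHParams(variant="modified")),
    }


def plant_from_config(cfg: Mapping[str, Any]) -> PlantParams:
    p = cfg["plant"]
    whole = PlantParams(
        k_se=float(p["k_se"]), b_2=float(p["b_2"]),
        k_lt=float(p["k_lt"]), b_1=float(p["b_1"]),
        j_p=float(p["j_p"]), b_p=float(p["b_p"]), k_p=float(p["k_p"]),
        r=float(p["r_m"]), n=1, m=1,
        initial_stretch=float(p["initial_stretch_m"]),
    )
    return fiber_parameter_scaling(whole, int(p["n_columns"]),
                                   int(p["m_fibers"]))


@dataclass
class RunReport:
    scenario: dict
    metrics: SaccadeMetrics
    events: dict
    config_fingerprint: str
    trace_files: list[str]

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "metrics": asdict(self.metrics),
            "events": self.events,
            "config_fingerprint": self.config_fingerprint,
            "trace_files": self.trace_files,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _population_events(res: SimulationResult, t1: float, t2: float) -> dict:
    """Burst/pause windows of each population (absolute times, ms)."""
    events: dict[str, Any] = {}
    for name, isi in _BURST_ISI.items():
        for side in ("ipsi", "contra"):
            s = res.spike_train(name, side)
            s = s[s > 60.0]   # drop the initial network settling transient
            on, off = burst_window(s, max_isi=isi)
            events[f"{name}_{side}_burst"] = [on, off]
    opn = res.spike_train("OPN")
    events["OPN_pause"] = list(pause_window(opn, min_gap=15.0,
                                            t_lo=t1 - 30.0, t_hi=t2 + 30.0))
    for side in ("ipsi", "contra"):
        for name in ("TN", "IN"):
            s = res.spike_train(name, side)
            after = s[s > t2]
            events[f"{name}_{side}_resume"] = (
                float(after[0]) if after.size else np.nan)
    return events


def _commands(
    res: SimulationResult,
    t_grid: np.ndarray,
    cfg: Mapping[str, Any],
    theta_target: float,
    plant: PlantParams,
) -> tuple[np.ndarray, np.ndarray, ControllerParams, dict]:
    """Assemble N_ag / N_ant (whole-muscle tension units) on the plant grid."""
    ctrl = cfg["controller"]
    rmap = cfg["rate_map"]
    f_fix0 = float(ctrl["fixation_tension_n"])
    pulse_mag = float(ctrl["pulse_magnitude_n"])
    f_ag_t, f_ant_t = steady_state_tensions(theta_target, plant, f_fix0)

    on, off = burst_window(
        res.spike_train("AN", "ipsi")[res.spike_train("AN", "ipsi") > 60.0],
        max_isi=_BURST_ISI["AN"])
    if not np.isfinite(on):
        raise RuntimeError("no abducens burst found; circuit failed to fire")
    # neuromuscular transmission + excitation-contraction delay between
    # the motoneuron discharge and the muscle seeing the innervation
    delay = float(ctrl.get("motor_delay_ms", 0.0))
    on, off = on + delay, off + delay
    t3 = off + float(ctrl["t3_offset_ms"])

    # innervation from the mapped motoneuron rate during the burst window
    _, n_from_rate, _ = motoneuron_commands(
        res, "ipsi",
        baseline_rate=float(rmap["baseline_rate_hz"]),
        peak_rate=float(rmap["peak_rate_hz"]),
        fixation_tension=f_fix0,
        pulse_magnitude=pulse_mag,
    )
    n_rate = np.interp(t_grid - delay, res.t, n_from_rate)

    n_ag = np.where(t_grid < on, f_fix0,
                    np.where(t_grid < off, n_rate, f_ag_t))
    # the step level is the fixation tension of the target position
    # (tonic rates are the linear image of these tensions)
    n_ant = np.where(t_grid < on, f_fix0,
                     np.where(t_grid < t3, 0.0, f_ant_t))
    params = ControllerParams(
        tau_gac=float(ctrl["tau_gac_ms"]), tau_gde=float(ctrl["tau_gde_ms"]),
        tau_tde=float(ctrl["tau_tde_ms"]), tau_tac=float(ctrl["tau_tac_ms"]),
        t1=float(on), t2=float(off), t3=float(t3),
    )
    info = {"an_burst": [float(on), float(off)], "t3": float(t3),
            "f_ag_target": f_ag_t, "f_ant_target": f_ant_t}
    return n_ag, n_ant, params, info


def run_saccade(
    magnitude: float | None = None,
    cfg: Mapping[str, Any] | None = None,
    scenario: Scenario | None = None,
    out_dir: str | Path | None = None,
    duration: float | None = None,
) -> tuple[RunReport, dict]:
    """Execute one saccade scenario end to end.

    Returns ``(report, arrays)`` where ``arrays`` carries the time series
    (circuit result, tensions, trajectory) for further analysis.
    """
    cfg = cfg or default_config()
    if scenario is None:
        if magnitude is None:
            raise ValueError("give either magnitude or scenario")
        scenario = scenario_from_config(cfg, magnitude)
    sim = cfg["simulation"]
    net = build_network(scenario, cfg)
    t1, t2 = net.drives.t1, net.drives.t2
    if duration is None:
        duration = t2 + float(sim["post_saccade_ms"])
    res = simulate_circuit(net, duration, dt=float(sim["dt_network_ms"]),
                           record_every=int(sim["record_every"]))
    events = _population_events(res, t1, t2)

    plant = plant_from_config(cfg)
    dt_p = float(sim["dt_plant_ms"])
    t_grid = np.arange(0.0, duration + dt_p / 2, dt_p)
    n_ag, n_ant, cp, cmd_info = _commands(res, t_grid, cfg,
                                          scenario.magnitude, plant)
    f_fix_hold = float(cfg["controller"]["fixation_tension_n"])
    if scenario.n_active == 0:
        # no recruited fibers: no innervation change reaches the muscles,
        # the eye holds the primary position
        n_ag = np.full_like(n_ag, f_fix_hold)
        n_ant = np.full_like(n_ant, f_fix_hold)
        cmd_info["f_ag_target"] = f_fix_hold
        cmd_info["f_ant_target"] = f_fix_hold
        cmd_info["hold_fixation"] = True
    f_fix0 = float(cfg["controller"]["fixation_tension_n"])
    f_act = agonist_filter(t_grid, n_ag, cp, f0=f_fix0).f
    f_ant = antagonist_filter(t_grid, n_ant, cp, f0=f_fix0).f
    if cmd_info.get("hold_fixation"):
        f_inact = np.full_like(t_grid, f_fix0)
    else:
        f_inact = inactive_fiber_program(t_grid, cp, f_fix0,
                                         cmd_info["f_ag_target"])

    m = plant.m
    n_act = min(scenario.n_active, m)
    f_ag_fibers = np.empty((t_grid.size, m))
    f_ag_fibers[:, :n_act] = f_act[:, None]
    f_ag_fibers[:, n_act:] = f_inact[:, None]
    f_ant_arr = np.repeat(f_ant[:, None], m, axis=1)

    def forcing(t_ms: float):
        k = min(int(round(t_ms / dt_p)), t_grid.size - 1)
        return f_ag_fibers[k], f_ant_arr[k]

    state0 = initial_state(plant, 0.0, f_fix0, f_fix0)
    t_p, theta, omega = simulate_plant(forcing, plant, duration, dt=dt_p,
                                       state0=state0)
    thr = float(cfg["plant"]["velocity_threshold_deg_s"])
    metrics = saccade_metrics(t_p, theta, omega, velocity_threshold=thr)
    events["saccade_onset"] = metrics.onset_ms
    events["saccade_end"] = metrics.onset_ms + metrics.duration_ms
    events.update(cmd_info)

    trace_files: list[str] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj = pd.DataFrame({"time_ms": t_p, "theta_deg": theta,
                             "theta_dot_deg_s": omega})
        fp = out / f"trajectory_{scenario.magnitude:g}deg.csv"
        traj.to_csv(fp, index=False)
        trace_files.append(str(fp))
        tens = pd.DataFrame({"time_ms": t_grid, "n_ag": n_ag, "n_ant": n_ant,
                             "f_active": f_act, "f_inactive": f_inact,
                             "f_antagonist": f_ant})
        fp = out / f"tensions_{scenario.magnitude:g}deg.csv"
        tens.to_csv(fp, index=False)
        trace_files.append(str(fp))
        rows = []
        for (name, side), s in res.spikes.items():
            rows.extend((name, side, float(x)) for x in s)
        spk = pd.DataFrame(rows, columns=["population", "side", "spike_time_ms"])
        fp = out / f"spikes_{scenario.magnitude:g}deg.csv"
        spk.to_csv(fp, index=False)
        trace_files.append(str(fp))

    report = RunReport(
        scenario={"magnitude_deg": scenario.magnitude,
                  "burst_duration_ms": scenario.burst_duration,
                  "n_active": scenario.n_active},
        metrics=metrics,
        events={k: v for k, v in events.items()},
        config_fingerprint=config_fingerprint(cfg),
        trace_files=trace_files,
    )
    if out_dir is not None:
        (Path(out_dir) / f"summary_{scenario.magnitude:g}deg.json").write_text(
            report.to_json())
    arrays = {"result": res, "t": t_p, "theta": theta, "omega": omega,
              "n_ag": n_ag, "n_ant": n_ant, "f_active": f_act,
              "f_ant": f_ant, "f_inactive": f_inact, "t_grid": t_grid}
    return report, arrays


def choreography(report: RunReport) -> dict[str, float]:
    """Timing of each population event relative to the measured saccade."""
    ev = report.events
    onset = ev["saccade_onset"]
    end = ev["saccade_end"]
    return {
        "LLBN_onset_lead": onset - ev["LLBN_ipsi_burst"][0],
        "OPN_pause_lead": onset - ev["OPN_pause"][0],
        "EBN_onset_lead": onset - ev["EBN_ipsi_burst"][0],
        "IBN_onset_lead": onset - ev["IBN_ipsi_burst"][0],
        "AN_onset_lead": onset - ev["AN_ipsi_burst"][0],
        "EBN_end_lead": end - ev["EBN_ipsi_burst"][1],
        "OPN_resume_offset": ev["OPN_pause"][1] - end,
    }


def main_sequence(
    cfg: Mapping[str, Any] | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run every configured scenario; tabulate the main-sequence metrics."""
    cfg = cfg or default_config()
    rows = []
    errors = []
    for mag in sorted(int(k) for k in cfg["scenarios"]):
        try:
            rep, _ = run_saccade(mag, cfg, out_dir=out_dir)
            rows.append({
                "magnitude_deg": mag,
                "measured_magnitude_deg": rep.metrics.final_position_deg,
                "duration_ms": rep.metrics.duration_ms,
                "peak_velocity_deg_s": rep.metrics.peak_velocity_deg_s,
            })
        except Exception as exc:   # partial table + error list
            errors.append((mag, repr(exc)))
    table = pd.DataFrame(rows)
    if errors:
        table.attrs["errors"] = errors
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "main_sequence.csv", index=False)
    return table


def neuron_demo(
    population: str,
    cfg: Mapping[str, Any] | None = None,
    out_dir: str | Path = "demo",
    magnitude: float = 16.0,
) -> list[str]:
    """Export the three-panel trace data for one population (16 deg run).

    Writes a CSV with the dendritic potential, the axonal potential and
    the synaptic pulse-train current of the requested population.
    """
    cfg = cfg or default_config()
    from .circuit import POPULATIONS
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; "
                         f"one of {POPULATIONS}")
    sim = cfg["simulation"]
    scenario = scenario_from_config(cfg, magnitude)
    net = build_network(scenario, cfg)
    duration = net.drives.t2 + float(sim["post_saccade_ms"])
    res = simulate_circuit(net, duration, dt=float(sim["dt_network_ms"]),
                           record_every=int(sim["record_every"]))
    side = "midline" if population == "OPN" else "ipsi"
    u = net.index(population, side)
    train = res.pulse_train(population, side)
    i_pulse = train.sample(res.t)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "time_ms": res.t,
        "v_dendrite_mv": res.v_dendrite[u],
        "v_axon_mv": res.v_axon[u],
        "i_synapse_ua": i_pulse,
    })
    fp = out / f"demo_{population}_{magnitude:g}deg.csv"
    df.to_csv(fp, index=False)
    spikes = res.spike_train(population, side)
    fs = out / f"demo_{population}_{magnitude:g}deg_spikes.csv"
    pd.DataFrame({"spike_time_ms": spikes}).to_csv(fs, index=False)
    return [str(fp), str(fs)]
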