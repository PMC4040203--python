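# sacgen default configuration: all membrane, timing and mechanical
# parameters of the saccade generator.  Values mirror the published
# parameter tables of the circuit where printed; entries marked
# "calibrated" are package calibrations documented in docs/methods.md.

simulation:
  dt_network_ms: 0.001      # network integration step
  dt_plant_ms: 0.01         # plant / controller grid
  record_every: 25          # trace subsampling (0.05 ms at default dt)
  post_saccade_ms: 220.0    # simulated fixation after the burst ends

timing:
  latent_period_ms: 120.0   # t1: saccades start at 120 ms
  # scripted drive gates, relative to t1 and t2 = t1 + burst_duration
  sc_lead_ms: 20.0          # SC burst onset before saccade (20-25 ms band)
  sc_end_offset_ms: 8.0     # SC off at t2 + offset (~ saccade end)
  fn_lead_ms: 10.0          # contralateral FN onset before saccade
  fn_end_offset_ms: 0.0     # contralateral FN off at t2 + offset
  fn_burst_lead_ms: 0.0     # ipsilateral FN end-burst onset at t2 + lead
  fn_burst_width_ms: 20.0   # ipsilateral FN end-burst duration

# Scripted drive waveforms.  Amplitudes are per postsynaptic target
# (synaptic strength is a property of the receiving membrane): the SC
# burst drives the LLBN hard and the EBN weakly.
drives:
  sc:
    rate_hz: 800.0          # pulse rate of the collicular drive
    pulse_width_ms: 0.5
    amplitude_ua: {LLBN: 34.0, EBN: 2.0}
    ramp_final_fraction: 0.65   # slow linear reduction of the envelope
  fn:
    rate_hz: 500.0
    pulse_width_ms: 0.5
    amplitude_ua: {LLBN: 6.0, EBN: 1.0, IBN: 32.0}
  fn_end:
    rate_hz: 500.0
    pulse_width_ms: 0.5
    amplitude_ua: {LLBN: 4.0, EBN: 1.0, IBN: 28.0}

# Membrane parameter table: dendrite capacitor (uF) / resistor (kOhm),
# axon variant + firing-rate coefficient, synaptic pulse amplitude (uA).
# table_coefficient is the published starting value; rate_coefficient is
# the calibrated value actually simulated (see docs/methods.md).
neurons:
  LLBN:
    dendrite: {c_m: 0.5, r_eq: 3.75}
    axon: {variant: basic, threshold_mv: -45.0, table_coefficient: 18000,
           rate_coefficient: 5000}
    synapse: {pulse_amplitude: 20.0, detection_level: -35.0}
  OPN:
    dendrite: {c_m: 1.0, r_eq: 6.3}
    axon: {variant: modified, threshold_mv: -60.0, table_coefficient: 1800,
           rate_coefficient: 1800}
    synapse: {pulse_amplitude: 45.0, detection_level: -30.0}
  EBN:
    dendrite: {c_m: 0.45, r_eq: 3.1}
    axon: {variant: modified, threshold_mv: -60.0, table_coefficient: 35000,
           rate_coefficient: 24000}
    synapse: {pulse_amplitude: 75.0, detection_level: -20.0}
  IBN:
    dendrite: {c_m: 0.35, r_eq: 4.5}
    axon: {variant: basic, threshold_mv: -45.0, table_coefficient: 15000,
           rate_coefficient: 5000}
    synapse: {pulse_amplitude: 65.0, detection_level: -35.0}
  AN:
    dendrite: {c_m: 0.35, r_eq: 5.5}
    axon: {variant: basic, threshold_mv: -45.0, table_coefficient: 17000,
           rate_coefficient: 5000}
    synapse: {pulse_amplitude: 55.0, detection_level: -20.0}
  "ON":   # quoted: bare ON is a YAML 1.1 boolean
    dendrite: {c_m: 0.45, r_eq: 4.0}
    axon: {variant: basic, threshold_mv: -45.0, table_coefficient: 17000,
           rate_coefficient: 3000}
    synapse: {pulse_amplitude: 55.0, detection_level: -20.0}
  TN:
    dendrite: {c_m: 0.35, r_eq: 4.5}
    synapse: {pulse_amplitude: 10.0}
    fhn: {a: 0.7, b: 0.8, eps: 0.08, speed: 4.0, input_gain: 0.05,
          integral_gain: 0.0002, i_rest: 0.45}
  IN:
    dendrite: {c_m: 0.4, r_eq: 4.5}
    synapse: {pulse_amplitude: 10.0}
    fhn: {a: 0.7, b: 0.8, eps: 0.08, speed: 4.0, input_gain: 0.05,
          integral_gain: 0.0002, i_rest: 0.45}

dendrite_common:
  n_compartments: 14
  r_a_ohm: 100.0
  v_th_mv: -60.0

synapse_common:
  detection_level_mv: 0.0
  axonal_delay_ms: 1.0

# per-connection overrides (synapse parameters live on connections):
# transmission delays (ms) and pulse detection levels (mV).  The deep
# OPN levels widen each inhibitory pulse so the pause neuron's tonic
# barrage clamps the autonomous burst neurons without gaps.
connection_delays:
  LLBN->OPN: 1.0
connection_detection_levels:
  OPN->EBN: -50.0
  OPN->IBN: -50.0

# Saccade scenarios: magnitude (deg) -> agonist burst duration (ms) and
# number of active agonist neurons (of 100 fibers).
scenarios:
  4:  {burst_duration_ms: 40.0, n_active: 48}
  8:  {burst_duration_ms: 42.0, n_active: 76}
  12: {burst_duration_ms: 52.0, n_active: 75}
  16: {burst_duration_ms: 56.0, n_active: 100}
  20: {burst_duration_ms: 65.0, n_active: 92}

controller:
  tau_gac_ms: 11.0       # agonist activation (calibrated defaults, see docs)
  tau_gde_ms: 6.0       # agonist deactivation (slide)
  tau_tde_ms: 5.0       # antagonist deactivation (pause)
  tau_tac_ms: 5.0       # antagonist re-activation
  t3_offset_ms: 0.0     # antagonist step at the burst end (brake)
  motor_delay_ms: 3.5   # neuromuscular + excitation-contraction delay
  pulse_magnitude_n: 0.8   # saturated agonist pulse, whole-muscle units (N)
  fixation_tension_n: 0.4   # F_ag = F_ant at primary position (N)

# EBN peak-rate measurement protocol: sustained suprathreshold
# excitatory pulse train into the dendrite (calibration for the 1 kHz
# peak-rate gate; same coefficient drives the circuit EBN)
calibration:
  ebn_drive_amplitude_ua: 16.0
  ebn_drive_rate_hz: 800.0
  ebn_drive_width_ms: 0.5

rate_map:
  # affine innervation map anchors: tonic rate at primary position and
  # the nominal motoneuron plateau rate mapping to the pulse magnitude
  baseline_rate_hz: 100.0
  peak_rate_hz: 700.0

plant:
  # whole-muscle estimates (single-tendon-equivalent); scaled to the
  # element level by the series/parallel rules before simulation
  k_se: 125.0          # N/m
  b_2: 0.5             # N·s/m
  k_lt: 60.7           # N/m
  b_1: 1.0             # N·s/m
  j_p: 0.03            # N·s²/m (see docs/methods.md)
  b_p: 3.0             # N·s/m (see docs/methods.md)
  k_p: 16.34           # N/m
  r_m: 0.010           # eyeball radius, m
  n_columns: 1
  m_fibers: 100
  initial_stretch_m: 3.705e-3
  velocity_threshold_deg_s: 10.0   # saccade onset/offset convention
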