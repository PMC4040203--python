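# sacgen — a physiological saccade generator for horizontal monkey saccades

Saccades are the rapid conjugate eye movements that redirect gaze.  In
the primate brainstem they are produced by a small, well-characterised
circuit: long-lead burst neurons (LLBN) driven by the superior
colliculus inhibit the omnipause neuron (OPN), whose pause releases the
excitatory and inhibitory burst neurons (EBN, IBN); the EBN drives the
abducens motoneurons (AN) at up to ~1 kHz, tonic neurons and
interneurons (TN, IN) integrate the burst into a position-holding step,
and the oculomotor nucleus (ON) carries the antagonist command.  This
package simulates that whole pathway as executable physiology:

* **eight biophysical neuron populations** — a 14-compartment passive
  dendrite chain feeding a Hodgkin–Huxley spike generator (with a
  modified α_M variant whose threshold sits at the resting potential,
  making the EBN and OPN fire autonomously when released from
  inhibition) or a FitzHugh–Nagumo tonic integrator, coupled through
  delayed rectangular pulse-train synapses;
* **a first-order time-optimal controller** — the agonist pulse-slide-step
  and antagonist pause-step innervations, low-pass filtered into
  active-state tensions `dF/dt = (N − F)/τ(t)` with phase-switched time
  constants;
* **a muscle-fiber oculomotor plant** — two antagonist muscles of 100
  series viscoelastic fibers plus tendons acting on the eyeball,
  `T_ag − T_ant = J_p r θ̈ + B_p r θ̇ + K_p r θ`, with the per-column
  tension eliminated algebraically from the series constraint.

Under the time-optimal strategy the motoneuron firing rate does **not**
encode saccade magnitude: the burst duration and the number of active
agonist neurons do.  The five standard scenarios are

| magnitude | burst duration | active neurons |
|----------:|---------------:|---------------:|
|        4° |          40 ms |             48 |
|        8° |          42 ms |             76 |
|       12° |          52 ms |             75 |
|       16° |          56 ms |            100 |
|       20° |          65 ms |             92 |

## Worked example

```python
from sacgen.runner import run_saccade, choreography

report, arrays = run_saccade(16)      # the 16-degree scenario
print(report.metrics)
print(choreography(report))
```

prints (default configuration):

```
SaccadeMetrics(onset_ms=124.7, duration_ms=81.5, magnitude_deg=17.0,
               peak_velocity_deg_s=347.1, final_position_deg=16.0)
{'LLBN_onset_lead': 21.4, 'OPN_pause_lead': 17.1, 'EBN_onset_lead': 8.1,
 'IBN_onset_lead': 9.0, 'AN_onset_lead': 5.5, 'EBN_end_lead': 21.7,
 'OPN_resume_offset': -12.0}
```

The eye starts moving ≈6 ms after the latent period ends, peaks near
350°/s and settles at 16.0°; the LLBN begins bursting ≈21 ms before the
movement, the burst neurons ≈8 ms before, the motoneurons ≈5.5 ms
before — the staggered onsets emerge from each population's dendritic
time constant, not from scripted per-neuron delays.  The same circuit
run also exposes every membrane trace, spike train and synaptic pulse
train (`arrays["result"]`).

From the shell:

```bash
sacgen simulate --scenario 16 --out out/          # traces + summary JSON
sacgen main-sequence --out out/                   # all five scenarios
sacgen neuron-demo --population EBN --out demo/   # dendrite/axon/synapse panels
```

All parameters (membrane table, drive gates, controller time constants,
plant mechanics) live in a single YAML configuration shipped with the
package; pass `--config my.yaml` to override any subset.  Runs are
deterministic: identical configuration gives bit-identical spike trains,
and every report carries a configuration fingerprint.

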