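# Methods

`sacgen` simulates conjugate horizontal monkey saccades of 4°–20° with a
three-stage forward model: a spiking midbrain circuit generates the
motoneuron discharge, a first-order time-optimal controller converts
innervation into muscle active-state tension, and a linear homeomorphic
muscle-fiber plant rotates the eyeball.  This note records the model
equations as implemented, the parameters that matter, the calibrations
the package performs, and the known limitations.

## Neuron model

Each of the eight populations (LLBN, OPN, EBN, IBN, TN, IN, AN, ON) is a
three-part unit: a passive dendrite chain, a spike generator, and a
pulse-train synapse.

**Dendrite.** Fourteen identical passive RC compartments (membrane
capacitance `C_m`, resistance `R_EQ`, Thevenin rest `V_TH` = −60 mV)
coupled through a 100 Ω axial resistance.  Presynaptic current enters
compartment 1; the axon hillock reads the last compartment through the
axial resistance, one-way (`I_m = (v_n − V_TH)/R_a`).  Because the axial
resistance is small against the membrane resistance, the chain behaves
as a strongly coupled low-pass: each neuron's `C_m·R_EQ` product sets
its onset delay in the circuit choreography, which is how the scripted
gate times translate into the staggered burst onsets.  Integration is
fixed-step RK4; the chain is linear and non-stiff, and the simulated DC
steady state matches the direct resistive-ladder solve to <0.1%.

**Spike generator.** Burst populations use the squid-axon
conductance model in the 1952 sign convention (`V = V_rp − V_m`, rest
−60 mV, E_Na = +55 mV, E_K = −72 mV, E_l = −49.4 mV, leak 1/3.33 kΩ,
ḡ_K = 36 mS, ḡ_Na = 120 mS).  Two variants exist:

* *basic* (LLBN, IBN, AN, ON): textbook rates; firing threshold ≈ −45 mV.
* *modified* (EBN, OPN): the α_M activation rate is shifted by +15 mV
  (its `(V+25)` argument becomes `(V+10)`), which moves the threshold to
  the resting potential.  These neurons fire autonomously the moment
  inhibition is withdrawn — the property that lets the omnipause gate
  control saccade initiation.

The three gating equations are multiplied by a per-population **rate
coefficient** expressed on a per-second base: a coefficient of 1000
reproduces textbook kinetics, larger values speed the gates up
proportionally and raise the attainable firing rate.  Two dynamical
ceilings shape what coefficients are usable:

* the *basic* variant loses repetitive firing above ≈5× textbook speed —
  the class-2 oscillation window closes once the gates become
  quasi-static relative to the membrane — so LLBN/IBN/AN/ON run at
  calibrated coefficients near 5000 (ON at 3000; its drive ramps slowly
  and the faster setting accommodates) and burst at 250–400 Hz rather
  than the 600–1000 Hz of the physiological recordings;
* the *modified* variant keeps firing to ≈28× but blocks beyond, so the
  EBN runs at 24 000 (tabulated starting value 35 000), where the
  standard drive protocol yields a 993 Hz peak rate — within the
  1,000 Hz ± 10% gate.  The OPN runs at its tabulated 1800 and fires
  tonically at ≈175 Hz.

**Threshold measurement.**  The firing threshold is bracketed by
bisection over 1-ms current-pulse amplitudes and read off the minimal
suprathreshold trajectory as the membrane potential at spike takeoff
(first point where dV/dt exceeds 10 mV/ms), the standard
electrophysiological criterion.  "Maximum subthreshold potential" is not
a usable read-out for this model: it creeps without bound as the
bisection bracket tightens, because the system has no true saddle and
the boundary trajectory ultimately fires.  The takeoff read-out is
stable in step size and criterion (5–20 mV/ms) and gives −44.6 mV
(basic) and −60.0 mV (modified, which fires from rest).

**Tonic units.**  TN and IN are FitzHugh–Nagumo relaxation oscillators
(a = 0.7, b = 0.8, ε = 0.08, time scale 4 /ms) on top of a leak-free
integrator: the running integral of the dendritic current shifts the
oscillator's operating current (integral gain 2 × 10⁻⁴ per µA·ms), so a
burst input permanently raises the tonic rate, while the instantaneous
current (gain 0.05/µA) lets an inhibitory barrage silence spiking
without erasing the stored level.  The original tonic-bursting
parameterisation of this cell class is not reproduced here; the standard
oscillator fulfils the circuit-level contract (integrate bursts, resume
position-holding tonic firing within 5 ms of inhibition offset).

**Synapse.**  A voltage-to-frequency converter: each action potential
produces one rectangular current pulse whose width is the time the
axonal potential spends above a detection level, delayed by the axonal
transmission time (1 ms default) and scaled by the per-neuron amplitude
(20–75 µA).  Excitatory/inhibitory sign belongs to the connection.
Detection levels are calibrated per neuron (−20 to −35 mV) and, where a
connection needs it, per connection: the OPN→EBN and OPN→IBN synapses
use a deep −50 mV level so the ≈175 Hz pause-neuron discharge produces
≈4-ms-wide pulses that clamp the autonomous burst neurons without
inter-pulse gaps.  With narrow pulses the fast EBN escapes one spike per
OPN cycle — a phase-locked leak that violates pause-burst mutual
exclusion — so the wide-pulse clamp is a structural requirement of
pulse-train inhibition, not a tuning nicety.

## Circuit and scripted drives

Fifteen units (a midline OPN, all others once per side) are wired per
the two-sided network: SC→LLBN/EBN excitation, LLBN→OPN inhibition and
LLBN→IBN excitation, OPN→EBN/IBN inhibition bilaterally, IBN inhibition
of the contralateral EBN/TN/AN and ipsilateral ON/IN, EBN→TN/AN
excitation, TN→IN→AN, and AN→contralateral ON.  The IBN→IN connection is
implemented same-side (the alternative contralateral reading of the
firing sequence is a config switch away via the wiring table).

The superior colliculus and fastigial nucleus are scripted waveform
generators, not spiking models.  The SC burst is an 800 Hz pulse train
whose envelope ramps linearly to 65% over the gate window
(t₁ − 20 ms → t₂ + 8 ms, where t₁ = 120 ms is the end of the latent
period and t₂ = t₁ + burst duration); the contralateral FN drive is a
500 Hz train over t₁ − 10 → t₂; the ipsilateral FN end-burst
(t₂ → t₂ + 20 ms) raises the contralateral IBN, which chokes the
ipsilateral EBN before the OPN resumes.  Drive amplitudes are per
postsynaptic target (synaptic strength is a property of the receiving
membrane): the SC drives the LLBN at 34 µA and the EBN weakly at 2 µA.

The network integrates at dt = 1 µs-scale steps (1 × 10⁻³ ms) with RK4;
at the EBN's 24× gating speed the fastest deactivation rates during deep
hyperpolarisation approach the RK4 stability limit at 2 × 10⁻³ ms, so
the smaller step is the default.  The simulation is fully deterministic:
identical configuration gives bit-identical spike trains.

## Controller

Motoneuron innervation N(t), in whole-muscle tension units, is low-pass
filtered into active-state tension with a phase-switched time constant:
agonist activation τ_gac = 11 ms during the pulse, deactivation
τ_gde = 6 ms during the slide (from t₂); antagonist deactivation
τ_tde = 5 ms during the pause, re-activation τ_tac = 5 ms from t₃ (the
burst end).  The filter uses the exact per-sample exponential update, so
the piecewise closed forms hold to machine precision.  These time
constants are package calibrations in the range reported by
system-identification studies of the primate saccadic plant; the source
circuit description does not print its values.

The agonist command is a pulse-slide-step: the pulse window and plateau
come from the simulated abducens burst (the plateau rate maps affinely
to the saturated pulse magnitude of 0.8 N), shifted by a 3.5 ms
neuromuscular/excitation-contraction delay; the step is the fixation
tension of the target position from the plant-equilibrium map
(F_ag/F_ant = 0.4 ± k·θ N with k fixed by the static force balance, here
0.0127 N/deg) — fixation tensions are functions of eye position at
steady state, and the tonic firing rates are their linear image.  The
antagonist command is a pause-step.  `n_active` of the 100 agonist
fibers receive the motoneuron command; the rest follow the
inactive-fiber program (exponential decay with τ_gac during the pulse,
recovery with τ_gde during the slide, settling at the new fixation
tension).  With no recruited fibers there is no innervation change and
the eye holds fixation.

## Plant

Each muscle is one column (n = 1) of m = 100 identical fibers in series
between two tendon elements; a tendon is a spring K_se with dashpot B_2,
a fiber a spring K_lt, dashpot B_1 and active-tension generator.
Element stretch rates are affine in the unknown column tension, so the
series constraint (stretch rates sum to the muscle end velocity,
±r·dθ/dt) eliminates the tension algebraically each step.  Element
values come from whole-muscle estimates by the series/parallel rules
(k_elem = series-count × k_whole / n, same for viscosities), which
preserves the aggregate stiffness exactly; the 100-fiber chain and its
single-element reduction agree to well below 1% trajectory RMS.  Both
muscles carry a 3.705 mm pre-stretch at the primary position.

Whole-muscle defaults: K_se = 125 N/m, K_lt = 60.7 N/m (literature
estimates), B_1 = 1.0 N·s/m, B_2 = 0.5 N·s/m, K_p = 16.34 N/m, and
eyeball terms J_p = 0.03 N·s²/m, B_p = 3.0 N·s/m (r = 10 mm).  The last
three are calibrated so the fixed-height agonist pulse and the tabulated
(burst duration, fiber count) pairs land each scenario near its
magnitude without large overshoot while still settling well inside the
200 ms measurement window.  Saccade onset/offset use the 10°/s velocity
convention, with offset taken at the first drop below threshold after
the velocity peak (a post-saccadic glissade does not extend the
duration).

## Problem sizes and determinism

The standard end-to-end run simulates ≈340–390 ms of network time at
10⁻³ ms steps (15 units × ≈370 000 steps) plus the plant at 10⁻² ms
steps (206 mechanical states), ≈12 s per scenario on one core.  The
single-neuron gates (peak rate, thresholds) run in seconds.  There is no
randomness anywhere in the default pipeline.

## What the scripted drives do and do not emulate

The SC/FN waveforms reproduce the gate *timing* and drive levels of the
physiological inputs, not their spiking statistics, retinotopy or
closed-loop cerebellar feedback: saccade termination is scripted (gate
times derived from the burst duration), not computed from displacement
feedback.  Passing choreography tests therefore validate the brainstem
circuit's response to correctly-timed inputs, not the generation of
those timings.

## Known limitations

* **Burst-rate ceiling.**  The basic-variant populations cannot reach
  the recorded 600–1000 Hz peak rates (class-2 window closes at the
  required gating speeds, and the 14-compartment dendrite removes the
  input ripple that 1:1 entrainment would need).  Relative properties —
  motoneuron plateau invariance across scenarios (<1% here), burst
  ordering, gating — are unaffected.
* **Pause-lead residual.**  The OPN pause begins ≈17 ms before the
  measured saccade onset (physiological band 6–10 ms): the pause must
  precede movement by the whole internal chain (EBN release through the
  hyperpolarised dendrite ≈8 ms, EBN→AN ≈1.5 ms, neuromuscular delay
  plus velocity-threshold rise ≈6 ms), and shortening any link
  destabilises the fixation hold.
* **Burst-end lead.**  The EBN burst ends ≈10 ms before saccade end only
  for the smallest saccade; for larger ones the linear plant's approach
  tail keeps the eye above the 10°/s offset threshold for tens of
  milliseconds after the burst, stretching the measured lead.
* **Peak-velocity ordering.**  With the magnitude-independent pulse
  height the time-optimal scheme requires, peak velocity tracks the
  active-fiber fraction, and the scenario table assigns the 20° saccade
  fewer active fibers (92) than the 16° one (100): the simulated peak
  velocity at 20° is ≈7% below 16°, and at 12° marginally (≈1%) below
  8°.  Raising velocity late into the burst enough to reverse this needs
  an effective build-up time constant ≥65 ms, which forces either
  underdamped ringing or settling too slow for the ±0.5° accuracy gate.
  Duration remains monotone in magnitude.  The corresponding acceptance
  property is left failing rather than tuned away.
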