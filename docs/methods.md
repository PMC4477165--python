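# Methods

This note documents the models, numerical choices and declared fixture
parameters behind `clamploop`, and what the simulated-preparation tests do
and do not establish about behaviour on real cells.

## Execution model

The engine executes a named block graph at a fixed step (default
dt = 5·10⁻⁵ s, i.e. 20 kHz; acquisition systems for these protocols commonly
run at 15–50 kHz).  Within a step, blocks fire in a topological order
computed over the non-feedback wires; any closed loop must contain a wire
explicitly declared *feedback*, which behaves as a unit-delay register with a
stated initial value.  This mirrors the sample-and-hold semantics of a
digital rig — the current computed from sample *n* is applied at sample
*n*+1 — and deliberately rules out algebraic-loop solving: an undeclared
cycle is a configuration error, not something to be patched silently.

Model time is derived as t = n·dt, never accumulated.  One root seed is
supplied per run; each stochastic block draws from an independent child
stream keyed by a hash of its block name, so adding or renaming unrelated
blocks never perturbs the noise seen by the rest of the graph, and identical
(configuration, seed) pairs give bit-identical logs.  Any non-finite block
output aborts the run naming the block and step index — this is also the
*instability detector* exercised by the AEC hazard test below.

Units are SI throughout the engine (V, A, S, s, Hz).  Configuration files
may write `10 nS`, `-70 mV`, `250 pA`; conversion happens once, at the
config boundary, to keep silent 10³ errors out of the wiring.

## Simulated preparations

The neuron models are the canonical published forms; none of the protocol
logic depends on which one is patched in.

- **LIF / QIF / aEIF.**  The adaptive exponential model is the default
  preparation ("l5_aeif"), calibrated L5-pyramidal-like: C = 200 pF,
  g_L = 10 nS (τ_m = 20 ms), E_L = −70 mV, V_T = −50 mV, Δ_T = 2 mV,
  V_reset = −58 mV, t_ref = 2 ms, a = 2 nS, b = 40 pA, τ_w = 144 ms.  The
  10 nS resting conductance makes the conventional rule "unitary background
  conductances at 2% and 6% of resting input conductance" concrete:
  g_e = 0.2 nS, g_i = 0.6 nS.  Spikes are registered at the numerical
  cut-off V_T + 5Δ_T.
- **HH / reduced Traub–Miles.**  Squid-parameter Hodgkin–Huxley and the
  reduced Traub–Miles model, both scaled to a 2·10⁻⁴ cm² patch.  These
  models' resting potential is emergent (HH rests at −65 mV although its
  leak reversal is −54.4 mV), so initialisation solves the steady-state
  current balance for the most hyperpolarised zero and starts the gates at
  equilibrium.  Spike detection: upward crossing of 0 mV with 2 ms lockout.
- **Tsodyks–Markram synapse.**  Resource/utilisation dynamics with
  exponential PSC decay; τ_facil = 0 pins utilisation at U (pure
  depression).
- **Electrode.**  A series R_s with parallel C_e; the recorded potential is
  V_m plus the drop across this RC driven by the pipette current.

Integration is explicit Euler at the engine dt for all membrane and gating
dynamics.  Two linear subsystems deviate: the electrode ODE and the TM
inter-spike decays use the exact exponential update for piecewise-constant
input.  The electrode time constant (R_s·C_e ≈ 10 µs for 10 MΩ/1 pF) can be
*shorter* than the engine step, where Euler is unstable; and the TM
fixed-point tests compare against the closed-form event map, which the exact
update reproduces independent of dt.  Both updates are exact, so nothing is
traded away.

## Background synthesis and the balance rule

Synaptic barrages are replaced by the diffusion approximation: each channel
is an OU process with mean ḡ·τ·R and variance g²τR/2, the standard
point-conductance result (dimensionally consistent; the long-run OU tests
verify the implementation against exactly these moments).
Negative conductance excursions are preserved inside the process and clipped
to zero only at the injection point, the common dynamic-clamp convention.

Time-varying rates map to time-varying per-step target moments
(Ḡ(t), G_S(t), D(t)) while the SDE relaxes with the fixed channel τ — so a
rate modulation at frequency ω reaches the conductance attenuated by
1/√(1+(ωτ)²).  The "no synaptic filtering" demonstrator variant instead adds
the mean modulation ḡτ(R(t) − R₀) directly to the stationary process,
bypassing that low-pass; a test verifies both depths against the analytic
factor.  A phase offset parameter (default 0) is provided for the
modulation.

Balanced inhibition solves 0 = Ḡ_e(E_e − V_b) + Ḡ_i(E_i − V_b) for R_i.
The balance potential defaults to V_b = −51.85 mV, 1–2 mV below the −50 mV
threshold of the default preparation; with the canonical 1× excitatory rate
R_e = 7000 Hz this yields R_i = 2149 Hz.  The background scale conditions
are 0×/1×/2×/3× ≡ R_e ∈ {0, 7000, 14000, 21000} Hz with R_i re-balanced at
each scale.

## Active electrode compensation

Kernel identification injects an i.i.d. uniform current (default ±100 pA,
10 s — the probe amplitude/duration and the 15 ms kernel length are package
defaults, config-overridable, as no experimental values are prescribed) and
solves the ridge-regularisable least-squares problem
V(n) ≈ c + Σ_k K(k) I(n−k) with an explicit intercept, accumulating the
normal equations in blocks so probe length is memory-unbounded.  The
membrane component is a single exponential fitted to the kernel tail beyond
`membrane_tail_start` (default 1 ms); the electrode kernel is then recovered
by the Fourier-domain correction K_e(f) = K(f) / (1 + K_m(f)/R_e), iterating
R_e = ΣK_e from the plain-subtraction initialiser.  This correction accounts
for the membrane's filtering of electrode-passed current and is exact at DC
for a resistive electrode in series.

On simulated circuits (R_s = 10 MΩ, C_e = 1 pF, R_m = 100 MΩ,
τ_m = 20 ms) the recovered R_s, R_m and τ_m are each within 5%; closed-loop
conductance injection through a 20 MΩ simulated pipette with the estimated
kernel tracks the true membrane potential to < 0.5 mV RMS.  Deliberately
doubling the kernel turns the per-sample subtraction into positive feedback;
with 3× background the loop gain exceeds one and the engine's non-finite
detector fires — the hazard that makes compensation quality a safety
property, not a nicety.

## Controllers

Two discretisation conventions coexist on purpose.  Event-triggered
controllers (firing-rate clamp, stimulus-intensity control) treat each spike
or stimulus as one iteration: errors accumulate with **no dt factor** and
outputs hold between events.  The voltage hold runs every engine step and
integrates its error over time (P = 10, I = 100 on volts, scaled to nA).

- **Rate estimator.**  "Weighted average of history and 1/ISI" is realised
  with exponential-in-ISI weighting (the same algebra as the probability
  estimator), default τ_r = 1 s.
- **Firing-rate clamp.**  Spike-triggered PID (default P = 0.0045,
  I = 0.0023, D = 0; rate error in Hz, output in nA) around a constant bias
  current, default 0.2 nA — just below rheobase under the 1× balanced
  background.  The bias plays the role of the experimenter's initial holding
  current: a spike-triggered controller on a quiescent cell would otherwise
  never receive its first update.  It is the exact analogue of the S₁
  offset in the stimulus-intensity law.
- **Probability / amplitude estimator.**  p₀ initialises at the target
  (fast lock-in; p₀ = 0 available).  "Responded" means ≥ 1 spike detected
  in the triggered window 10 ms before to 500 ms after the stimulus.  The
  amplitude variant is the same update, unbounded, carrying volts.
- **Stimulus-intensity PI.**  S is dimensionless (device units), mapped to
  a charge-balanced biphasic pulse (200 µs per phase, positive first) by a
  configurable scale.  For the EPSP clamp the error is expressed in mV
  (device-style units) so the default gain G = 1600 acts on numbers of
  order 0.1; the probability clamp's error is already dimensionless.
  Response-clamp defaults: P = 1, I = 0.3, G = 700, τ = 600 s; EPSP clamp:
  G = 1600, τ = 300 s (both sliding-average timescales are exposed, since
  the two protocols default differently).
- **PSP measurement.**  Peak-minus-baseline within a search window
  (default: 10 ms baseline, 100 ms search), signed by polarity.

## Drifting-excitability fixtures

The extracellular-stimulation protocols run against *declared synthetic*
stand-ins, not biological claims; their parameters live in the fixture
manifests.

- **Antidromic case**: spike probability is a sigmoid in stimulus intensity,
  centre θ = 300 device units, width 30; θ performs an OU walk with
  τ = 120 s and stationary sd of 10% of the 6·width dynamic range.
- **Synaptic case**: intensity recruits presynaptic drive through
  1 − e^(−S/300), feeding the TM synapse whose efficacy is scaled by an OU
  factor (mean 1, sd 15%, τ = 120 s); the passive membrane turns the PSC
  into a PSP whose fully recruited nominal peak is 1 mV.

The scales were fixed by linearising the closed loop: with the default gains
the discrete poles are complex with modulus ≈ 0.98 — stable, lightly damped,
locking in within tens of stimuli, which is the regime the protocols are
meant to demonstrate.  Runs are event-resolved: drift advances per stimulus
with the exact OU transition, and each stimulus produces a short simulated
recording window (5101 samples at 0.1 ms for spike detection; an Euler
membrane+synapse simulation at 0.2 ms for the PSP), so the spike detector,
segment logger and amplitude measurement operate on actual traces.
Replaying a recorded stimulus sequence against a fresh drift realisation
(paired seeds) leaves the probability estimate unregulated; its variance
exceeds the closed-loop value, the signature property of closed-loop
operation.

What these fixtures do **not** emulate: multi-timescale excitability
kinetics, stimulation-history dependence, failure correlations, electrode
drift, or any biophysical mechanism of the drift — passing tests show the
controllers and estimators behave as specified around a drifting plant, not
that a particular neuron will.

## Analysis

Cycle histograms fold spike times modulo the stimulus period into 32 bins
(default), counting only whole cycles so the total is an exact integer
invariant; rates are per-cycle-normalised.  The sinusoid fit
r(t) = r0 + r1·sin(ωt + φ) is linear least squares on a sin/cos basis, with
r1 ≥ 0 and φ in (−π, π]; a flat histogram reports r1 = 0, φ = 0 with a
degeneracy flag.  F–I curves discard a 0.5 s onset transient and fit the
suprathreshold slope by least squares.  Parameter-recovery tests use 10⁴
cycles of an inhomogeneous Poisson process at 1 Hz modulation: at 100 Hz the
same cycle count spans only 100 s of a 10 Hz process and the Cramér–Rao
bound on r1 (≈15%) would exceed the 5% check, whereas 10⁴ s of data puts 5%
at ≈3σ.

## Problem sizes and determinism

The shipped validation runs use: 60 s at 20 kHz for the firing-rate clamp
(mean over the final 20 s against the 17 Hz setpoint); 300 stimuli at ISI
4 s, first 50 discarded, for both event-level clamps; 100 s OU runs for the
moment checks; 10 s probes for kernel identification; 4 background scales ×
5 current levels × 4 s for the gain-modulation experiment; 20 paired seeds
for the open-/closed-loop variance comparison.  All are reproducible from
(config, seed).

## Known limitations

No real-time scheduling, hardware I/O or host/target split — this is the
desk-scale counterpart of a rig, not a driver stack.  Point neurons only
(no morphology, channel noise or temperature dependence).  Synaptic
background is the diffusion approximation, never event-by-event Poisson
trains.  One modulation frequency per run (transfer-function sweeps are a
script on top).  The voltage-hold gating and triggered logging are
implemented, but combined multi-controller protocols beyond the registered
demonstrators are left to user-assembled graphs.
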