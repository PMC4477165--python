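# clamploop

Closed-loop cellular-electrophysiology protocols — dynamic clamp, active
electrode compensation (AEC), firing-rate clamp, evoked-response-probability
clamp and EPSP-size clamp — executed against **simulated preparations**
(model neurons, synapses and pipette electrodes) by a deterministic
fixed-step block engine.

Real-time rigs for these experiments wire together small processing blocks:
conductance generators, spike detectors, sample-and-hold controllers, the
DAQ, the cell.  `clamploop` reproduces that composition in software, with the
patched cell replaced by an integrate-and-fire or Hodgkin–Huxley model behind
a simulated RC pipette.  Every protocol that would run against an amplifier
can therefore be assembled, executed and *debugged* on a desk: the ground
truth for the membrane potential, the electrode artifact and the hidden
excitability drift is always available.  The package is aimed at cellular
electrophysiologists prototyping closed-loop protocols and at method
developers who need a reproducible software testbed for controller gains,
compensation quality or estimator behaviour before touching a slice.

## The models in brief

**Dynamic clamp.**  A virtual synaptic bombardment is injected as current
recomputed each sample from the measured potential,

$$I_{syn}(t) = G_e(t)\,(E_e - V(t)) + G_i(t)\,(E_i - V(t)),$$

with reversals $E_e = 0$ mV, $E_i = -80$ mV.  The background conductances
$G_{e,i}$ are Ornstein–Uhlenbeck processes (the point-conductance diffusion
approximation of Poisson synaptic barrages),

$$\frac{dG_x}{dt} = \frac{\bar G_x - G_x}{\tau_x} + \sqrt{2 D_x}\,\xi_x(t),
\qquad \bar G_x = g_x \tau_x R_x,\quad
G_{Sx}^2 = \tfrac12 g_x^2 \tau_x R_x,$$

where $g_x$ is the unitary conductance, $\tau_x$ the synaptic correlation
time and $R_x$ the virtual presynaptic rate.  Inhibition can be *balanced*,
solving $0 = \bar G_e (E_e - V_b) + \bar G_i (E_i - V_b)$ for $R_i$ at a
potential $V_b$ just below threshold.

**AEC.**  Single-electrode current injection corrupts the recording with the
pipette's voltage drop.  The electrode kernel $K_e$ (lag-indexed impulse
response) is identified by least squares from the response to a uniform
white-noise probe current, separated from the membrane's exponential
component by a tail fit plus a Fourier-domain correction, and the artifact
$K_e * I$ is subtracted online, sample by sample.

**Event-triggered controllers.**  The firing-rate clamp estimates the rate at
each spike, $r \leftarrow r e^{-\mathrm{isi}/\tau_r} +
\frac{1}{\mathrm{isi}}(1 - e^{-\mathrm{isi}/\tau_r})$, and updates an
external current through a sample-and-hold PID on the rate error.  The
response clamp keeps a sliding estimate of the evoked-spike probability,

$$p_n = p_{n-1}\,e^{-ISI/\tau} + F\,(1 - e^{-ISI/\tau}),$$

($F = 1$ on a response, else 0) and regulates the extracellular stimulus
intensity with a PI law $S_{n+1} = S_1 + G\,(P\,EP_n + I\,EI_n)$,
$EP_n = p_{target} - p_n$, $EI_n = EI_{n-1} + EP_n$.  The EPSP-size clamp is
the same law with $F$ replaced by the measured PSP peak amplitude.

## Worked example

Clamp the firing rate of the default L5-like aEIF preparation (10 nS resting
conductance, −70 mV rest, −50 mV threshold) to 17 Hz while it receives 1×
balanced OU background conductances:

```
$ clamploop run examples/firing_rate_clamp.yaml
{
  "R_e": 7000.0,
  "R_i": 2148.9046773238597,
  "target": 17.0,
  "n_spikes": 1034,
  "mean_rate_final": 17.0,
  "mean_I_ext_final": 3.788927600073349e-10
}
```

The excitatory rate is the 1× condition (7000 Hz); the inhibitory rate is
balanced at −51.85 mV, giving 2149 Hz.  Over the 60 s run the controller
fires the neuron 1034 times; the mean rate over the final 20 s sits exactly
on the 17 Hz setpoint, held by an adapted external current of ≈0.38 nA.

The plain conductance-clamp protocol shows the recreated high-conductance
state:

```
$ clamploop run examples/conductance_clamp.yaml
{ "mean_V": -0.051, "sd_V": 0.0026, "rate": 6.9, "isi_cv": 0.647, ... }
```

a steady depolarisation from −70 mV to ≈−51 mV with millivolt-scale
fluctuations and irregular firing (ISI CV ≈ 0.65).

From Python the same run is three lines:

```python
from clamploop import ProtocolConfig, run_protocol
res = run_protocol(ProtocolConfig(protocol="firing_rate_clamp",
                                  duration=60.0, dt=5e-5, seed=1))
print(res.summary["mean_rate_final"])   # 17.0
```

Other registered protocols: `arbitrary_stream_and_record`,
`sine_modulated_background` (with/without synaptic filtering of the
modulation), `voltage_hold`, `response_probability_clamp`,
`epsp_size_clamp`, plus `clamploop replay` for open-loop replay of a
recorded stimulus sequence and `clamploop fixture` for ground-truth test
fixtures.  See `docs/methods.md` for the model details, parameter defaults
and known limitations.

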