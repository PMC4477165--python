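# Spike-triggered PID firing-rate clamp on the default L5-like aEIF
# preparation under 1x OU background conductances.
protocol: firing_rate_clamp
preparation: l5_aeif
duration: 60.0
dt: 5e-5
seed: 1
params:
  target: 17.0      # Hz
  P: 0.0045         # nA/Hz, per spike event
  I: 0.0023
  D: 0.0
  background: 1x    # R_e = 7000 Hz, R_i balanced (2149 Hz)
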