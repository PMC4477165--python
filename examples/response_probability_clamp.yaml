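# Closed-loop control of the evoked-spike probability on the synthetic
# drifting-excitability preparation (300 stimuli, ISI 4 s).
protocol: response_probability_clamp
seed: 5
params:
  p_target: 0.5
  G: 700.0
  P_pid: 1.0
  I_pid: 0.3
  tau: 600.0
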