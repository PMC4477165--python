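# Stationary high-conductance-state recreation: OU background conductances
# injected via the dynamic-clamp law, plus a constant external current.
protocol: conductance_clamp
preparation: l5_aeif
duration: 10.0
dt: 5e-5
seed: 4
params:
  background: 1x
  I_ext: 280 pA
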