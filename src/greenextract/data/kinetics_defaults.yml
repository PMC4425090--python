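# Reference kinetic parameters for the two solvents (lab maceration).
rd: 1.0e-3          # m
t0_min: 5.0
x0: 0.100           # g/g DM starting accessibility
hexane:
  deff: 0.034e-10   # m2/s
  x_inf: 0.4634     # g/g DM (from the gravimetric yield)
methf:
  deff: 0.122e-10
  x_inf: 0.4596
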