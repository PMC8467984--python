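# Predator-competition model, moderate combined noise (base parameter set).
model:
  case: competition
  a: 1.0
  b: 1.0
  c: 0.5
  f: 0.5
  s_eff: 0.1
  B_eff: 0.05
noise:
  two_eps2_D: [0.005, 0.005]
  lam: [0.5, 0.5]
  jump_var: [0.02, 0.02]
output:
  directory: out/case2_base
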