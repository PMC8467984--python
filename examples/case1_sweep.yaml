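# Saturation sweep base: frequent small jumps (rate 1.0, magnitude variance
# 0.01); `lvjump sweep` varies A_eff over {0, 0.0125, 0.025, 0.0375, 0.05}.
model:
  case: saturation
  a: 1.0
  b: 1.0
  c: 0.5
  f: 0.5
  s_eff: 0.1
  A_eff: 0.0
noise:
  two_eps2_D: [0.005, 0.005]
  lam: [1.0, 1.0]
  jump_var: [0.01, 0.01]
output:
  directory: out/case1_sweep
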