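# Predator-competition model in the sparse-jump regime: weak Gaussian noise
# (2D_i = 0.001), jumps at rate 0.2 with magnitude variance 0.04
# (Poisson intensity 0.008), self-competition 0.08.
model:
  case: competition
  a: 1.0
  b: 1.0
  c: 0.5
  f: 0.5
  s_eff: 0.08
  B_eff: 0.05
noise:
  two_eps2_D: [0.001, 0.001]
  lam: [0.2, 0.2]
  jump_var: [0.04, 0.04]
  jump_intensity: 0.008
output:
  directory: out/case2_jump
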