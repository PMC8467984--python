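# Predator-saturation model in the sparse-jump regime: weak Gaussian noise
# (2D_i = 0.001) and rare large jumps (rate 0.1, magnitude variance 0.08,
# Poisson intensity 0.008).  jump_intensity drives `lvjump compare` scans
# that trade arrival rate against magnitude at constant intensity.
model:
  case: saturation
  a: 1.0
  b: 1.0
  c: 0.5
  f: 0.5
  s_eff: 0.1
  A_eff: 0.05
noise:
  two_eps2_D: [0.001, 0.001]
  lam: [0.1, 0.1]
  jump_var: [0.08, 0.08]
  jump_intensity: 0.008
output:
  directory: out/case1_jump
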