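# Predator-saturation model, moderate combined noise (base parameter set):
# prey birth a=1, predation b=1, predator death c=0.5, conversion f=0.5,
# self-competition 0.1, saturation 0.05; Gaussian intensities 2D_i = 0.005,
# jumps at rate 0.5 with magnitude variance 0.02 per channel.
model:
  case: saturation
  a: 1.0
  b: 1.0
  c: 0.5
  f: 0.5
  s_eff: 0.1
  A_eff: 0.05
noise:
  two_eps2_D: [0.005, 0.005]
  lam: [0.5, 0.5]
  jump_var: [0.02, 0.02]
output:
  directory: out/case1_base
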