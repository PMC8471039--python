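name: fig4c
params:
  v: 1.0
  a: 0.0
  B2: 0.0
  k: 1.0
  omega: 4.0
  u_max: 5.0
  include_wall_interaction: false
  squirmer_double_angle: true
x0: 0.0
z0: 2.0
theta0: -1.5707963267948966
problem:
  id: 2
  theta1: 1.5707963267948966
notes: reorientation at fixed return height z0=2
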