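name: fig3b_w12
params:
  v: 1.0
  a: 0.0
  B2: 0.0
  k: 1.0
  omega: 12.0
  u_max: 5.0
  include_wall_interaction: false
  squirmer_double_angle: true
x0: 0.0
z0: 3.6705212530108713
theta0: -1.5707963267948966
problem:
  id: 1
  x1: 6.283185307179586
notes: '|V0|=0.34 realised with u_max=5.0 at the outer-branch height z0=3.6705212530108713'
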