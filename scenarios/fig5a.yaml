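name: fig5a
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
z0: 3.0
theta0: -1.5707963267948966
T: 5.0
policy:
  kind: open_loop
  T_switch: 1.127069483013858
  phase: 0.0
notes: open-loop period from the switch-time estimate at z0
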