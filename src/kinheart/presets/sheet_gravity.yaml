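# Hanging-plate anisotropy test: vertical 100 x 20 x 100 mm plate pinned
# along its top face, gravity 9.8 m/s^2, no activation, soft stiffness
# (M = 3) to make the fiber-direction dependence visible.  Change
# fibers.direction to [1, 0, 0] (horizontal) or [0.707, 0, 0.707] (45 deg)
# to reproduce the other cases.
mesh:
  generator: sheet
  spec: {x_len: 100.0, y_len: 20.0, z_len: 100.0, n_x: 10, n_y: 2, n_z: 10}
fibers:
  mode: constant
  direction: [0.0, 0.0, 1.0]
weights:
  mode: anisotropic
schedule:
  a_mc: 0.0
engine:
  h: 0.005
  stiffness_M: 3
  volume_preservation: false
  pins: top
  gravity: [0.0, 0.0, -9800.0]
run:
  n_cycles: 3.0
outputs:
  directory: out_sheet_gravity
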