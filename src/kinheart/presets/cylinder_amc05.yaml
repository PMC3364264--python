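# Thick-walled cylinder systole benchmark: trapezoid time-contraction
# curve, transmural +60 -> -60 deg helix fibers, maximum contraction
# rate 0.5.  One 1.1 s cycle at h = 0.01 s gives 111 recorded frames.
mesh:
  generator: cylinder
fibers:
  mode: rule
  rule: {alpha_trans: 0.0, alpha_helix_endo: 60.0, alpha_helix_epi: -60.0}
weights:
  mode: anisotropic
schedule:
  cycle_T: 1.1
  a_mc: 0.5
engine:
  h: 0.01
  stiffness_M: 10
run:
  n_cycles: 1.0
outputs:
  directory: out_cylinder_amc05
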