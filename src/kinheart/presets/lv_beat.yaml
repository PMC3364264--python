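# Idealized-LV beat: truncated half-ellipsoid (25 mm endocardial base
# radius, 10 mm wall, 70 mm long axis), transmural helix fibers, base
# ring pinned, one 1.1 s cycle.  The summary line reports the LVEF.
mesh:
  generator: lv
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
  pins: base
run:
  n_cycles: 1.0
outputs:
  directory: out_lv_beat
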