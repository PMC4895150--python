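# Isotropic tissue conductivities (S/m).  The anisotropic white-matter mode
# replaces the wm entry with fiber-aligned tensors (longitudinal 1.1,
# transverse 0.13 S/m); the wm value below is the isotropic control.
conductivity:
  scalp: 0.465
  skull: 0.01
  dura: 0.065
  csf: 1.65
  gm: 0.276
  wm: 0.126
  electrode: 9.4e6
  substrate: 0.1e-9

wm_anisotropic:
  sigma_longitudinal: 1.1
  sigma_transverse: 0.13
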