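# Base (pre-lengthening) template dimensions in um; every neurite path is
# lengthened by the factor 1.6 at build time.  Stylized defaults — substitute
# SWC reconstructions via read_swc for published morphometry.
L5:
  soma_length: 20.0
  soma_diameter: 20.0
  apical_length: 1100.0
  apical_diameter: 4.0
  tuft_length: 150.0
  tuft_diameter: 1.5
  basal_length: 150.0
  basal_diameter: 2.0
  initial_segment_length: 30.0
  initial_segment_diameter: 1.5
  axon_length: 5000.0
  axon_diameter: 1.5
L3:
  soma_length: 15.0
  soma_diameter: 15.0
  apical_length: 380.0
  apical_diameter: 3.0
  tuft_length: 120.0
  tuft_diameter: 1.2
  basal_length: 120.0
  basal_diameter: 1.5
  initial_segment_length: 30.0
  initial_segment_diameter: 1.2
  axon_length: 1000.0
  axon_diameter: 1.2
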