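# Default extruded-slab geometry (mm).
#
# Only the gyral width (8.5) is a protocol value; every other dimension is a
# literature-typical default and explicitly configuration.  The
# crown-to-crown path length is a calibration constraint: 1 mm arc-length
# sampling of the cortical path must yield 57 soma positions per plane.
precentral_gyrus_width: 8.5
sulcal_depth: 15.0
gm_thickness: 2.5
lip_fillet_radius: 3.0
scalp_thickness: 4.0
skull_thickness: 5.0
dura_thickness: 0.5
csf_thickness: 1.0
extrusion_length_z: 50.0
crown_to_crown_path_length: 56.2
sulcus_half_width: 1.0
path_depth: 1.25
wm_margin: 12.0
x_half_extent: 25.0
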