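# Membrane parameter schema, version 1.
#
# The source protocol prints no channel parameters; these defaults are a
# reduced excitable scheme (fast Na+, delayed-rectifier K+, slow
# non-inactivating K+ with published cat-cortex pyramidal kinetics) whose
# densities were calibrated once against the qualitative polarity orderings
# and then frozen.  All values are configuration, not measurement.
#
# Units: cm uF/cm^2, conductances S/cm^2, ra_ohm_cm Ohm*cm, potentials mV.
membrane:
  global:
    ra_ohm_cm: 150.0
    celsius: 36.0
    v_init: -70.0
    e_na: 60.0
    e_k: -90.0
    q10: 2.3
    kinetics_t_ref: 23.0
  soma:
    cm: 1.0
    g_pas: 3.3e-5
    gbar_na: 0.05
    gbar_kv: 0.01
    gbar_km: 3.0e-4
  apical:
    cm: 1.0
    g_pas: 3.3e-5
    gbar_na: 0.12
    gbar_kv: 0.012
    gbar_km: 0.0
  basal:
    cm: 1.0
    g_pas: 3.3e-5
    gbar_na: 0.01
    gbar_kv: 0.001
    gbar_km: 0.0
  initial_segment:
    cm: 1.0
    g_pas: 3.3e-5
    gbar_na: 3.0
    gbar_kv: 0.1
    gbar_km: 0.0
  node:
    cm: 1.0
    g_pas: 0.02
    gbar_na: 3.0
    gbar_kv: 0.1
    gbar_km: 0.0
  axon:   # myelinated internode
    cm: 0.04
    g_pas: 1.0e-6
    gbar_na: 0.0
    gbar_kv: 0.0
    gbar_km: 0.0
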