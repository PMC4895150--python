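# cortistim

Computational pipeline for subdural cortical stimulation (SuCS) biophysics:
parametric gyral volume-conductor models with anisotropic white-matter
conductivity, quasi-static finite-element field solves, and compartmental
L3/L5 pyramidal-neuron excitation-threshold mapping across stimulus
polarities (anodal / cathodal / bipolar).

Everything is synthetic and parametric — no imaging data is required. Two
geometries are provided:

* **slab** — a mirror-symmetric extruded gyral fold (crown / lip / bank /
  bottom sulcus and their opposites) with layered scalp–skull–dura–CSF–GM–WM
  compartments and covered disc electrodes on the cortical surface;
* **asymmetric** — a folded surrogate with unequal banks, standing in for an
  MRI-derived head model (which is out of scope).

## Package layout

| module | role |
| --- | --- |
| `cortistim.scenario_geometry` | geometry construction, electrodes, region labels, structured graded tet meshing |
| `cortistim.mesh_io` | Gmsh MSH v4.1 and legacy VTK serialization |
| `cortistim.conductivity_model` | isotropic tissue table, fiber fields, anisotropic WM tensors |
| `cortistim.volume_conductor` | P1 FEM quasi-static solves, current-controlled contacts, sampling, activating function |
| `cortistim.neuron_morphology` | parametric L3/L5 pyramidal templates, axon bending at the GM/WM boundary, SWC I/O, discretization |
| `cortistim.placement` | soma distribution along the cortical path, orientation frames, shift/rotation perturbations |
| `cortistim.cable_solver` | batched semi-implicit cable integration under extracellular forcing, AP detection and initiation-site classification |
| `cortistim.threshold_pipeline` | per-neuron threshold bisection campaigns across polarities |
| `cortistim.analysis_report` | region minima, excited-fraction curves, sensitivity comparisons, spatial maps, initiation summaries |

## CLI

```bash
cortistim geometry --model slab --resolution 1.0 --out slab.msh
cortistim solve --mesh slab.msh --drive anodal --out phi.vtk
cortistim thresholds --config campaign.yaml --out records.csv
cortistim report --records records.csv --out report_dir
```

A campaign YAML mirrors `cortistim.threshold_pipeline.CampaignConfig`
(geometry, conductivity mode, grounding scheme, polarities, amplitude cap and
search resolution, pulse, placement spacings, mesh resolution, seed).
Campaigns are deterministic given the config + seed, checkpoint after every
layer × polarity group, and resume from an existing output CSV.

## Notes on defaults

Only a handful of dimensions are protocol values (8.5 mm gyral width, 13 mm
electrode separation, 0.6 / 1.8 mm soma heights above the GM/WM boundary,
the 60 % neurite lengthening, the 100 µs monophasic pulse, the 100 mA cap
and the conductivity table). Every other geometric, morphometric and
membrane parameter is explicit configuration with documented defaults in
`src/cortistim/data/*.yaml`; membrane channel densities were calibrated once
against the qualitative polarity orderings and then frozen.
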