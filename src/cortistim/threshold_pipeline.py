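"""Per-neuron excitation-threshold campaigns across stimulus polarities.

One unit-amplitude field solve per driven contact suffices: the volume
conductor is linear, so cathodal forcing is the negated anodal field and the
bipolar field is the anodal field minus the return-contact field.  Bisection
over the amplitude then needs only cable integrations, which run batched
over all neurons of a layer (they share one discretization).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cable_solver import (
    CableModel,
    MembraneParameters,
    PulseSpec,
    classify_initiation,
    simulate_batch,
    APEvent,
)
from .conductivity_model import ConductivityTable, build_conductivity
from .errors import ConfigurationError, EscalationError, ParameterError
from .neuron_morphology import (
    MorphologyParams,
    bend_axon_at_boundary,
    build_morphology,
    discretize,
)
from .placement import PlacementSet, distribute_neurons
from .scenario_geometry import (
    AsymmetricParams,
    HeadGeometry,
    SlabParams,
    build_asymmetric_geometry,
    build_slab_geometry,
    default_electrode_pair,
    generate_mesh,
    label_regions,
    place_electrodes,
)
from .volume_conductor import StimulusDrive, VolumeConductor

__all__ = [
    "CampaignConfig",
    "NeuronBatch",
    "build_neuron_batch",
    "excitation_threshold",
    "search_thresholds",
    "run_campaign",
]

log = logging.getLogger(__name__)

POLARITIES = ("anodal", "cathodal", "bipolar")

RECORD_COLUMNS = [
    "neuron", "layer", "polarity", "region", "plane", "arc",
    "x", "y", "z", "excitable", "threshold_ma",
    "init_category", "init_compartment", "init_time_ms",
]


@dataclass
class CampaignConfig:
    """Everything needed to reproduce one threshold campaign."""

    geometry: str = "slab"  # slab | asymmetric
    geometry_params: dict = field(default_factory=dict)
    conductivity_mode: str = "anisotropic"  # anisotropic | isotropic_control
    grounding: str = "exterior_grounded_except_top"
    polarities: tuple = ("anodal", "cathodal", "bipolar")
    layers: tuple = ("L5", "L3")
    amplitude_cap_ma: float = 100.0
    resolution_ma: float = 1.0
    pulse: PulseSpec = field(default_factory=PulseSpec)
    spacing_mm: float = 1.0
    plane_spacing_mm: float = 1.0
    roi_mm: float = 50.0
    single_plane: bool = True  # place neurons only under the active electrode
    electrode_separation_mm: float = 13.0
    electrode_diameter_mm: float = 4.0
    electrodes_centered: bool = False
    mesh_resolution_mm: float = 0.8
    dt_us: float = 5.0
    duration_ms: float = 3.0
    max_compartment_um: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_cap_ma <= 0.0 or self.resolution_ma <= 0.0:
            raise ParameterError("amplitude cap and resolution must be positive")
        for p in self.polarities:
            if p not in POLARITIES:
                raise ParameterError(f"unknown polarity {p!r}")

    def build_geometry(self) -> HeadGeometry:
        if self.geometry == "slab":
            params = SlabParams(**self.geometry_params)
            geom = build_slab_geometry(params)
        elif self.geometry == "asymmetric":
            params = AsymmetricParams(**self.geometry_params)
            geom = build_asymmetric_geometry(params)
        else:
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        specs = default_electrode_pair(
            geom, separation=self.electrode_separation_mm,
            centered=self.electrodes_centered,
            diameter=self.electrode_diameter_mm)
        return place_electrodes(geom, specs)

    @classmethod
    def from_yaml(cls, path: str) -> "CampaignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "pulse" in data:
            data["pulse"] = PulseSpec(**data["pulse"])
        for key in ("polarities", "layers"):
            if key in data:
                data[key] = tuple(data[key])
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in names})


@dataclass
class NeuronBatch:
    """All placed instances of one layer sharing a cable discretization."""

    layer: str
    placement: PlacementSet
    model: CableModel
    centers: np.ndarray  # (N, n_comp, 3) world compartment centres
    depths: np.ndarray  # (N, n_comp) cortical depth of each centre
    bend_ranges: list  # per neuron, axon arc range of the bend (or None)
    compsets: list  # per-neuron world CompartmentSet


def build_neuron_batch(geom: HeadGeometry, placement: PlacementSet,
                       morph_params: MorphologyParams | None = None,
                       membrane: MembraneParameters | None = None,
                       max_compartment_um: float = 25.0,
                       bend_radius_mm: float = 0.3) -> NeuronBatch:
    """Instantiate, orient, bend (L5) and discretize every placed neuron."""
    layer = placement.layer
    template = build_morphology(layer, morph_params)
    t = geom.params.gm_thickness

    def beyond(points: np.ndarray) -> np.ndarray:
        return geom.depth(points[:, :2]) > t

    local_comp = discretize(template, max_compartment_um)
    model = CableModel(local_comp, membrane)

    centers = np.empty((placement.n, local_comp.n, 3))
    depths = np.empty((placement.n, local_comp.n))
    bends: list = []
    compsets: list = []
    for i in range(placement.n):
        world = template.transformed(placement.frames[i], placement.soma[i])
        if layer == "L5":
            world = bend_axon_at_boundary(world, beyond, (0.0, -1.0, 0.0),
                                          bend_radius=bend_radius_mm)
        comp = discretize(world, max_compartment_um)
        if comp.n != local_comp.n:
            raise ConfigurationError("instance discretization mismatch")
        centers[i] = comp.centers
        depths[i] = geom.depth(comp.centers[:, :2])
        bends.append(world.bend_range)
        compsets.append(comp)
    return NeuronBatch(layer=layer, placement=placement, model=model,
                       centers=centers, depths=depths, bend_ranges=bends,
                       compsets=compsets)


def search_thresholds(model: CableModel, phi_unit: np.ndarray,
                      pulse: PulseSpec, cap_ma: float, resolution_ma: float,
                      dt_us: float, duration_ms: float):
    """Batched bisection to ``resolution_ma`` on [0, cap] per neuron.

    Returns (thresholds (N,), excitable (N,), at-threshold BatchResult with
    crossing times of the final confirming run).
    """
    phi_unit = np.atleast_2d(phi_unit)
    N = phi_unit.shape[0]

    res = simulate_batch(model, phi_unit, np.full(N, cap_ma), pulse,
                         dt_us=dt_us, duration_ms=duration_ms)
    excitable = res.fired
    lo = np.zeros(N)
    hi = np.full(N, cap_ma)
    while (hi[excitable] - lo[excitable] > resolution_ma + 1e-12).any():
        mid = 0.5 * (lo + hi)
        r = simulate_batch(model, phi_unit, mid, pulse,
                           dt_us=dt_us, duration_ms=duration_ms)
        fired = r.fired
        hi = np.where(excitable & fired, mid, hi)
        lo = np.where(excitable & ~fired, mid, lo)
    thresholds = np.where(excitable, hi, np.nan)
    final = simulate_batch(model, phi_unit,
                           np.where(excitable, hi, cap_ma), pulse,
                           dt_us=dt_us, duration_ms=duration_ms)
    if (excitable & ~final.fired).any():
        bad = int(np.flatnonzero(excitable & ~final.fired)[0])
        raise EscalationError(
            f"non-monotone firing: neuron {bad} fired in the bracket but not "
            f"at the returned threshold {hi[bad]:.3f} mA")
    return thresholds, excitable, final


def excitation_threshold(batch: NeuronBatch, index: int, phi_unit: np.ndarray,
                         pulse: PulseSpec, cap_ma: float = 100.0,
                         resolution_ma: float = 1.0, dt_us: float = 5.0,
                         duration_ms: float = 3.0, gm_thickness: float = 2.5):
    """Threshold record dict for a single neuron instance (spec-level op).

    Verifies the bracket: the returned amplitude fires while amplitude -
    resolution does not (when above zero).
    """
    phi = np.atleast_2d(phi_unit)
    thr, exc, final = search_thresholds(batch.model, phi, pulse, cap_ma,
                                        resolution_ma, dt_us, duration_ms)
    record = {"excitable": bool(exc[0]), "threshold_ma": float(thr[0]),
              "init_category": "", "init_compartment": -1,
              "init_time_ms": np.nan}
    if exc[0]:
        below = thr[0] - resolution_ma
        if below > 0.0:
            sub = simulate_batch(batch.model, phi, np.array([below]), pulse,
                                 dt_us=dt_us, duration_ms=duration_ms)
            if sub.fired[0]:
                raise EscalationError(
                    f"amplitude {below:.3f} mA below the returned threshold "
                    f"{thr[0]:.3f} mA also fires")
        fc = final.first_cross[0]
        i = int(np.nanargmin(fc))
        ev = APEvent(True, fc, initiation_compartment=i,
                     initiation_time=float(fc[i]))
        record["init_compartment"] = i
        record["init_time_ms"] = float(fc[i])
        record["init_category"] = classify_initiation(
            ev, batch.compsets[index], batch.depths[index], gm_thickness,
            batch.bend_ranges[index])
    return record


def _records_for_polarity(batch: NeuronBatch, phi_unit: np.ndarray,
                          polarity: str, config: CampaignConfig,
                          gm_thickness: float) -> pd.DataFrame:
    thr, exc, final = search_thresholds(
        batch.model, phi_unit, config.pulse, config.amplitude_cap_ma,
        config.resolution_ma, config.dt_us, config.duration_ms)
    pl = batch.placement
    rows = []
    for i in range(pl.n):
        row = {
            "neuron": int(pl.ids[i]), "layer": batch.layer,
            "polarity": polarity, "region": pl.region[i],
            "plane": int(pl.plane[i]), "arc": float(pl.arc[i]),
            "x": pl.soma[i, 0], "y": pl.soma[i, 1], "z": pl.soma[i, 2],
            "excitable": bool(exc[i]),
            "threshold_ma": float(thr[i]) if exc[i] else np.nan,
            "init_category": "", "init_compartment": -1,
            "init_time_ms": np.nan,
        }
        if exc[i]:
            fc = final.first_cross[i]
            ci = int(np.nanargmin(fc))
            ev = APEvent(True, fc, initiation_compartment=ci,
                         initiation_time=float(fc[ci]))
            row["init_compartment"] = ci
            row["init_time_ms"] = float(fc[ci])
            row["init_category"] = classify_initiation(
                ev, batch.compsets[i], batch.depths[i], gm_thickness,
                batch.bend_ranges[i])
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_campaign(config: CampaignConfig, out_path: str | None = None,
                 membrane: MembraneParameters | None = None,
                 conductivity_table: ConductivityTable | None = None,
                 geometry: HeadGeometry | None = None,
                 placements: dict | None = None) -> pd.DataFrame:
    """Execute a full campaign; deterministic given the config.

    With ``out_path`` the record table is checkpointed after every
    layer x polarity group and finished groups are skipped on re-run.
    """
    rng = np.random.default_rng(config.seed)  # reserved for stochastic options
    del rng
    geom = geometry if geometry is not None else config.build_geometry()
    mesh = generate_mesh(geom, resolution=config.mesh_resolution_mm)
    log.info("mesh: %d nodes, %d elements", mesh.n_nodes, mesh.n_elements)
    cond = build_conductivity(geom, mesh, config.conductivity_mode,
                              conductivity_table)
    vc = VolumeConductor(mesh, cond)

    field_active = vc.solve(StimulusDrive("anodal", grounding=config.grounding))
    field_return = None
    if "bipolar" in config.polarities:
        ret = [i for i, e in enumerate(geom.electrodes, 1) if e.role == "return"]
        if not ret:
            raise ConfigurationError("bipolar polarity requires a return contact")
        field_return = vc.solve(StimulusDrive(
            "anodal", grounding=config.grounding, contacts=((ret[0], 1.0),)))

    done = None
    if out_path and os.path.exists(out_path):
        done = pd.read_csv(out_path)
        log.info("resuming: %d records present", len(done))

    active = geom.active_electrode
    if config.single_plane:
        planes = np.array([active.center_z if active else 0.0])
    else:
        planes = None

    region_map = label_regions(geom, active)
    groups = []
    if done is not None:
        groups.append(done)
    for layer in config.layers:
        placement = (placements or {}).get(layer) or distribute_neurons(
            geom, layer, spacing_along_path=config.spacing_mm,
            plane_spacing=config.plane_spacing_mm, roi_mm=config.roi_mm,
            planes=planes, region_map=region_map)
        if placement.n == 0:
            raise ConfigurationError(f"no {layer} instances to simulate")
        batch = build_neuron_batch(
            geom, placement, membrane=membrane,
            max_compartment_um=config.max_compartment_um)
        pts = batch.centers.reshape(-1, 3)
        phi_a = field_active.sample(pts).reshape(placement.n, -1)
        phi_r = (field_return.sample(pts).reshape(placement.n, -1)
                 if field_return is not None else None)
        for polarity in config.polarities:
            if done is not None and (
                    (done["layer"] == layer)
                    & (done["polarity"] == polarity)).any():
                log.info("skipping completed group %s/%s", layer, polarity)
                continue
            if polarity == "anodal":
                phi = phi_a
            elif polarity == "cathodal":
                phi = -phi_a
            else:
                phi = phi_a - phi_r
            log.info("thresholds: %s %s (%d neurons)", layer, polarity,
                     placement.n)
            df = _records_for_polarity(batch, phi, polarity, config,
                                       geom.params.gm_thickness)
            groups.append(df)
            if out_path:
                pd.concat(groups, ignore_index=True).to_csv(out_path,
                                                            index=False)
    return pd.concat(groups, ignore_index=True)
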