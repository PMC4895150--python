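"""Distribution of neuron instances over the cortical geometry.

Somata sit at uniform arc-length intervals along the crown -> sulcus ->
opposite-crown path, replicated on cross-section planes along the extrusion
axis, at a layer-specific height above the GM/WM boundary.  Orientation
frames align the apical axis with the outward cortical normal.  Perturbation
operators (normal shifts, dendrite rotation about the apical axis) support
the sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ParameterError, PlacementError
from .scenario_geometry import HeadGeometry, RegionMap, label_regions

__all__ = [
    "PlacementSet",
    "SOMA_HEIGHT_ABOVE_BOUNDARY",
    "distribute_neurons",
    "perturb_positions",
    "rotate_dendrites",
]

#: soma height above the GM/WM boundary per layer (mm)
SOMA_HEIGHT_ABOVE_BOUNDARY = {"L5": 0.6, "L3": 1.8}


@dataclass
class PlacementSet:
    """Soma positions, orientation frames and labels for one layer."""

    ids: np.ndarray  # (N,) int
    soma: np.ndarray  # (N, 3) mm
    frames: np.ndarray  # (N, 3, 3) columns = world directions of local x/y/z
    layer: str
    region: np.ndarray  # (N,) object
    plane: np.ndarray  # (N,) int plane index
    arc: np.ndarray  # (N,) arc position along the path (mm)

    @property
    def n(self) -> int:
        return len(self.ids)

    def apical_axis(self) -> np.ndarray:
        """World apical direction (local +y) per instance."""
        return self.frames[:, :, 1]

    def to_frame(self) -> pd.DataFrame:
        quat = Rotation.from_matrix(self.frames).as_quat()
        df = pd.DataFrame({
            "id": self.ids,
            "x": self.soma[:, 0], "y": self.soma[:, 1], "z": self.soma[:, 2],
            "layer": self.layer, "region": self.region, "plane": self.plane,
            "arc": self.arc,
            "qx": quat[:, 0], "qy": quat[:, 1],
            "qz": quat[:, 2], "qw": quat[:, 3],
        })
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def distribute_neurons(geom: HeadGeometry, layer: str,
                       spacing_along_path: float = 1.0,
                       plane_spacing: float = 1.0,
                       roi_mm: float = 50.0,
                       planes: np.ndarray | None = None,
                       region_map: RegionMap | None = None) -> PlacementSet:
    """Place somata along the cortical path on planes spanning the ROI.

    ``planes`` overrides the default inclusive 1 mm ladder over the ROI
    (useful for single-plane campaigns).
    """
    if layer not in SOMA_HEIGHT_ABOVE_BOUNDARY:
        raise ParameterError(f"unknown layer {layer!r}")
    if spacing_along_path <= 0.0 or plane_spacing <= 0.0:
        raise ParameterError("spacings must be positive")
    p = geom.params
    if planes is None and (roi_mm > p.extrusion_length_z + 1e-9
                           or roi_mm > 2 * p.x_half_extent + 1e-9):
        raise PlacementError(f"ROI {roi_mm} mm exceeds the geometry extent")

    path = geom.cortical_path()
    region_map = region_map or label_regions(geom)
    # centre the ladder on the path midpoint so slab placement mirrors exactly
    n_s = int(np.floor(path.length / spacing_along_path + 1e-9)) + 1
    offset = 0.5 * (path.length - (n_s - 1) * spacing_along_path)
    s_values = offset + spacing_along_path * np.arange(n_s)
    target_depth = p.gm_thickness - SOMA_HEIGHT_ABOVE_BOUNDARY[layer]
    if target_depth <= 0.0:
        raise PlacementError("soma height above the boundary exceeds GM thickness")

    soma2d = np.empty((len(s_values), 2))
    for i, s in enumerate(s_values):
        soma2d[i] = geom.depth_point(float(s), target_depth, path)
    normals = path.inward_normal(s_values)
    apical2d = -normals  # toward the pial surface
    regions = region_map.label_of_s(s_values)

    if planes is None:
        planes = np.arange(-0.5 * roi_mm, 0.5 * roi_mm + 1e-9, plane_spacing)
    planes = np.asarray(planes, float)

    n_per = len(s_values)
    N = n_per * len(planes)
    soma = np.empty((N, 3))
    frames = np.empty((N, 3, 3))
    region = np.empty(N, dtype=object)
    plane_idx = np.empty(N, dtype=np.int64)
    arc = np.empty(N)
    zhat = np.array([0.0, 0.0, 1.0])
    for k, z in enumerate(planes):
        sl = slice(k * n_per, (k + 1) * n_per)
        soma[sl, 0] = soma2d[:, 0]
        soma[sl, 1] = soma2d[:, 1]
        soma[sl, 2] = z
        a3 = np.column_stack([apical2d, np.zeros(n_per)])
        u = np.cross(a3, np.broadcast_to(zhat, a3.shape))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        frames[sl, :, 0] = u
        frames[sl, :, 1] = a3
        frames[sl, :, 2] = np.broadcast_to(zhat, a3.shape)
        region[sl] = regions
        plane_idx[sl] = k
        arc[sl] = s_values
    return PlacementSet(ids=np.arange(N), soma=soma, frames=frames,
                        layer=layer, region=region, plane=plane_idx, arc=arc)


def perturb_positions(pset: PlacementSet, geom: HeadGeometry,
                      offset_mm: float, sign: str = "up") -> PlacementSet:
    """Shift somata along the local cortical normal (up = toward the pia).

    Instances whose soma would leave the gray matter are dropped with a
    warning reporting the exclusion count.
    """
    if sign not in ("up", "down"):
        raise ParameterError("sign must be 'up' or 'down'")
    direction = 1.0 if sign == "up" else -1.0
    shift = direction * offset_mm * pset.apical_axis()
    soma = pset.soma + shift
    depth = geom.depth(soma[:, :2])
    inside = (depth > 0.0) & (depth < geom.params.gm_thickness)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} somata left the GM after a "
                      f"{offset_mm} mm {sign} shift and were excluded")
    return PlacementSet(ids=pset.ids[inside], soma=soma[inside],
                        frames=pset.frames[inside], layer=pset.layer,
                        region=pset.region[inside], plane=pset.plane[inside],
                        arc=pset.arc[inside])


def rotate_dendrites(pset: PlacementSet, angle_deg: float) -> PlacementSet:
    """Rotate orientation frames about the local apical axis; somata fixed."""
    if not 0.0 <= angle_deg <= 90.0:
        raise ParameterError("rotation angle must be in [0, 90] degrees")
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # rotation about the local y axis (apical), applied in local coordinates
    Ry = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    frames = pset.frames @ Ry[None, :, :]
    return PlacementSet(ids=pset.ids.copy(), soma=pset.soma.copy(),
                        frames=frames, layer=pset.layer,
                        region=pset.region.copy(), plane=pset.plane.copy(),
                        arc=pset.arc.copy())
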