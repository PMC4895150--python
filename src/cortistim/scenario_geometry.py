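"""Synthetic gyral volume-conductor geometries, electrodes, region labels and meshing.

Two parametric cross-sections are provided, both extruded along z:

* a mirror-symmetric slab with a single sulcal fold centred on the midplane
  (x = 0), and
* an asymmetric surrogate in which the two banks of the fold differ in arc
  length (and optionally curvature).  This stands in for an MRI-derived head
  model, which is out of scope here.

Coordinates are millimetres.  x runs across the gyri (midplane of the fold at
x = 0), y is the depth axis perpendicular to the skull (positive up, pial
surface of the crowns at y = 0) and z is the extrusion axis.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
import yaml
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box as shapely_box

from .errors import (
    GeometryError,
    MeshError,
    ParameterError,
    PlacementError,
)

__all__ = [
    "Tissue",
    "SlabParams",
    "AsymmetricParams",
    "ElectrodeSpec",
    "RegionBands",
    "RegionMap",
    "CorticalPath",
    "HeadGeometry",
    "Mesh",
    "build_slab_geometry",
    "build_asymmetric_geometry",
    "place_electrodes",
    "default_electrode_pair",
    "label_regions",
    "generate_mesh",
]


class Tissue(enum.IntEnum):
    """Tissue compartment codes used for element labels."""

    SCALP = 1
    SKULL = 2
    DURA = 3
    CSF = 4
    GM = 5
    WM = 6
    ELECTRODE = 7
    SUBSTRATE = 8


#: Region labels along the crown -> sulcus -> opposite-crown path.
REGION_LABELS = ("C", "L", "B", "BS", "OB", "OL", "OC")


@dataclass(frozen=True)
class SlabParams:
    """Parameters of the mirror-symmetric extruded-slab cross-section.

    Only the gyral width is printed in the source protocol; the remaining
    dimensions default to literature-typical values and are explicitly
    configuration, not measurement.
    """

    precentral_gyrus_width: float = 8.5
    sulcal_depth: float = 15.0
    gm_thickness: float = 2.5
    #: pial radius of curvature at the gyral lips; keeps the cortex at full
    #: thickness around the fold (must exceed gm_thickness)
    lip_fillet_radius: float = 3.0
    scalp_thickness: float = 4.0
    skull_thickness: float = 5.0
    dura_thickness: float = 0.5
    csf_thickness: float = 1.0
    extrusion_length_z: float = 50.0
    crown_to_crown_path_length: float = 56.2
    sulcus_half_width: float = 1.0
    #: depth (into GM) of the canonical cortical path used for placement
    path_depth: float = 1.25
    #: extent of WM kept below the sulcus bottom
    wm_margin: float = 12.0
    #: half extent of the domain box in x
    x_half_extent: float = 25.0

    def validate(self) -> None:
        positive = (
            "precentral_gyrus_width",
            "gm_thickness",
            "scalp_thickness",
            "skull_thickness",
            "dura_thickness",
            "csf_thickness",
            "extrusion_length_z",
            "crown_to_crown_path_length",
            "sulcus_half_width",
            "path_depth",
            "wm_margin",
            "x_half_extent",
        )
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sulcal_depth <= self.sulcus_half_width:
            raise GeometryError(
                "sulcal_depth must exceed sulcus_half_width to form a fold "
                f"(got {self.sulcal_depth} <= {self.sulcus_half_width})"
            )
        if self.lip_fillet_radius < 0.0:
            raise GeometryError("lip fillet radius must be non-negative")
        if self.lip_fillet_radius > 0.0 and \
                self.lip_fillet_radius <= self.gm_thickness:
            raise GeometryError("lip fillet radius must exceed gm_thickness "
                                "so the cortex keeps full thickness at the lip")
        if self.sulcal_depth <= self.lip_fillet_radius + self.sulcus_half_width:
            raise GeometryError("sulcal depth too small for the lip fillet")
        if self.path_depth >= self.gm_thickness:
            raise ParameterError("path_depth must lie inside the gray matter")

    @classmethod
    def from_yaml(cls, path: str) -> "SlabParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in names})


@dataclass(frozen=True)
class AsymmetricParams(SlabParams):
    """Slab parameters plus per-side bank asymmetry.

    ``asymmetry_factor`` is the ratio of the opposite-side (x > 0) bank arc
    length to the electrode-side (x < 0) bank arc length.  Factor 1
    reproduces the slab cross-section exactly.
    """

    asymmetry_factor: float = 1.3
    #: bulge curvature (1/mm) of each bank, 0 = straight wall
    bank_curvature_active: float = 0.0
    bank_curvature_opposite: float = 0.0
    #: outer-boundary closure: "box" keeps the slab exterior; "hull" adds a
    #: distant ground patch on the bottom boundary standing in for a chest
    #: reference electrode
    closure: str = "box"

    def validate(self) -> None:  # noqa: D102
        super().validate()
        if self.asymmetry_factor < 1.0:
            raise ParameterError(
                f"asymmetry factor must be >= 1, got {self.asymmetry_factor}"
            )
        if self.bank_curvature_active < 0.0 or self.bank_curvature_opposite < 0.0:
            raise GeometryError("bank curvature must be non-negative")
        if self.closure not in ("box", "hull"):
            raise ParameterError(f"unknown closure mode {self.closure!r}")


@dataclass(frozen=True)
class ElectrodeSpec:
    """A covered disc electrode lying on the subdural (cortical) surface."""

    center_x: float
    center_z: float
    role: str = "active"  # active | return | reference
    diameter: float = 4.0
    thickness: float = 0.5
    substrate_extent: float = 8.0
    substrate_thickness: float = 0.5
    kind: str = "disc_covered"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.thickness <= 0:
            raise ParameterError("electrode dimensions must be positive")
        if self.role not in ("active", "return", "reference"):
            raise ParameterError(f"unknown electrode role {self.role!r}")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


# --------------------------------------------------------------------------
# cross-section construction helpers
# --------------------------------------------------------------------------


def _arc_points(p0, p1, curvature: float, n: int = 24, bulge_sign: float = 1.0):
    """Sample a circular arc of given curvature between two points.

    curvature == 0 returns the straight segment.  The arc bulges to the side
    of the chord given by ``bulge_sign`` (+1 = left of p0->p1).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if curvature == 0.0:
        t = np.linspace(0.0, 1.0, n)[:, None]
        return p0[None, :] * (1 - t) + p1[None, :] * t
    chord = np.linalg.norm(p1 - p0)
    radius = 1.0 / curvature
    if 2.0 * radius < chord:
        raise GeometryError(
            f"bank curvature {curvature} too large for chord {chord:.3f} mm"
        )
    mid = 0.5 * (p0 + p1)
    direction = (p1 - p0) / chord
    normal = bulge_sign * np.array([-direction[1], direction[0]])
    h = np.sqrt(radius**2 - (0.5 * chord) ** 2)
    center = mid - normal * h
    a0 = np.arctan2(p0[1] - center[1], p0[0] - center[0])
    a1 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
    # choose the arc on the bulge side (shorter sweep)
    da = (a1 - a0 + np.pi) % (2.0 * np.pi) - np.pi
    angles = a0 + np.linspace(0.0, da, n)
    return center[None, :] + radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _lip_fillet(wall_top: np.ndarray, wall_dir_up: np.ndarray,
                brain_normal: np.ndarray, radius: float):
    """Fillet circle tangent to a bank wall and the pial plane y = 0.

    Returns (removed polygon to union into the slot, arc midpoint).
    ``wall_dir_up`` points up along the wall; ``brain_normal`` points from the
    wall into the brain.
    """
    u = wall_dir_up / np.linalg.norm(wall_dir_up)
    n = brain_normal / np.linalg.norm(brain_normal)
    if abs(u[1]) < 1e-9:
        raise GeometryError("bank wall is horizontal; cannot fillet the lip")
    # centre on the brain-side offset line of the wall, at height -radius
    a = (-radius - wall_top[1] - radius * n[1]) / u[1]
    center = wall_top + a * u + radius * n
    w_t = center - radius * n  # tangent point on the wall
    p_t = np.array([center[0], 0.0])  # tangent point on the pial plane
    ang_w = np.arctan2(w_t[1] - center[1], w_t[0] - center[0])
    ang_p = np.arctan2(p_t[1] - center[1], p_t[0] - center[0])
    da = (ang_p - ang_w + np.pi) % (2.0 * np.pi) - np.pi
    angles = ang_w + np.linspace(0.0, da, 32)
    arc = center[None, :] + radius * np.stack(
        [np.cos(angles), np.sin(angles)], axis=1)
    # removed material: wall tangent point -> original lip -> pial tangent
    # point, closed by the arc
    region = Polygon(np.vstack([[w_t], [wall_top], [p_t], arc[::-1][1:-1]]))
    if not region.is_valid:
        region = region.buffer(0.0)
    mid = center + radius * np.array(
        [np.cos(ang_w + 0.5 * da), np.sin(ang_w + 0.5 * da)])
    return region, mid


def _build_slot_polygon(params: SlabParams):
    """Polygon of the CSF-filled sulcal slot plus lip landmark points."""
    hw = params.sulcus_half_width
    yc = -(params.sulcal_depth - hw)  # centre of the rounded bottom

    factor = getattr(params, "asymmetry_factor", 1.0)
    curv_a = getattr(params, "bank_curvature_active", 0.0)
    curv_o = getattr(params, "bank_curvature_opposite", 0.0)

    bank = params.sulcal_depth - hw  # straight electrode-side bank length
    # opposite bank: straight chord slanted outward so its length is factor*bank
    run = bank * np.sqrt(max(factor**2 - 1.0, 0.0))
    x_top_right = hw + run

    left_wall = _arc_points((-hw, yc), (-hw, 0.0), curv_a, bulge_sign=1.0)
    right_wall = _arc_points((hw, yc), (x_top_right, 0.0), curv_o, bulge_sign=-1.0)
    angles = np.linspace(np.pi, 2.0 * np.pi, 48)
    bottom = np.stack([hw * np.cos(angles), yc + hw * np.sin(angles)], axis=1)

    ring = np.vstack(
        [
            left_wall[::-1],  # (-hw, 0) down to (-hw, yc)
            bottom[1:],  # around the bottom to (hw, yc)
            right_wall[1:],  # up to (x_top_right, 0)
        ]
    )
    poly = Polygon(ring)
    if not poly.is_valid or poly.area <= 0.0:
        raise GeometryError("sulcal slot polygon is self-intersecting")

    r = params.lip_fillet_radius
    if r <= 0.0:
        lips = (np.array([-hw, 0.0]), np.array([x_top_right, 0.0]))
        return poly, lips
    dir_l = left_wall[-1] - left_wall[-2]
    reg_l, mid_l = _lip_fillet(np.array([-hw, 0.0]), dir_l,
                               np.array([-dir_l[1], dir_l[0]]), r)
    dir_r = right_wall[-1] - right_wall[-2]
    reg_r, mid_r = _lip_fillet(np.array([x_top_right, 0.0]), dir_r,
                               np.array([dir_r[1], -dir_r[0]]), r)
    poly = poly.union(reg_l).union(reg_r)
    if poly.geom_type != "Polygon" or not poly.is_valid:
        raise GeometryError("lip fillets produced an invalid slot polygon")
    return poly, (mid_l, mid_r)


class CorticalPath:
    """Arc-length parameterised polyline along the cortex at fixed depth."""

    def __init__(self, points: np.ndarray):
        if len(points) < 2:
            raise GeometryError("cortical path needs at least two points")
        self.points = np.asarray(points, float)
        seg = np.diff(self.points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        keep = seglen > 1e-12
        self.points = np.vstack([self.points[:1], self.points[1:][keep]])
        seg = np.diff(self.points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        self.cumlen = np.concatenate([[0.0], np.cumsum(seglen)])
        self.length = float(self.cumlen[-1])
        self._tangents = seg / seglen[:, None]
        dense_s = np.arange(0.0, self.length, 0.05)
        self._dense_s = dense_s
        self._tree = cKDTree(self.sample(dense_s))

    def sample(self, s) -> np.ndarray:
        """xy point(s) at arc position(s) ``s``."""
        s = np.atleast_1d(np.asarray(s, float))
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self.cumlen, s, side="right") - 1, 0,
                      len(self._tangents) - 1)
        local = s - self.cumlen[idx]
        return self.points[idx] + self._tangents[idx] * local[:, None]

    def tangent(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self.cumlen, s, side="right") - 1, 0,
                      len(self._tangents) - 1)
        return self._tangents[idx]

    def inward_normal(self, s) -> np.ndarray:
        """Unit normal pointing deeper into the cortex."""
        t = self.tangent(s)
        return np.stack([t[:, 1], -t[:, 0]], axis=1)

    def project(self, xy: np.ndarray) -> np.ndarray:
        """Arc position of the nearest path point for each query point."""
        xy = np.atleast_2d(np.asarray(xy, float))
        _, idx = self._tree.query(xy)
        return self._dense_s[idx]


@dataclass
class RegionBands:
    """Arc-length half-widths of the lip and bottom-sulcus bands."""

    lip_halfwidth: float = 2.0
    bottom_halfwidth: float = 2.0


class RegionMap:
    """Total labelling of the cortical path into the seven gyral regions."""

    def __init__(self, path: CorticalPath, s_lip: float, s_bottom: float,
                 s_lip_opp: float, bands: RegionBands):
        self.path = path
        self.s_lip = s_lip
        self.s_bottom = s_bottom
        self.s_lip_opp = s_lip_opp
        self.bands = bands

    def label_of_s(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        out = np.empty(s.shape, dtype=object)
        lw, bw = self.bands.lip_halfwidth, self.bands.bottom_halfwidth
        out[:] = "B"
        out[s < self.s_lip - lw] = "C"
        out[np.abs(s - self.s_lip) <= lw] = "L"
        out[np.abs(s - self.s_bottom) <= bw] = "BS"
        opp = s > self.s_bottom + bw
        out[opp] = "OB"
        out[np.abs(s - self.s_lip_opp) <= lw] = "OL"
        out[s > self.s_lip_opp + lw] = "OC"
        return out

    def label_points(self, xy: np.ndarray) -> np.ndarray:
        return self.label_of_s(self.path.project(xy))


# --------------------------------------------------------------------------
# head geometry
# --------------------------------------------------------------------------


class HeadGeometry:
    """Labelled tissue compartments + electrode placements for a gyral model.

    The geometry is an implicit description (vectorised point -> tissue
    queries); :func:`generate_mesh` turns it into a labelled tetrahedral mesh.
    """

    def __init__(self, params: SlabParams, kind: str):
        params.validate()
        self.params = params
        self.kind = kind
        self.slot, self.lip_points = _build_slot_polygon(params)
        self._slot_boundary = self.slot.exterior
        self.electrodes: list[ElectrodeSpec] = []

        p = params
        self.y_top = (
            p.csf_thickness + p.dura_thickness + p.skull_thickness + p.scalp_thickness
        )
        self.y_bottom = -(p.sulcal_depth + p.wm_margin)
        self.bounds = (
            (-p.x_half_extent, p.x_half_extent),
            (self.y_bottom, self.y_top),
            (-0.5 * p.extrusion_length_z, 0.5 * p.extrusion_length_z),
        )
        slot_max_x = float(np.max(np.asarray(self.slot.exterior.coords)[:, 0]))
        if slot_max_x >= p.x_half_extent - 1.0:
            raise GeometryError("sulcal slot reaches the domain boundary; "
                                "increase x_half_extent")
        self._path_cache: dict[float, CorticalPath] = {}

    # -- implicit queries ---------------------------------------------------

    def depth(self, xy: np.ndarray) -> np.ndarray:
        """Signed cortical depth (mm) of cross-section points.

        Positive inside the brain (distance to the pial surface), negative in
        the CSF slot / above the brain.
        """
        xy = np.atleast_2d(np.asarray(xy, float))
        x, y = xy[:, 0], xy[:, 1]
        pts = shapely.points(x, y)
        d_slot = shapely.distance(pts, self._slot_boundary)
        inside_slot = shapely.contains_xy(self.slot, x, y)
        depth = np.minimum(-y, d_slot)
        depth = np.where(inside_slot, -d_slot, depth)
        above = y >= 0.0
        depth = np.where(above & ~inside_slot, -y, depth)
        return depth

    def tissue_at(self, points: np.ndarray) -> np.ndarray:
        """Tissue code for each 3D point (Nx3)."""
        points = np.atleast_2d(np.asarray(points, float))
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        p = self.params
        out = np.full(len(points), int(Tissue.SCALP), dtype=np.int32)

        below = y < 0.0
        depth = self.depth(points[:, :2][below]) if below.any() else np.empty(0)
        sub = np.full(below.sum(), int(Tissue.CSF), dtype=np.int32)
        sub[depth > 0.0] = int(Tissue.GM)
        sub[depth > p.gm_thickness] = int(Tissue.WM)
        out[below] = sub

        y0 = 0.0
        layers = (
            (Tissue.CSF, p.csf_thickness),
            (Tissue.DURA, p.dura_thickness),
            (Tissue.SKULL, p.skull_thickness),
            (Tissue.SCALP, p.scalp_thickness),
        )
        for tissue, thickness in layers:
            mask = (y >= y0) & (y < y0 + thickness)
            out[mask] = int(tissue)
            y0 += thickness

        for spec in self.electrodes:
            r2 = (x - spec.center_x) ** 2 + (z - spec.center_z) ** 2
            disc = (r2 <= spec.radius**2) & (y >= 0.0) & (y < spec.thickness)
            out[disc] = int(Tissue.ELECTRODE)
            half = 0.5 * spec.substrate_extent
            sub_mask = (
                (np.abs(x - spec.center_x) <= half)
                & (np.abs(z - spec.center_z) <= half)
                & (y >= spec.thickness)
                & (y < spec.thickness + spec.substrate_thickness)
            )
            out[sub_mask] = int(Tissue.SUBSTRATE)
        return out

    def contact_at(self, points: np.ndarray) -> np.ndarray:
        """Electrode contact index (0 = none, 1-based otherwise) per point."""
        points = np.atleast_2d(np.asarray(points, float))
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        out = np.zeros(len(points), dtype=np.int32)
        for i, spec in enumerate(self.electrodes, start=1):
            r2 = (x - spec.center_x) ** 2 + (z - spec.center_z) ** 2
            disc = (r2 <= spec.radius**2) & (y >= 0.0) & (y < spec.thickness)
            out[disc] = i
        return out

    # -- cortical path ------------------------------------------------------

    def _brain_polygon(self) -> Polygon:
        (x0, x1), (y0, _), _ = self.bounds
        return shapely_box(x0, y0, x1, 0.0).difference(self.slot)

    def cortical_path(self, depth: float | None = None) -> CorticalPath:
        """Crown -> sulcus -> opposite-crown path at the given cortical depth.

        The crown runs on either side are sized so the total arc length
        equals ``crown_to_crown_path_length``.
        """
        p = self.params
        if depth is None:
            depth = p.path_depth
        depth = float(depth)
        if depth in self._path_cache:
            return self._path_cache[depth]
        if not 0.0 < depth < p.gm_thickness:
            raise ParameterError("path depth must lie strictly inside the GM")

        inner = self._brain_polygon().buffer(-depth, quad_segs=64)
        if inner.is_empty:
            raise GeometryError("geometry too thin for the requested path depth")
        if inner.geom_type == "MultiPolygon":
            inner = max(inner.geoms, key=lambda g: g.area)
        ring = np.asarray(inner.exterior.coords)[:-1]

        (bx0, bx1), (by0, _), _ = self.bounds
        near_side = (ring[:, 0] <= bx0 + depth + 1e-6) | (
            ring[:, 0] >= bx1 - depth - 1e-6
        )
        near_bottom = ring[:, 1] <= by0 + depth + 1e-6
        keep = ~(near_side | near_bottom)
        if not keep.any():
            raise GeometryError("could not locate cortical portion of offset ring")
        # rotate so a discarded vertex is first, then take the longest kept run
        first_out = int(np.argmin(keep))
        keep = np.roll(keep, -first_out)
        ring = np.roll(ring, -first_out, axis=0)
        idx = np.flatnonzero(keep)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, breaks + 1)
        run = max(runs, key=len)
        top = ring[run]
        if top[0, 0] > top[-1, 0]:
            top = top[::-1]

        flat = np.abs(top[:, 1] + depth) < 1e-6
        fold_idx = np.flatnonzero(~flat)
        if len(fold_idx) == 0:
            raise GeometryError("offset ring has no fold")
        i_entry = max(fold_idx[0] - 1, 0)
        i_exit = min(fold_idx[-1] + 1, len(top) - 1)
        fold = top[i_entry: i_exit + 1]
        # the fold endpoints are the flat tangency points at y = -depth; the
        # crown runs are horizontal extensions sized to the requested length
        fold_len = _polyline_length(fold)
        crown_run = 0.5 * (p.crown_to_crown_path_length - fold_len)
        if crown_run <= 0.0:
            raise GeometryError(
                f"crown_to_crown_path_length {p.crown_to_crown_path_length} shorter "
                f"than the fold arc length {fold_len:.2f}"
            )
        x_start = fold[0, 0] - crown_run
        x_end = fold[-1, 0] + crown_run
        if x_start < bx0 + depth + 0.5 or x_end > bx1 - depth - 0.5:
            raise GeometryError("domain too narrow for the requested path length; "
                                "increase x_half_extent")
        left = np.stack(
            [np.linspace(x_start, fold[0, 0], 64, endpoint=False),
             np.full(64, -depth)], axis=1)
        right = np.stack(
            [np.linspace(fold[-1, 0], x_end, 65)[1:],
             np.full(64, -depth)], axis=1)
        path = CorticalPath(np.vstack([left, fold, right]))
        self._path_cache[depth] = path
        return path

    def depth_point(self, s: float, target_depth: float,
                    path: CorticalPath | None = None) -> np.ndarray:
        """Cross-section point at arc position ``s`` moved to ``target_depth``.

        Root-finds the signed-depth function along the local path normal, so
        it stays correct where normal offsets are not exact (lip arcs).
        """
        if path is None:
            path = self.cortical_path()
        q = path.sample([s])[0]
        n = path.inward_normal([s])[0]

        def f(u: float) -> float:
            return float(self.depth([q + u * n])[0]) - target_depth

        lo, hi = -self.params.gm_thickness, self.params.gm_thickness
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0.0:  # widen once before giving up
            lo, hi = 2.0 * lo, 2.0 * hi
            flo, fhi = f(lo), f(hi)
            if flo * fhi > 0.0:
                raise GeometryError(f"cannot reach depth {target_depth} at s={s}")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if f(mid) * flo <= 0.0:
                hi = mid
            else:
                lo = mid
                flo = f(lo)
        return q + 0.5 * (lo + hi) * n

    # -- misc ---------------------------------------------------------------

    def analytic_volume(self) -> float:
        """Volume of the meshed domain box (the tissue labels partition it)."""
        (x0, x1), (y0, y1), (z0, z1) = self.bounds
        return (x1 - x0) * (y1 - y0) * (z1 - z0)

    @property
    def active_electrode(self) -> ElectrodeSpec | None:
        for e in self.electrodes:
            if e.role == "active":
                return e
        return None

    def copy(self) -> "HeadGeometry":
        g = HeadGeometry(self.params, self.kind)
        g.electrodes = list(self.electrodes)
        return g


def build_slab_geometry(params: SlabParams | None = None) -> HeadGeometry:
    """Mirror-symmetric extruded slab with a single sulcal fold at x = 0."""
    params = params or SlabParams()
    if isinstance(params, AsymmetricParams):
        raise ParameterError("use build_asymmetric_geometry for AsymmetricParams")
    return HeadGeometry(params, kind="slab")


def build_asymmetric_geometry(params: AsymmetricParams | None = None) -> HeadGeometry:
    """Folded surrogate with unequal banks (stand-in for a realistic model)."""
    params = params or AsymmetricParams()
    if not isinstance(params, AsymmetricParams):
        params = AsymmetricParams(**dataclasses.asdict(params))
    return HeadGeometry(params, kind="asymmetric")


# --------------------------------------------------------------------------
# electrodes
# --------------------------------------------------------------------------


def place_electrodes(geom: HeadGeometry,
                     specs: Sequence[ElectrodeSpec]) -> HeadGeometry:
    """Embed disc electrodes (plus insulating substrate) below the dura.

    Raises :class:`PlacementError` on overlapping discs or an active-return
    separation below 10 mm.
    """
    specs = list(specs)
    (x0, x1), _, (z0, z1) = geom.bounds
    for spec in specs:
        if not (x0 < spec.center_x < x1 and z0 < spec.center_z < z1):
            raise PlacementError(
                f"electrode centre ({spec.center_x}, {spec.center_z}) does not "
                "project onto the subdural surface"
            )
        if spec.thickness + spec.substrate_thickness > geom.params.csf_thickness:
            raise PlacementError("electrode + substrate thicker than the CSF gap")
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            d = float(np.hypot(a.center_x - b.center_x, a.center_z - b.center_z))
            if d < a.radius + b.radius:
                raise PlacementError(
                    f"electrodes overlap: centre distance {d:.2f} mm < radii sum "
                    f"{a.radius + b.radius:.2f} mm"
                )
            if {a.role, b.role} == {"active", "return"} and d < 10.0:
                raise PlacementError(
                    f"active-return separation {d:.2f} mm violates the 10 mm minimum"
                )
    out = geom.copy()
    out.electrodes = specs
    return out


def default_electrode_pair(geom: HeadGeometry, separation: float = 13.0,
                           centered: bool = False, **kwargs) -> list[ElectrodeSpec]:
    """Active/return discs over the crown, separated along the gyral axis.

    With ``centered=False`` the pair sits over the middle of the
    electrode-side crown run; ``centered=True`` puts it on the fold midplane
    (the configuration used for mirror-symmetry checks).
    """
    if centered:
        x_c = 0.0
    else:
        path = geom.cortical_path()
        rm = label_regions(geom)
        s_mid = 0.5 * (0.0 + rm.s_lip - rm.bands.lip_halfwidth)
        x_c = float(path.sample([s_mid])[0][0])
    half = 0.5 * separation
    return [
        ElectrodeSpec(center_x=x_c, center_z=-half, role="active", **kwargs),
        ElectrodeSpec(center_x=x_c, center_z=+half, role="return", **kwargs),
    ]


# --------------------------------------------------------------------------
# region labelling
# --------------------------------------------------------------------------


def label_regions(geom: HeadGeometry,
                  active_electrode: ElectrodeSpec | None = None,
                  bands: RegionBands | None = None) -> RegionMap:
    """Partition the cortical path into C/L/B/BS/OB/OL/OC arc-length bands.

    The crown (C) is the electrode-side crown run; landmark arc positions are
    the projections of the two pial lip corners and the deepest fold point.
    """
    bands = bands or RegionBands()
    path = geom.cortical_path()
    p = geom.params
    s_lip = float(path.project([geom.lip_points[0]])[0])
    s_bottom = float(path.project([[0.0, -p.sulcal_depth]])[0])
    s_lip_opp = float(path.project([geom.lip_points[1]])[0])
    if geom.kind == "slab":
        # landmarks are exactly symmetric; snap them so the region bands are
        # too (projection onto the densified path is only grid-accurate)
        s_bottom = 0.5 * path.length
        s_lip_opp = path.length - s_lip
    return RegionMap(path, s_lip, s_bottom, s_lip_opp, bands)


# --------------------------------------------------------------------------
# meshing
# --------------------------------------------------------------------------

#: alternating five-tet decomposition, parity 0: corner vertex offsets of the
#: four corner tets plus the central tet {000, 110, 101, 011}; parity 1 is
#: its mirror image in u.  Alternating parities make the split conforming
#: across faces and exactly mirror-symmetric for grids with an even cell
#: count along the reflection axis.
_FIVE_TETS = {
    0: [((1, 0, 0), (0, 0, 0), (1, 1, 0), (1, 0, 1)),
        ((0, 1, 0), (0, 0, 0), (1, 1, 0), (0, 1, 1)),
        ((0, 0, 1), (0, 0, 0), (1, 0, 1), (0, 1, 1)),
        ((1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
        ((0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1))],
    1: [((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)),
        ((1, 1, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)),
        ((1, 0, 1), (1, 0, 0), (0, 0, 1), (1, 1, 1)),
        ((0, 1, 1), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
        ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1))],
}

BOUNDARY_TAGS = ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax")


@dataclass
class Mesh:
    """Labelled tetrahedral mesh on a graded tensor-product grid."""

    nodes: np.ndarray  # (n, 3) mm
    elements: np.ndarray  # (m, 4) node ids, positive orientation
    tissue: np.ndarray  # (m,) Tissue codes
    contact: np.ndarray  # (m,) electrode contact index, 0 = none
    facets: dict  # tag -> (k, 3) node ids on the exterior
    grid: tuple  # (gx, gy, gz) 1D coordinate arrays
    geometry: HeadGeometry | None = None
    #: contact index -> electrode role, for meshes loaded without geometry
    contact_roles: dict | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        a = self.nodes[self.elements[:, 1]] - self.nodes[self.elements[:, 0]]
        b = self.nodes[self.elements[:, 2]] - self.nodes[self.elements[:, 0]]
        c = self.nodes[self.elements[:, 3]] - self.nodes[self.elements[:, 0]]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def quality(self) -> np.ndarray:
        """Radius-ratio quality measure in (0, 1] (1 = regular tetrahedron)."""
        n = self.nodes
        e = self.elements
        vol = self.element_volumes()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        edge2 = np.stack(
            [np.sum((n[e[:, i]] - n[e[:, j]]) ** 2, axis=1) for i, j in pairs]
        )
        lmax = np.sqrt(edge2.max(axis=0))
        faces = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        area = np.zeros(len(e))
        for i, j, k in faces:
            area += 0.5 * np.linalg.norm(
                np.cross(n[e[:, j]] - n[e[:, i]], n[e[:, k]] - n[e[:, i]]), axis=1
            )
        inradius = 3.0 * vol / area
        return 2.0 * np.sqrt(6.0) * inradius / lmax

    # -- point location / interpolation ------------------------------------

    def locate(self, points: np.ndarray):
        """Containing-tet vertex ids and barycentric weights per point."""
        from .errors import SamplingError

        points = np.atleast_2d(np.asarray(points, float))
        gx, gy, gz = self.grid
        eps = 1e-9
        for axis, g in enumerate((gx, gy, gz)):
            bad = (points[:, axis] < g[0] - eps) | (points[:, axis] > g[-1] + eps)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise SamplingError(
                    f"point {points[i]} outside the meshed domain on axis {axis}"
                )
        idx = []
        frac = []
        for axis, g in enumerate((gx, gy, gz)):
            i = np.clip(np.searchsorted(g, points[:, axis], side="right") - 1,
                        0, len(g) - 2)
            idx.append(i)
            frac.append((points[:, axis] - g[i]) / (g[i + 1] - g[i]))
        ix, iy, iz = idx
        u, v, w3 = frac
        parity = (ix + iy + iz) % 2
        npts = len(points)
        weights = np.empty((npts, 4))
        offsets = np.empty((npts, 4, 3), dtype=np.int64)

        # region selectors and barycentric weights of the alternating
        # five-tet split, per parity
        def fill(mask, verts, wcols):
            if not mask.any():
                return
            offsets[mask] = np.asarray(verts, dtype=np.int64)[None, :, :]
            weights[mask] = np.stack(wcols, axis=1)[mask]

        one = np.ones(npts)
        p0 = parity == 0
        a0 = p0 & (u - v - w3 >= 0)
        b0 = p0 & (v - u - w3 >= 0) & ~a0
        c0 = p0 & (w3 - u - v >= 0) & ~a0 & ~b0
        d0 = p0 & (u + v + w3 >= 2) & ~a0 & ~b0 & ~c0
        e0 = p0 & ~a0 & ~b0 & ~c0 & ~d0
        fill(a0, ((1, 0, 0), (0, 0, 0), (1, 1, 0), (1, 0, 1)),
             (u - v - w3, one - u, v, w3))
        fill(b0, ((0, 1, 0), (0, 0, 0), (1, 1, 0), (0, 1, 1)),
             (v - u - w3, one - v, u, w3))
        fill(c0, ((0, 0, 1), (0, 0, 0), (1, 0, 1), (0, 1, 1)),
             (w3 - u - v, one - w3, u, v))
        fill(d0, ((1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
             (u + v + w3 - 2.0, one - w3, one - v, one - u))
        fill(e0, ((0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
             (one - 0.5 * (u + v + w3), 0.5 * (u + v - w3),
              0.5 * (u - v + w3), 0.5 * (-u + v + w3)))

        p1 = ~p0
        a1 = p1 & (one - u - v - w3 >= 0)
        b1 = p1 & (u + v - w3 >= 1) & ~a1
        c1 = p1 & (u + w3 - v >= 1) & ~a1 & ~b1
        d1 = p1 & (v + w3 - u >= 1) & ~a1 & ~b1 & ~c1
        e1 = p1 & ~a1 & ~b1 & ~c1 & ~d1
        fill(a1, ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)),
             (one - u - v - w3, u, v, w3))
        fill(b1, ((1, 1, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)),
             (u + v - w3 - 1.0, one - v, one - u, w3))
        fill(c1, ((1, 0, 1), (1, 0, 0), (0, 0, 1), (1, 1, 1)),
             (u + w3 - v - 1.0, one - w3, one - u, v))
        fill(d1, ((0, 1, 1), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
             (v + w3 - u - 1.0, one - w3, one - v, u))
        fill(e1, ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
             (0.5 * (1.0 + u - v - w3), 0.5 * (1.0 - u + v - w3),
              0.5 * (1.0 - u - v + w3), 0.5 * (u + v + w3 - 1.0)))

        ny, nz = len(gy), len(gz)
        corner = ((ix[:, None] + offsets[:, :, 0]) * ny
                  + (iy[:, None] + offsets[:, :, 1])) * nz \
            + (iz[:, None] + offsets[:, :, 2])
        return corner, weights

    def interpolate(self, nodal: np.ndarray, points: np.ndarray) -> np.ndarray:
        corner, w = self.locate(points)
        return np.sum(nodal[corner] * w, axis=1)


def _graded_axis(lo: float, hi: float, fine_lo: float, fine_hi: float,
                 h: float, coarse_factor: float, growth: float = 1.35) -> np.ndarray:
    """1D grid, spacing ``h`` inside [fine_lo, fine_hi], geometric outside."""
    fine_lo, fine_hi = max(lo, fine_lo), min(hi, fine_hi)
    n_fine = max(1, int(np.ceil((fine_hi - fine_lo) / h)))
    coords = list(np.linspace(fine_lo, fine_hi, n_fine + 1))
    hmax = coarse_factor * h
    step = h
    while coords[-1] < hi - 1e-9:
        step = min(step * growth, hmax, hi - coords[-1])
        coords.append(coords[-1] + step)
    coords[-1] = hi
    step = h
    while coords[0] > lo + 1e-9:
        step = min(step * growth, hmax, coords[0] - lo)
        coords.insert(0, coords[0] - step)
    coords[0] = lo
    return np.array(coords)


def generate_mesh(geom: HeadGeometry, resolution: float = 1.0,
                  coarse_factor: float = 4.0,
                  quality_floor: float = 0.05) -> Mesh:
    """Labelled tet mesh of the domain box, graded fine around the fold.

    Each grid cell takes the tissue of its centre and is split into six
    Kuhn tetrahedra, which makes point location and linear interpolation
    exact and cheap.  Exterior boundary facets are tagged by box side.
    """
    if resolution <= 0.0:
        raise ParameterError("mesh resolution must be positive")
    p = geom.params
    (x0, x1), (y0, y1), (z0, z1) = geom.bounds

    slot_xs = np.asarray(geom.slot.exterior.coords)[:, 0]
    fine_x = (min(slot_xs.min(), -p.sulcus_half_width) - 4.0 - resolution,
              slot_xs.max() + 4.0 + resolution)
    path = geom.cortical_path()
    fine_x = (min(fine_x[0], path.points[:, 0].min() - 2.0),
              max(fine_x[1], path.points[:, 0].max() + 2.0))
    fine_y = (-(p.sulcal_depth + p.gm_thickness + 2.0),
              p.csf_thickness + p.dura_thickness)
    if geom.electrodes:
        zc = [e.center_z for e in geom.electrodes]
        zr = max(e.radius for e in geom.electrodes)
        fine_z = (min(zc) - zr - 3.0, max(zc) + zr + 3.0)
    else:
        fine_z = (-6.0, 6.0)

    # symmetric x grid: build the positive half and mirror it (even cell
    # count in x keeps the alternating tet split exactly mirror-symmetric);
    # the slot walls at +-sulcus_half_width become grid planes so the fold
    # width does not drift with resolution
    half = _graded_axis(0.0, x1, 0.0, max(abs(fine_x[0]), abs(fine_x[1])),
                        resolution, coarse_factor)
    hw = p.sulcus_half_width
    half = np.unique(np.concatenate([half, [hw]]))
    half = half[np.concatenate([[True], np.diff(half) > 0.2 * resolution])]
    if not np.any(np.abs(half - hw) < 1e-9):
        half = np.sort(np.append(half[np.abs(half - hw) > 0.2 * resolution],
                                 hw))
    half[0], half[-1] = 0.0, x1
    gx = np.concatenate([-half[::-1], half[1:]])
    gy = _graded_axis(y0, y1, *fine_y, resolution, coarse_factor)
    # horizontal tissue interfaces (and electrode/substrate planes) must be
    # grid planes or thin layers vanish at coarse resolutions
    breaks = [0.0, p.csf_thickness, p.csf_thickness + p.dura_thickness,
              p.csf_thickness + p.dura_thickness + p.skull_thickness]
    for e in geom.electrodes:
        breaks += [e.thickness, e.thickness + e.substrate_thickness]
    gy = np.unique(np.concatenate([gy, np.asarray(breaks)]))
    gy = gy[(gy >= y0 - 1e-9) & (gy <= y1 + 1e-9)]
    gy = gy[np.concatenate([[True], np.diff(gy) > 0.2 * resolution])]
    for b in breaks:  # keep the interfaces themselves after dedup
        if y0 < b < y1 and not np.any(np.abs(gy - b) < 1e-9):
            gy = np.sort(np.append(gy[np.abs(gy - b) > 0.2 * resolution], b))
    gz = _graded_axis(z0, z1, *fine_z, resolution, coarse_factor)

    nx, ny, nz = len(gx), len(gy), len(gz)
    if (nx - 1) * (ny - 1) * (nz - 1) > 4_000_000:
        raise MeshError(
            f"grid {nx - 1}x{ny - 1}x{nz - 1} cells exceeds the element budget; "
            "coarsen the resolution"
        )
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    cx = 0.5 * (gx[:-1] + gx[1:])
    cy = 0.5 * (gy[:-1] + gy[1:])
    cz = 0.5 * (gz[:-1] + gz[1:])
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    centers = np.stack([CX.ravel(), CY.ravel(), CZ.ravel()], axis=1)
    cell_tissue = geom.tissue_at(centers)
    cell_contact = geom.contact_at(centers)

    # corner ids of every cell
    I, J, K = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    n_cells = len(I)
    parity = (I + J + K) % 2
    elems = np.empty((n_cells, 5, 4), dtype=np.int64)
    for p in (0, 1):
        sel = parity == p
        for t, verts in enumerate(_FIVE_TETS[p]):
            for vslot, (di, dj, dk) in enumerate(verts):
                elems[sel, t, vslot] = nid(I[sel] + di, J[sel] + dj,
                                           K[sel] + dk)
    elements = elems.reshape(-1, 4)
    tissue = np.repeat(cell_tissue, 5)
    contact = np.repeat(cell_contact, 5)

    facets = {}
    for tag, axis, side in (
        ("xmin", 0, 0), ("xmax", 0, -1),
        ("ymin", 1, 0), ("ymax", 1, -1),
        ("zmin", 2, 0), ("zmax", 2, -1),
    ):
        g = (gx, gy, gz)[axis]
        value = g[side]
        on_plane = np.abs(nodes[:, axis] - value) < 1e-9
        mask = on_plane[elements]  # (m, 4)
        three = mask.sum(axis=1) == 3
        if not three.any():
            facets[tag] = np.empty((0, 3), dtype=np.int64)
            continue
        sel = elements[three]
        msel = mask[three]
        tri = sel[msel].reshape(-1, 3)
        facets[tag] = tri

    mesh = Mesh(nodes=nodes, elements=elements, tissue=tissue, contact=contact,
                facets=facets, grid=(gx, gy, gz), geometry=geom)
    qmin = float(mesh.quality().min())
    if qmin < quality_floor:
        raise MeshError(f"minimum element quality {qmin:.3f} below floor "
                        f"{quality_floor}; reduce grid grading")
    return mesh
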