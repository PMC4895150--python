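"""Parametric L3/L5 pyramidal morphologies, axon bending and SWC round-trip.

Published cat-cortex morphometry is not reproduced point-for-point; a
stylized pyramidal template (documented section lengths/diameters, all
configurable) preserves the structural distinctions that matter here: an
apical trunk toward the pia, a myelinated axon with an initial segment,
nodes and internodes, L3 axons confined to gray matter and L5 axons crossing
into white matter where they bend toward the fiber direction.  SWC import is
available for substituting real reconstructions.

Coordinates are mm (soma centre at the origin, +y toward the pia in the
local frame); diameters are um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import FormatError, ParameterError

__all__ = [
    "Section",
    "NeuronMorphology",
    "CompartmentSet",
    "MorphologyParams",
    "build_morphology",
    "bend_axon_at_boundary",
    "discretize",
    "read_swc",
    "write_swc",
]

SECTION_TYPES = ("soma", "axon", "initial_segment", "apical", "basal", "node")
_SWC_CODE = {"soma": 1, "axon": 2, "basal": 3, "apical": 4,
             "initial_segment": 5, "node": 6}
_SWC_TYPE = {v: k for k, v in _SWC_CODE.items()}

#: lengthening applied to every neurite path to fit human cortical dimensions
LENGTHEN_FACTOR = 1.6


@dataclass
class Section:
    """Unbranched neurite piece; ``points`` includes the attachment point."""

    name: str
    stype: str
    points: np.ndarray  # (n, 3) mm
    diameters: np.ndarray  # (n,) um
    parent: int  # section index, -1 for the root soma
    parent_point: int  # index into the parent's points (0 or -1 typically)

    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class NeuronMorphology:
    """Connected tree of sections rooted at the soma."""

    sections: list
    layer: str  # "L3" | "L5"
    #: axon arc range occupied by the bend inserted at the GM/WM boundary
    bend_range: tuple | None = None

    def section_by_name(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    def axon_sections(self) -> list:
        return [s for s in self.sections
                if s.stype in ("axon", "initial_segment", "node")]

    def total_length(self, stype: str | None = None) -> float:
        return sum(s.length() for s in self.sections
                   if stype is None or s.stype == stype)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "NeuronMorphology":
        """Rigidly place the morphology: world = R @ local + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        secs = [replace(s, points=s.points @ R.T + t,
                        diameters=s.diameters.copy())
                for s in self.sections]
        return NeuronMorphology(secs, self.layer, self.bend_range)

    def extent_y(self) -> tuple:
        ys = np.concatenate([s.points[:, 1] for s in self.sections])
        return float(ys.min()), float(ys.max())


@dataclass(frozen=True)
class MorphologyParams:
    """Base (pre-lengthening) template dimensions, lengths um."""

    soma_length: float
    soma_diameter: float
    apical_length: float
    apical_diameter: float
    tuft_length: float
    tuft_diameter: float
    basal_length: float
    basal_diameter: float
    initial_segment_length: float
    initial_segment_diameter: float
    axon_length: float
    axon_diameter: float
    node_length: float = 2.0
    internode_length: float = 100.0
    lengthen: float = LENGTHEN_FACTOR

    @classmethod
    def defaults(cls, layer: str) -> "MorphologyParams":
        if layer == "L5":
            # long corticofugal axon: the terminal ends deep in the white
            # matter, far from the stimulation field
            return cls(soma_length=20.0, soma_diameter=20.0,
                       apical_length=1100.0, apical_diameter=4.0,
                       tuft_length=150.0, tuft_diameter=1.5,
                       basal_length=150.0, basal_diameter=2.0,
                       initial_segment_length=30.0,
                       initial_segment_diameter=1.5,
                       axon_length=5000.0, axon_diameter=1.5)
        if layer == "L3":
            # intracortical axon: terminates within the gray matter, just
            # above the GM/WM boundary
            return cls(soma_length=15.0, soma_diameter=15.0,
                       apical_length=380.0, apical_diameter=3.0,
                       tuft_length=120.0, tuft_diameter=1.2,
                       basal_length=120.0, basal_diameter=1.5,
                       initial_segment_length=30.0,
                       initial_segment_diameter=1.2,
                       axon_length=1000.0, axon_diameter=1.2)
        raise ParameterError(f"unknown layer {layer!r}")

    @classmethod
    def from_yaml(cls, path: str, layer: str) -> "MorphologyParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = cls.defaults(layer)
        return replace(base, **data.get(layer, {}))


def _segment(start, direction, length_mm, n=None, step=0.025):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    if n is None:
        n = max(2, int(np.ceil(length_mm / step)) + 1)
    t = np.linspace(0.0, length_mm, n)
    return np.asarray(start, float)[None, :] + t[:, None] * direction[None, :]


def build_morphology(layer: str, params: MorphologyParams | None = None
                     ) -> NeuronMorphology:
    """Stylized pyramidal cell in local coordinates (apical along +y).

    Every neurite path length equals ``lengthen`` (default 1.6) times its
    base template length.
    """
    if layer not in ("L3", "L5"):
        raise ParameterError(f"unknown layer {layer!r}")
    p = params or MorphologyParams.defaults(layer)
    k = p.lengthen
    um = 1e-3  # template lengths are um, coordinates mm

    secs: list[Section] = []
    half = 0.5 * p.soma_length * um
    soma_pts = np.array([[0.0, -half, 0.0], [0.0, half, 0.0]])
    secs.append(Section("soma", "soma", soma_pts,
                        np.full(2, p.soma_diameter), -1, -1))

    top = soma_pts[-1]
    bottom = soma_pts[0]
    apical_len = k * p.apical_length * um
    apical_pts = _segment(top, (0, 1, 0), apical_len)
    n_ap = len(apical_pts)
    secs.append(Section("apical", "apical", apical_pts,
                        np.linspace(p.apical_diameter,
                                    0.6 * p.apical_diameter, n_ap), 0, -1))
    ap_i = len(secs) - 1
    # branch directions are mirror-symmetric in local x (so slab populations
    # stay exactly achiral) but not axisymmetric about the apical axis
    tuft_len = k * p.tuft_length * um
    for i, d in enumerate(((0.5, 0.8, 0.33), (-0.5, 0.8, 0.33))):
        pts = _segment(apical_pts[-1], d, tuft_len)
        secs.append(Section(f"tuft{i}", "apical", pts,
                            np.full(len(pts), p.tuft_diameter), ap_i, -1))

    basal_len = k * p.basal_length * um
    for i, d in enumerate(((0.8, -0.45, 0.4), (-0.8, -0.45, 0.4),
                           (0.0, -0.45, -0.9))):
        pts = _segment(bottom, d, basal_len)
        secs.append(Section(f"basal{i}", "basal", pts,
                            np.full(len(pts), p.basal_diameter), 0, 0))

    is_len = k * p.initial_segment_length * um
    is_pts = _segment(bottom, (0, -1, 0), is_len)
    secs.append(Section("initial_segment", "initial_segment", is_pts,
                        np.full(len(is_pts), p.initial_segment_diameter), 0, 0))
    prev = len(secs) - 1

    # myelinated axon: alternating internodes and nodes whose lengths sum to
    # exactly the lengthened shaft length, always ending on a node (the
    # excitable axon terminal)
    shaft_len = k * p.axon_length * um
    inter = k * p.internode_length * um
    node = k * p.node_length * um
    plan = []
    rem = shaft_len
    while rem > 1e-12:
        if rem <= inter + node:
            if rem > node:
                plan.append(("axon", rem - node))
                rem = node
            plan.append(("node", rem))
            rem = 0.0
        else:
            plan.append(("axon", inter))
            plan.append(("node", node))
            rem -= inter + node
    cursor = is_pts[-1]
    counts = {"axon": 0, "node": 0}
    for stype, seg_len in plan:
        n = 2 if stype == "node" else None
        pts = _segment(cursor, (0, -1, 0), seg_len, n=n)
        name = ("internode" if stype == "axon" else "node")
        secs.append(Section(f"{name}{counts[stype]}", stype, pts,
                            np.full(len(pts), p.axon_diameter), prev, -1))
        counts[stype] += 1
        prev = len(secs) - 1
        cursor = pts[-1]
    return NeuronMorphology(secs, layer)


# --------------------------------------------------------------------------
# axon bending at the GM/WM boundary
# --------------------------------------------------------------------------


def _axon_chain(m: NeuronMorphology):
    """Indices of axonal sections in root-to-terminal order."""
    idx = [i for i, s in enumerate(m.sections)
           if s.stype in ("initial_segment", "axon", "node")]
    return idx


def bend_axon_at_boundary(m: NeuronMorphology, crossing_test,
                          fiber_direction, bend_radius: float = 0.3
                          ) -> NeuronMorphology:
    """Deflect the axon beyond the GM/WM boundary toward the fiber direction.

    ``crossing_test(points) -> bool`` flags points beyond the boundary (in
    WM); ``fiber_direction`` is the WM fiber axis the axon turns into.  Total
    axon arc length is preserved exactly (points are re-laid along an arc of
    the given radius followed by a straight run).  An infinite/None radius or
    an axon that never reaches the boundary leaves the morphology unchanged.
    """
    if bend_radius is None or not np.isfinite(bend_radius):
        return m
    if bend_radius <= 0.0:
        raise ParameterError("bend radius must be positive")
    chain = _axon_chain(m)
    pts_list = [m.sections[i].points for i in chain]
    counts = [len(p) for p in pts_list]
    allpts = np.vstack(pts_list)
    seg = np.linalg.norm(np.diff(allpts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    beyond = np.asarray(crossing_test(allpts), bool)
    if not beyond.any():
        warnings.warn("axon does not reach the GM/WM boundary; bend skipped")
        return m
    j = int(np.argmax(beyond))
    if j == 0:
        warnings.warn("axon starts beyond the GM/WM boundary; bend skipped")
        return m
    s_cross = arc[j - 1] + 0.5 * (arc[j] - arc[j - 1])
    # local tangent and crossing point
    t0 = allpts[j] - allpts[j - 1]
    t0 = t0 / np.linalg.norm(t0)
    P = allpts[j - 1] + (s_cross - arc[j - 1]) * t0

    f = np.asarray(fiber_direction, float)
    f = f / np.linalg.norm(f)
    if np.dot(f, t0) < 0.0:
        f = -f  # continue forward along the fiber axis
    cosang = np.clip(np.dot(t0, f), -1.0, 1.0)
    psi = float(np.arccos(cosang))
    if psi < 1e-9:
        return m
    n = f - cosang * t0
    n = n / np.linalg.norm(n)
    R = bend_radius
    arc_len = R * psi
    center = P + R * n

    def remap(s: np.ndarray) -> np.ndarray:
        u = s - s_cross
        out = np.empty((len(u), 3))
        on_arc = u <= arc_len
        ua = u[on_arc] / R
        out[on_arc] = (center[None, :]
                       - R * np.cos(ua)[:, None] * n[None, :]
                       + R * np.sin(ua)[:, None] * t0[None, :])
        rest = ~on_arc
        end = center - R * np.cos(psi) * n + R * np.sin(psi) * t0
        out[rest] = end[None, :] + (u[rest] - arc_len)[:, None] * f[None, :]
        return out

    new_all = allpts.copy()
    sel = arc > s_cross
    new_all[sel] = remap(arc[sel])

    secs = [replace(s, points=s.points.copy()) for s in m.sections]
    offset = 0
    for i, c in zip(chain, counts):
        secs[i].points = new_all[offset: offset + c]
        offset += c
    return NeuronMorphology(secs, m.layer,
                            bend_range=(float(s_cross),
                                        float(s_cross + arc_len)))


def axon_arc_positions(m: NeuronMorphology) -> tuple:
    """(section index -> (start, end) axon arc range) for axonal sections."""
    chain = _axon_chain(m)
    out = {}
    s = 0.0
    for i in chain:
        L = m.sections[i].length()
        out[i] = (s, s + L)
        s += L
    return out, s


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------


@dataclass
class CompartmentSet:
    """Ordered compartments with tree linkage (parent index < index)."""

    centers: np.ndarray  # (n, 3) mm
    lengths: np.ndarray  # (n,) um
    diameters: np.ndarray  # (n,) um
    stypes: np.ndarray  # (n,) object, section type per compartment
    section_index: np.ndarray  # (n,)
    parent: np.ndarray  # (n,) compartment index, -1 for root
    axon_arc: np.ndarray  # (n,) arc position along the axon (mm), nan elsewhere

    @property
    def n(self) -> int:
        return len(self.centers)

    def last_axon_compartment(self) -> int:
        ax = np.flatnonzero(np.isfinite(self.axon_arc))
        return int(ax[np.argmax(self.axon_arc[ax])])


def discretize(m: NeuronMorphology, max_compartment_length: float = 25.0
               ) -> CompartmentSet:
    """Split every section into compartments no longer than the given um."""
    if max_compartment_length <= 0.0:
        raise ParameterError("max compartment length must be positive")
    max_mm = max_compartment_length * 1e-3
    axon_ranges, _ = axon_arc_positions(m)

    centers, lengths, diams, stypes, sec_idx, parents, axarc = \
        [], [], [], [], [], [], []
    first_comp = {}
    last_comp = {}
    comp_at = {}  # (section, point index) -> compartment holding that point

    for si, sec in enumerate(m.sections):
        seg = np.linalg.norm(np.diff(sec.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        L = cum[-1]
        nseg = max(1, int(np.ceil(L / max_mm)))
        edges = np.linspace(0.0, L, nseg + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        pts = np.empty((nseg, 3))
        for a in range(3):
            pts[:, a] = np.interp(mids, cum, sec.points[:, a])
        dmid = np.interp(mids, cum, sec.diameters)

        if sec.parent < 0:
            parent0 = -1
        else:
            pp = sec.parent_point
            key = (sec.parent, pp % len(m.sections[sec.parent].points))
            parent0 = comp_at.get(key, last_comp[sec.parent])

        base = len(centers)
        for c in range(nseg):
            centers.append(pts[c])
            lengths.append((edges[c + 1] - edges[c]) * 1e3)
            diams.append(dmid[c])
            stypes.append(sec.stype)
            sec_idx.append(si)
            parents.append(parent0 if c == 0 else base + c - 1)
            if si in axon_ranges:
                axarc.append(axon_ranges[si][0] + mids[c])
            else:
                axarc.append(np.nan)
        first_comp[si] = base
        last_comp[si] = base + nseg - 1
        # compartments containing the section's endpoints, for attachments
        comp_at[(si, 0)] = base
        comp_at[(si, len(sec.points) - 1)] = base + nseg - 1

    return CompartmentSet(
        centers=np.asarray(centers), lengths=np.asarray(lengths),
        diameters=np.asarray(diams), stypes=np.asarray(stypes, dtype=object),
        section_index=np.asarray(sec_idx), parent=np.asarray(parents),
        axon_arc=np.asarray(axarc),
    )


# --------------------------------------------------------------------------
# SWC
# --------------------------------------------------------------------------


def write_swc(m: NeuronMorphology, path: str) -> None:
    """Standard 7-column SWC, coordinates um, radius um.

    Attachment points shared with the parent section are not duplicated.
    """
    rows = []
    point_ids: dict[tuple, int] = {}  # (section, point index) -> swc id
    next_id = 1
    for si, sec in enumerate(m.sections):
        code = _SWC_CODE[sec.stype]
        npts = len(sec.points)
        if sec.parent < 0:
            start, parent_id = 0, -1
        else:
            start = 1
            pkey = (sec.parent, sec.parent_point
                    % len(m.sections[sec.parent].points))
            parent_id = point_ids[pkey]
            point_ids[(si, 0)] = parent_id
        for i in range(start, npts):
            x, y, z = sec.points[i] * 1e3
            r = 0.5 * sec.diameters[i]
            rows.append((next_id, code, x, y, z, r, parent_id))
            point_ids[(si, i)] = next_id
            parent_id = next_id
            next_id += 1
    with open(path, "w") as fh:
        fh.write("# generated by cortistim (um)\n")
        for r in rows:
            fh.write(f"{r[0]} {r[1]} {r[2]:.6f} {r[3]:.6f} {r[4]:.6f} "
                     f"{r[5]:.6f} {r[6]}\n")


def read_swc(path: str) -> NeuronMorphology:
    """Parse SWC into sections (maximal unbranched same-type runs)."""
    ids, codes, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"SWC line must have 7 columns: {line!r}")
            ids.append(int(parts[0]))
            codes.append(int(parts[1]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
    if not ids:
        raise FormatError("empty SWC file")
    index = {pid: i for i, pid in enumerate(ids)}
    for c in codes:
        if c not in _SWC_TYPE:
            raise FormatError(f"unknown SWC type code {c}")
    xyz = np.asarray(xyz) * 1e-3  # um -> mm
    radii = np.asarray(radii)

    parent_idx = np.empty(len(ids), dtype=np.int64)
    for i, p in enumerate(parents):
        if p == -1:
            parent_idx[i] = -1
        elif p in index:
            parent_idx[i] = index[p]
        else:
            raise FormatError(f"SWC parent id {p} not defined")
    # cycle check: walking up from every node must terminate
    for i in range(len(ids)):
        seen = set()
        j = i
        while j != -1:
            if j in seen:
                raise FormatError("SWC parent links contain a cycle")
            seen.add(j)
            j = int(parent_idx[j])

    children = {}
    for i, p in enumerate(parent_idx):
        children.setdefault(int(p), []).append(i)
    n_children = {i: len(children.get(i, [])) for i in range(len(ids))}

    sections: list[Section] = []
    sec_of_point: dict[int, tuple] = {}
    roots = children.get(-1, [])
    if len(roots) != 1:
        raise FormatError("SWC must have exactly one root")
    root = roots[0]

    def emit(run: list, stype: str) -> int:
        head = run[0]
        p = int(parent_idx[head])
        if p == -1:
            parent_sec, parent_pt = -1, -1
            pts = xyz[run]
            dia = 2.0 * radii[run]
            offset = 0
        else:
            parent_sec, parent_pt = sec_of_point[p]
            pts = np.vstack([xyz[[p]], xyz[run]])
            dia = np.concatenate([[2.0 * radii[p]], 2.0 * radii[run]])
            offset = 1
        if len(pts) == 1:  # single-point soma -> zero-length stub
            pts = np.vstack([pts, pts])
            dia = np.concatenate([dia, dia])
        si = len(sections)
        sections.append(Section(f"{stype}{si}", stype, pts, dia,
                                parent_sec, parent_pt))
        for local, gi in enumerate(run):
            sec_of_point[gi] = (si, local + offset)
        return si

    # the soma chain is one section regardless of branch points on it
    stack: list[int] = []
    if codes[root] == 1:
        soma_run = [root]
        while True:
            soma_kids = [k for k in children.get(soma_run[-1], [])
                         if codes[k] == 1]
            if len(soma_kids) == 1:
                soma_run.append(soma_kids[0])
            else:
                break
        emit(soma_run, "soma")
        for gi in soma_run:
            stack.extend(k for k in children.get(gi, []) if codes[k] != 1)
    else:
        stack.append(root)

    while stack:
        head = stack.pop()
        run = [head]
        while True:
            kids = children.get(run[-1], [])
            if len(kids) == 1 and codes[kids[0]] == codes[run[-1]]:
                run.append(kids[0])
            else:
                break
        emit(run, _SWC_TYPE[codes[head]])
        stack.extend(children.get(run[-1], []))

    layer = "L5" if any(s.stype in ("axon", "node") for s in sections) else "L3"
    return NeuronMorphology(sections, layer)
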