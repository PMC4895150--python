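"""Serialization of labelled tet meshes: Gmsh MSH v4.1 (ASCII) and legacy VTK.

Only the dialect written here is read back (one node block, one element block
per discrete volume entity / tissue label, triangle blocks per boundary tag).
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .scenario_geometry import BOUNDARY_TAGS, Mesh, Tissue

#: physical tags for boundary surfaces start above the tissue codes;
#: electrode contact bodies start above the surface tags
_SURFACE_TAG_OFFSET = 100
_CONTACT_TAG_OFFSET = 200


def write_msh(mesh: Mesh, path: str) -> None:
    """Write the mesh as Gmsh MSH v4.1 with physical groups per tissue.

    Electrode contact bodies become additional volume groups named
    ``contact<i>_<role>`` so that a mesh loaded from disk keeps its drive
    topology.
    """
    tissues = sorted(int(t) for t in np.unique(mesh.tissue))
    surf_tags = {tag: _SURFACE_TAG_OFFSET + i for i, tag in enumerate(BOUNDARY_TAGS)}
    used_surfs = [t for t in BOUNDARY_TAGS if len(mesh.facets.get(t, ())) > 0]
    contacts = sorted(int(c) for c in np.unique(mesh.contact) if c != 0)
    roles = {}
    if mesh.geometry is not None:
        roles = {i: e.role for i, e in enumerate(mesh.geometry.electrodes, 1)}
    elif mesh.contact_roles:
        roles = dict(mesh.contact_roles)

    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    lines.append(str(len(tissues) + len(used_surfs) + len(contacts)))
    for t in tissues:
        lines.append(f'3 {t} "{Tissue(t).name.lower()}"')
    for tag in used_surfs:
        lines.append(f'2 {surf_tags[tag]} "{tag}"')
    for c in contacts:
        role = roles.get(c, "active" if c == 1 else "return")
        lines.append(f'3 {_CONTACT_TAG_OFFSET + c} "contact{c}_{role}"')
    lines.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bbox = f"{lo[0]} {lo[1]} {lo[2]} {hi[0]} {hi[1]} {hi[2]}"
    lines.append("$Entities")
    lines.append(f"0 0 {len(used_surfs)} {len(tissues) + len(contacts)}")
    for tag in used_surfs:
        lines.append(f"{surf_tags[tag]} {bbox} 1 {surf_tags[tag]} 0")
    for t in tissues:
        lines.append(f"{t} {bbox} 1 {t} 0")
    for c in contacts:
        tag = _CONTACT_TAG_OFFSET + c
        lines.append(f"{tag} {bbox} 1 {tag} 0")
    lines.append("$EndEntities")

    n = mesh.n_nodes
    first_vol = tissues[0]
    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"3 {first_vol} 0 {n}")
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in mesh.nodes)
    lines.append("$EndNodes")

    blocks = []
    eid = 1
    for tag in used_surfs:
        tris = mesh.facets[tag]
        body = []
        for tri in tris:
            body.append(f"{eid} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}")
            eid += 1
        blocks.append((f"2 {surf_tags[tag]} 2 {len(tris)}", body))
    for t in tissues:
        sel = np.flatnonzero((mesh.tissue == t) & (mesh.contact == 0))
        body = []
        for e in mesh.elements[sel]:
            body.append(f"{eid} {e[0] + 1} {e[1] + 1} {e[2] + 1} {e[3] + 1}")
            eid += 1
        blocks.append((f"3 {t} 4 {len(sel)}", body))
    for c in contacts:
        sel = np.flatnonzero(mesh.contact == c)
        body = []
        for e in mesh.elements[sel]:
            body.append(f"{eid} {e[0] + 1} {e[1] + 1} {e[2] + 1} {e[3] + 1}")
            eid += 1
        blocks.append((f"3 {_CONTACT_TAG_OFFSET + c} 4 {len(sel)}", body))

    total = eid - 1
    lines.append("$Elements")
    lines.append(f"{len(blocks)} {total} 1 {total}")
    for header, body in blocks:
        lines.append(header)
        lines.extend(body)
    lines.append("$EndElements")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path: str) -> Mesh:
    """Read a mesh written by :func:`write_msh`.

    The structured-grid acceleration data is reconstructed from the unique
    node coordinates (the writer only emits tensor-product grids).
    """
    with open(path) as fh:
        text = fh.read()

    def section(name: str) -> list[str]:
        try:
            start = text.index(f"${name}\n") + len(name) + 2
            end = text.index(f"$End{name}")
        except ValueError as exc:
            raise FormatError(f"missing ${name} section in {path}") from exc
        return text[start:end].strip("\n").split("\n")

    node_lines = section("Nodes")
    num_nodes = int(node_lines[0].split()[1])
    coords = np.loadtxt(node_lines[2 + num_nodes: 2 + 2 * num_nodes], ndmin=2)
    if len(coords) != num_nodes:
        raise FormatError("node count mismatch")

    contact_roles = {}
    for line in section("PhysicalNames")[1:]:
        parts = line.split(None, 2)
        name = parts[2].strip('"')
        if name.startswith("contact"):
            idx, role = name[len("contact"):].split("_", 1)
            contact_roles[int(idx)] = role

    elem_lines = section("Elements")
    n_blocks = int(elem_lines[0].split()[0])
    pos = 1
    tets, tet_tags, tet_contacts, tris, tri_tags = [], [], [], [], []
    for _ in range(n_blocks):
        dim, entity, etype, count = (int(v) for v in elem_lines[pos].split())
        pos += 1
        rows = [elem_lines[pos + i].split() for i in range(count)]
        pos += count
        if etype == 4:
            tets.append(np.array([[int(v) - 1 for v in r[1:5]] for r in rows],
                                 dtype=np.int64).reshape(-1, 4))
            if entity >= _CONTACT_TAG_OFFSET:
                tet_tags.append(np.full(count, int(Tissue.ELECTRODE)))
                tet_contacts.append(np.full(count,
                                            entity - _CONTACT_TAG_OFFSET))
            else:
                tet_tags.append(np.full(count, entity))
                tet_contacts.append(np.zeros(count, dtype=np.int64))
        elif etype == 2:
            tris.append(np.array([[int(v) - 1 for v in r[1:4]] for r in rows],
                                 dtype=np.int64).reshape(-1, 3))
            tri_tags.append(np.full(count, entity))
        else:
            raise FormatError(f"unsupported element type {etype}")
    elements = np.vstack(tets) if tets else np.empty((0, 4), dtype=np.int64)
    tissue = np.concatenate(tet_tags) if tet_tags else np.empty(0, dtype=np.int64)
    contact = (np.concatenate(tet_contacts) if tet_contacts
               else np.empty(0, dtype=np.int64))

    facets = {tag: np.empty((0, 3), dtype=np.int64) for tag in BOUNDARY_TAGS}
    surf_tags = {_SURFACE_TAG_OFFSET + i: tag for i, tag in enumerate(BOUNDARY_TAGS)}
    for tri, tag in zip(tris, tri_tags):
        facets[surf_tags[int(tag[0])]] = tri

    gx = np.unique(coords[:, 0])
    gy = np.unique(coords[:, 1])
    gz = np.unique(coords[:, 2])
    if len(gx) * len(gy) * len(gz) != num_nodes:
        raise FormatError("mesh is not a tensor-product grid")
    return Mesh(nodes=coords, elements=elements,
                tissue=tissue.astype(np.int32),
                contact=contact.astype(np.int32),
                facets=facets, grid=(gx, gy, gz), geometry=None,
                contact_roles=contact_roles or None)


def write_vtk(mesh: Mesh, path: str, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with tissue labels as cell data."""
    n, m = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncortistim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        fh.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10, dtype=np.int64), fmt="%d")

        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.tissue.astype(int), fmt="%d")
        for name, values in (cell_data or {}).items():
            values = np.asarray(values)
            if values.ndim == 1:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, values, fmt="%.9g")
            elif values.shape[1:] == (6,):
                # symmetric tensor xx yy zz xy yz xz
                fh.write(f"FIELD tensors 1\n{name} 6 {m} double\n")
                np.savetxt(fh, values, fmt="%.9g")
            else:
                raise FormatError(f"unsupported cell data shape {values.shape}")
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(values), fmt="%.9g")


def symmetric_tensor_components(tensors: np.ndarray) -> np.ndarray:
    """(m, 3, 3) -> (m, 6) components ordered xx yy zz xy yz xz."""
    t = np.asarray(tensors)
    return np.stack(
        [t[:, 0, 0], t[:, 1, 1], t[:, 2, 2], t[:, 0, 1], t[:, 1, 2], t[:, 0, 2]],
        axis=1,
    )
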