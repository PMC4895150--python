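"""Quasi-static potential solves on labelled tet meshes.

First-order tetrahedral FEM for div(sigma grad phi) = 0 with
current-controlled contacts: every electrode contact is tied to a single
floating-equipotential degree of freedom and driven with a prescribed net
current, which matches clinical current-controlled stimulators.  Undriven
contacts float with zero net current, so superposition across contacts holds
exactly.

Unit convention: coordinates mm, conductivity S/m, current mA.  With these,
the assembled system K phi = I yields phi in volts; nodal potentials are
stored in mV per mA of drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity_model import ASSEMBLY_SIGMA_FLOOR, ConductivityField
from .errors import ConfigurationError, InputError, SolverError
from .scenario_geometry import Mesh

__all__ = [
    "StimulusDrive",
    "PotentialField",
    "VolumeConductor",
    "solve_potential",
    "sample_potential",
    "activating_function",
]

GROUNDING_SCHEMES = (
    "exterior_grounded_except_top",
    "bottom_grounded",
    "distant_patch",
)


@dataclass(frozen=True)
class StimulusDrive:
    """Polarity, amplitude and grounding scheme of one stimulus configuration.

    ``polarity``: "anodal" (+I on the active contact), "cathodal" (-I on the
    active contact) or "bipolar" (+I active, -I return).
    """

    polarity: str = "anodal"
    amplitude: float = 1.0  # mA
    grounding: str = "exterior_grounded_except_top"
    #: optional explicit (contact_index, current_fraction) pairs overriding
    #: the polarity-derived drive
    contacts: tuple = ()

    def __post_init__(self) -> None:
        if self.amplitude <= 0.0:
            raise InputError("stimulus amplitude must be > 0")
        if self.polarity not in ("anodal", "cathodal", "bipolar"):
            raise InputError(f"unknown polarity {self.polarity!r}")
        if self.grounding not in GROUNDING_SCHEMES:
            raise InputError(f"unknown grounding scheme {self.grounding!r}")

    def contact_currents(self, roles: dict) -> list:
        """(contact index, signed current in mA) pairs for this drive."""
        if self.contacts:
            return [(c, f * self.amplitude) for c, f in self.contacts]
        active = [i for i, r in roles.items() if r == "active"]
        ret = [i for i, r in roles.items() if r == "return"]
        if not active:
            raise ConfigurationError("no active contact in the mesh")
        sign = -1.0 if self.polarity == "cathodal" else 1.0
        pairs = [(active[0], sign * self.amplitude)]
        if self.polarity == "bipolar":
            if not ret:
                raise ConfigurationError("bipolar drive requires a return contact")
            pairs.append((ret[0], -self.amplitude))
        return pairs


@dataclass
class PotentialField:
    """Nodal potentials (mV at the drive amplitude) with interpolation."""

    mesh: Mesh
    nodal_mv: np.ndarray
    drive: StimulusDrive | None = None

    def sample(self, points: np.ndarray) -> np.ndarray:
        return self.mesh.interpolate(self.nodal_mv, points)

    def scaled(self, factor: float) -> "PotentialField":
        return PotentialField(self.mesh, self.nodal_mv * factor, self.drive)

    def __add__(self, other: "PotentialField") -> "PotentialField":
        return PotentialField(self.mesh, self.nodal_mv + other.nodal_mv, None)

    def __sub__(self, other: "PotentialField") -> "PotentialField":
        return PotentialField(self.mesh, self.nodal_mv - other.nodal_mv, None)

    def __neg__(self) -> "PotentialField":
        return PotentialField(self.mesh, -self.nodal_mv, self.drive)


def _assemble_stiffness(mesh: Mesh, cond: ConductivityField) -> sp.csr_matrix:
    """P1 stiffness matrix with per-element 3x3 conductivity tensors."""
    nodes = mesh.nodes
    elems = mesh.elements
    x0 = nodes[elems[:, 0]]
    B = np.stack(
        [nodes[elems[:, i]] - x0 for i in (1, 2, 3)], axis=2
    )  # (m, 3, 3) columns = edge vectors
    det = np.linalg.det(B)
    vol = np.abs(det) / 6.0
    Binv = np.linalg.inv(B)
    grads = np.empty((len(elems), 4, 3))
    # gradients of barycentric coords 1..3 are the rows of B^{-1}
    grads[:, 1:, :] = Binv
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)

    sigma = cond.tensors.copy()
    eigs = np.linalg.eigvalsh(sigma)
    low = eigs[:, 0] < ASSEMBLY_SIGMA_FLOOR
    if low.any():
        sigma[low] += (ASSEMBLY_SIGMA_FLOOR * np.eye(3))[None, :, :]

    flux = np.einsum("mab,mib->mia", sigma, grads)  # sigma grad N_i
    Ke = np.einsum("mia,mja,m->mij", flux, grads, vol)

    rows = np.repeat(elems, 4, axis=1).ravel()
    cols = np.tile(elems, (1, 4)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K


class VolumeConductor:
    """Reusable solver: assembles once, solves many drives on the same mesh."""

    def __init__(self, mesh: Mesh, cond: ConductivityField,
                 rtol: float = 1e-8, maxiter: int = 40000):
        if not cond.is_spd():
            raise ConfigurationError("conductivity tensors must be SPD")
        if len(cond.tensors) != mesh.n_elements:
            raise InputError("conductivity field does not match the mesh")
        self.mesh = mesh
        self.rtol = rtol
        self.maxiter = maxiter
        self.K = _assemble_stiffness(mesh, cond)

        self.contact_nodes: dict[int, np.ndarray] = {}
        for c in np.unique(mesh.contact):
            if c == 0:
                continue
            nodes = np.unique(mesh.elements[mesh.contact == c])
            self.contact_nodes[int(c)] = nodes
        self.roles = {}
        geom = mesh.geometry
        if geom is not None:
            for i, spec in enumerate(geom.electrodes, start=1):
                if i in self.contact_nodes:
                    self.roles[i] = spec.role
        elif mesh.contact_roles:
            self.roles = {c: r for c, r in mesh.contact_roles.items()
                          if c in self.contact_nodes}

    def grounded_nodes(self, scheme: str, patch_radius: float = 10.0) -> np.ndarray:
        facets = self.mesh.facets
        if scheme == "exterior_grounded_except_top":
            tags = ("xmin", "xmax", "ymin", "zmin", "zmax")
            nodes = np.unique(np.concatenate([facets[t].ravel() for t in tags]))
        elif scheme == "bottom_grounded":
            nodes = np.unique(facets["ymin"].ravel())
        elif scheme == "distant_patch":
            bottom = np.unique(facets["ymin"].ravel())
            xyz = self.mesh.nodes[bottom]
            r = np.hypot(xyz[:, 0], xyz[:, 2])
            nodes = bottom[r <= patch_radius]
        else:
            raise ConfigurationError(f"unknown grounding scheme {scheme!r}")
        if len(nodes) == 0:
            raise ConfigurationError("grounding scheme selects no boundary nodes")
        return nodes

    def _reduce(self, ground: np.ndarray):
        n = self.mesh.n_nodes
        dof = np.full(n, -1, dtype=np.int64)
        masters = {}
        next_dof = 0
        tied = np.zeros(n, dtype=bool)
        for c, cn in sorted(self.contact_nodes.items()):
            masters[c] = next_dof
            dof[cn] = next_dof
            tied[cn] = True
            next_dof += 1
        free = np.flatnonzero(~tied)
        gset = np.zeros(n, dtype=bool)
        gset[ground] = True
        if (tied & gset).any():
            raise ConfigurationError("electrode contact touches the ground boundary")
        free = free[~gset[free]]
        dof[free] = next_dof + np.arange(len(free))
        n_red = next_dof + len(free)

        keep = dof >= 0
        rows = np.flatnonzero(keep)
        P = sp.coo_matrix(
            (np.ones(len(rows)), (rows, dof[rows])), shape=(n, n_red)
        ).tocsr()
        return P, dof, masters, n_red

    def solve(self, drive: StimulusDrive) -> PotentialField:
        """Potential field for the drive, in mV at the drive amplitude."""
        ground = self.grounded_nodes(drive.grounding)
        pairs = drive.contact_currents(self.roles)
        if not pairs:
            raise ConfigurationError("no driven contact")
        total = sum(i for _, i in pairs)
        if abs(total) > 1e-12 and len(ground) == 0:
            raise ConfigurationError("monopolar drive requires a ground in circuit")

        P, dof, masters, n_red = self._reduce(ground)
        K_red = (P.T @ self.K @ P).tocsr()
        rhs = np.zeros(n_red)
        for c, current in pairs:
            if c not in masters:
                raise ConfigurationError(f"contact {c} not present in the mesh")
            rhs[masters[c]] += current

        diag = K_red.diagonal()
        if (diag <= 0.0).any():
            raise SolverError("reduced stiffness matrix has non-positive diagonal")
        M = sp.diags(1.0 / diag)
        x, info = spla.cg(K_red, rhs, rtol=self.rtol, atol=0.0,
                          maxiter=self.maxiter, M=M)
        if info != 0:
            ilu = spla.spilu(K_red.tocsc(), drop_tol=1e-5, fill_factor=20)
            M2 = spla.LinearOperator(K_red.shape, ilu.solve)
            x, info = spla.cg(K_red, rhs, rtol=self.rtol, atol=0.0,
                              maxiter=self.maxiter, M=M2)
            if info != 0:
                res = np.linalg.norm(K_red @ x - rhs) / np.linalg.norm(rhs)
                raise SolverError(
                    f"CG did not converge (info={info}, relative residual {res:.2e})"
                )
        phi = np.zeros(self.mesh.n_nodes)
        sel = dof >= 0
        phi[sel] = x[dof[sel]]
        return PotentialField(self.mesh, phi * 1e3, drive)  # V -> mV

    def solve_point_source(self, point: np.ndarray, current: float = 1.0,
                           grounding: str = "all") -> PotentialField:
        """Unit point source at the node nearest ``point`` (oracle support).

        ``grounding="all"`` grounds the entire exterior.
        """
        d2 = np.sum((self.mesh.nodes - np.asarray(point, float)) ** 2, axis=1)
        src = int(np.argmin(d2))
        if grounding == "all":
            ground = np.unique(
                np.concatenate([f.ravel() for f in self.mesh.facets.values()])
            )
        else:
            ground = self.grounded_nodes(grounding)
        P, dof, _, n_red = self._reduce(ground)
        if dof[src] < 0:
            raise ConfigurationError("source node is grounded")
        K_red = (P.T @ self.K @ P).tocsr()
        rhs = np.zeros(n_red)
        rhs[dof[src]] = current
        M = sp.diags(1.0 / K_red.diagonal())
        x, info = spla.cg(K_red, rhs, rtol=self.rtol, atol=0.0,
                          maxiter=self.maxiter, M=M)
        if info != 0:
            raise SolverError(f"CG did not converge (info={info})")
        phi = np.zeros(self.mesh.n_nodes)
        sel = dof >= 0
        phi[sel] = x[dof[sel]]
        return PotentialField(self.mesh, phi * 1e3, None)

    def boundary_current(self, field: PotentialField, scheme: str) -> float:
        """Net current (mA) collected by the grounded boundary."""
        ground = self.grounded_nodes(scheme)
        residual = self.K @ (field.nodal_mv / 1e3)
        return float(-residual[ground].sum())


def solve_potential(mesh: Mesh, cond: ConductivityField,
                    drive: StimulusDrive, **kwargs) -> PotentialField:
    """One-shot convenience wrapper around :class:`VolumeConductor`."""
    return VolumeConductor(mesh, cond, **kwargs).solve(drive)


def sample_potential(field: PotentialField, points: np.ndarray) -> np.ndarray:
    """Barycentric interpolation of the solved potential (mV) at points."""
    return field.sample(points)


def activating_function(potentials: np.ndarray, spacing: float) -> np.ndarray:
    """Central second differences of potentials along a uniformly spaced path.

    Returns the raw second difference v[i-1] - 2 v[i] + v[i+1] per interior
    sample (a quadratic profile a*x^2 maps to the constant 2 a spacing^2);
    the two end samples are undefined and omitted.
    """
    v = np.asarray(potentials, float)
    if v.ndim != 1 or len(v) < 3:
        raise InputError("activating function needs >= 3 samples on a path")
    if spacing <= 0.0:
        raise InputError("spacing must be positive")
    return v[:-2] - 2.0 * v[1:-1] + v[2:]
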