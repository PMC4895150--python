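"""Tissue conductivities: isotropic table and anisotropic white-matter tensors.

White-matter anisotropy is expressed as S diag(sigma_L, sigma_T, sigma_T) S^T
with S an orthonormal eigenvector matrix whose first column is the local
fiber direction.  In the slab the fiber field is constant along the depth
axis; the folded surrogate uses a smooth geometry-derived field blending the
local cortical normal into the vertical stalk direction (a documented
stand-in for diffusion-tensor data, which is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, ParameterError
from .scenario_geometry import HeadGeometry, Mesh, Tissue

__all__ = [
    "ConductivityTable",
    "ConductivityTensorSpec",
    "FiberField",
    "ConductivityField",
    "assign_isotropic",
    "fiber_direction_field",
    "anisotropic_tensor",
    "apply_wm_anisotropy",
    "build_conductivity",
]

#: isotropic conductivities (S/m)
DEFAULT_CONDUCTIVITIES = {
    "scalp": 0.465,
    "skull": 0.01,
    "dura": 0.065,
    "csf": 1.65,
    "gm": 0.276,
    "wm": 0.126,  # isotropic-control value; anisotropic mode overrides WM
    "electrode": 9.4e6,
    "substrate": 0.1e-9,
}

#: anisotropic WM eigenvalues (S/m)
WM_SIGMA_LONGITUDINAL = 1.1
WM_SIGMA_TRANSVERSE = 0.13
WM_ISOTROPIC_CONTROL = 0.126

#: numerical floor applied at assembly time so the nearly-insulating
#: substrate (0.1e-9 S/m as specified) does not destroy solver conditioning;
#: still > 6 orders below every tissue.
ASSEMBLY_SIGMA_FLOOR = 1e-8


@dataclass
class ConductivityTable:
    """Per-tissue scalar conductivity in S/m."""

    values: dict = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES))

    def __post_init__(self) -> None:
        for name, sigma in self.values.items():
            if sigma <= 0.0:
                raise ParameterError(f"conductivity of {name} must be > 0")

    def __getitem__(self, tissue: str) -> float:
        return self.values[tissue]

    @classmethod
    def from_yaml(cls, path: str) -> "ConductivityTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        values = dict(DEFAULT_CONDUCTIVITIES)
        values.update(data.get("conductivity", data))
        return cls(values)


@dataclass
class ConductivityTensorSpec:
    """Eigenvector matrix plus longitudinal/transverse eigenvalues."""

    S: np.ndarray
    sigma_L: float = WM_SIGMA_LONGITUDINAL
    sigma_T: float = WM_SIGMA_TRANSVERSE

    def validate(self) -> None:
        S = np.asarray(self.S, float)
        if S.shape != (3, 3) or not np.allclose(S.T @ S, np.eye(3), atol=1e-9):
            raise ParameterError("S must be a 3x3 orthonormal matrix")
        if self.sigma_L <= 0.0 or self.sigma_T <= 0.0:
            raise ParameterError("sigma_L and sigma_T must be > 0")


@dataclass
class FiberField:
    """Unit fiber direction per WM element (zeros elsewhere)."""

    directions: np.ndarray  # (m, 3)
    wm_mask: np.ndarray  # (m,) bool


@dataclass
class ConductivityField:
    """Per-element symmetric 3x3 conductivity tensors (S/m)."""

    tensors: np.ndarray  # (m, 3, 3)

    def is_spd(self, tol: float = 1e-12) -> bool:
        sym = np.allclose(self.tensors, np.swapaxes(self.tensors, 1, 2), atol=1e-9)
        eigs = np.linalg.eigvalsh(self.tensors)
        return bool(sym and (eigs > tol).all())


def assign_isotropic(mesh: Mesh, table: ConductivityTable | None = None
                     ) -> ConductivityField:
    """sigma * I per element from the element's tissue label."""
    table = table or ConductivityTable()
    m = mesh.n_elements
    tensors = np.zeros((m, 3, 3))
    eye = np.eye(3)
    for code in np.unique(mesh.tissue):
        name = Tissue(int(code)).name.lower()
        if name not in table.values:
            raise ConfigurationError(f"no conductivity configured for tissue {name}")
        tensors[mesh.tissue == code] = table[name] * eye
    return ConductivityField(tensors)


def fiber_direction_field(geom: HeadGeometry, mesh: Mesh,
                          mode: str = "slab_perpendicular",
                          blend_length: float = 4.0) -> FiberField:
    """Unit fiber directions on WM elements.

    ``slab_perpendicular``: constant (0, 1, 0), i.e. perpendicular to the
    skull.  ``surrogate_streamline``: near the GM/WM boundary the direction
    follows the local cortical normal, turning smoothly into the vertical
    stalk direction over ``blend_length`` mm of extra depth.
    """
    wm = mesh.tissue == int(Tissue.WM)
    directions = np.zeros((mesh.n_elements, 3))
    if mode == "slab_perpendicular":
        directions[wm] = (0.0, 1.0, 0.0)
    elif mode == "surrogate_streamline":
        centroids = mesh.element_centroids()[wm]
        xy = centroids[:, :2]
        depth = geom.depth(xy)
        # inward normal ~ normalised depth gradient (central differences)
        h = 0.05
        gdx = (geom.depth(xy + [h, 0.0]) - geom.depth(xy - [h, 0.0])) / (2 * h)
        gdy = (geom.depth(xy + [0.0, h]) - geom.depth(xy - [0.0, h])) / (2 * h)
        norm = np.hypot(gdx, gdy)
        norm[norm < 1e-9] = 1.0
        nvec = np.stack([gdx / norm, gdy / norm], axis=1)
        # orient "deeper" consistently downward-ish, then blend to vertical
        flip = nvec[:, 1] > 0.0
        nvec[flip] *= -1.0
        alpha = np.clip((depth - geom.params.gm_thickness) / blend_length, 0.0, 1.0)
        vec = np.zeros((len(centroids), 3))
        vec[:, 0] = (1.0 - alpha) * nvec[:, 0]
        vec[:, 1] = (1.0 - alpha) * nvec[:, 1] + alpha * (-1.0)
        vec[:, 1] -= 1e-6  # break ties on the medial axis toward vertical
        vec /= np.maximum(np.linalg.norm(vec, axis=1, keepdims=True), 1e-12)
        directions[wm] = vec
    else:
        raise ParameterError(f"unknown fiber field mode {mode!r}")
    return FiberField(directions=directions, wm_mask=wm)


def anisotropic_tensor(spec: ConductivityTensorSpec) -> np.ndarray:
    """S diag(sigma_L, sigma_T, sigma_T) S^T."""
    spec.validate()
    S = np.asarray(spec.S, float)
    D = np.diag([spec.sigma_L, spec.sigma_T, spec.sigma_T])
    return S @ D @ S.T


def tensor_from_fiber(direction: np.ndarray, sigma_L: float,
                      sigma_T: float) -> np.ndarray:
    """Equivalent rank-1 form sigma_T I + (sigma_L - sigma_T) f f^T."""
    f = np.asarray(direction, float)
    f = f / np.linalg.norm(f)
    return sigma_T * np.eye(3) + (sigma_L - sigma_T) * np.outer(f, f)


def apply_wm_anisotropy(field: ConductivityField, fibers: FiberField,
                        sigma_L: float = WM_SIGMA_LONGITUDINAL,
                        sigma_T: float = WM_SIGMA_TRANSVERSE) -> ConductivityField:
    """Replace WM element tensors with fiber-aligned anisotropic tensors."""
    tensors = field.tensors.copy()
    f = fibers.directions[fibers.wm_mask]
    outer = np.einsum("mi,mj->mij", f, f)
    tensors[fibers.wm_mask] = sigma_T * np.eye(3) + (sigma_L - sigma_T) * outer
    return ConductivityField(tensors)


def build_conductivity(geom: HeadGeometry, mesh: Mesh,
                       mode: str = "anisotropic",
                       table: ConductivityTable | None = None
                       ) -> ConductivityField:
    """Full conductivity field for a campaign.

    ``anisotropic`` uses the fiber-aligned WM tensors; ``isotropic_control``
    keeps WM at the 0.126 S/m control value from the table.
    """
    field = assign_isotropic(mesh, table)
    if mode == "isotropic_control":
        return field
    if mode != "anisotropic":
        raise ParameterError(f"unknown conductivity mode {mode!r}")
    fiber_mode = ("slab_perpendicular" if geom.kind == "slab"
                  else "surrogate_streamline")
    fibers = fiber_direction_field(geom, mesh, mode=fiber_mode)
    return apply_wm_anisotropy(field, fibers)
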