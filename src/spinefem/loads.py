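"""Physiological load cases and boundary conditions.

Six standard loadings: a uniformly distributed 500 N compressive preload
on the superior surface of T11 acting together with a 7.5 N*m moment
(flexion, extension, left/right lateral bending, left/right axial
rotation), with every node on the inferior surface of L1 fully fixed.

Sign conventions (+x anterior, +y subject-left, +z superior, right-handed):

========================  =============================
case                      moment axis (7.5 N*m applied)
========================  =============================
flexion                   +y
extension                 -y
right_bending             +x
left_bending              -x
left_rotation             +z
right_rotation            -z
========================  =============================

The moment is applied as a self-equilibrated nodal force couple over the
surface: zero net force, requested net moment about the (area-weighted)
surface centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import InvalidParameterError, MeshingError
from .meshing import Mesh

CASE_AXES: Dict[str, np.ndarray] = {
    "flexion": np.array([0.0, 1.0, 0.0]),
    "extension": np.array([0.0, -1.0, 0.0]),
    "right_bending": np.array([1.0, 0.0, 0.0]),
    "left_bending": np.array([-1.0, 0.0, 0.0]),
    "left_rotation": np.array([0.0, 0.0, 1.0]),
    "right_rotation": np.array([0.0, 0.0, -1.0]),
}

CASE_LABELS = tuple(CASE_AXES)

#: case pairs that map onto each other under reflection about y=0
MIRROR_CASE = {
    "flexion": "flexion", "extension": "extension",
    "left_bending": "right_bending", "right_bending": "left_bending",
    "left_rotation": "right_rotation", "right_rotation": "left_rotation",
}


@dataclass(frozen=True)
class LoadCase:
    """One physiological loading: preload plus moment on T11, L1 base fixed."""

    label: str
    preload: float = 500.0          # N, -z on T11 superior surface
    moment: float = 7.5             # N*m
    surface: str = "T11_superior"
    constraint_surface: str = "L1_inferior"

    def __post_init__(self):
        if self.label not in CASE_AXES:
            raise InvalidParameterError(f"unknown load case {self.label!r}")

    @property
    def moment_vector(self) -> np.ndarray:
        return CASE_AXES[self.label] * self.moment * 1000.0   # N*mm

    def mirrored(self) -> "LoadCase":
        from dataclasses import replace
        return replace(self, label=MIRROR_CASE[self.label])


def _facet_weights(mesh: Mesh, group: str) -> Tuple[np.ndarray, np.ndarray]:
    """Consistent nodal area weights of a surface facet group.

    Linear facets load each corner with A/3; straight-edged quadratic
    facets load each midside with A/3 (corners receive zero).
    Returns (node ids, weights); weight sum equals the surface area.
    """
    if group not in mesh.facet_sets:
        raise MeshingError(f"no facet group {group!r} in mesh")
    facets = mesh.facet_sets[group]
    if facets.size == 0:
        raise MeshingError(f"facet group {group!r} is empty")
    x = mesh.nodes[facets[:, :3]]
    areas = 0.5 * np.linalg.norm(
        np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
    if areas.sum() <= 0:
        raise MeshingError(f"surface {group!r} has zero area")
    w = np.zeros(mesh.n_nodes)
    if facets.shape[1] == 3:
        for c in range(3):
            np.add.at(w, facets[:, c], areas / 3.0)
    else:
        for c in range(3, 6):
            np.add.at(w, facets[:, c], areas / 3.0)
    ids = np.flatnonzero(w != 0.0)
    return ids, w[ids]


def distribute_pressure(mesh: Mesh, group: str, total_force: float
                        ) -> np.ndarray:
    """Consistent nodal forces of a uniform downward (-z) traction.

    The assembled resultant equals (0, 0, -total_force) exactly (up to
    round-off).
    """
    f = np.zeros(3 * mesh.n_nodes)
    if total_force == 0.0:
        _facet_weights(mesh, group)   # still validate the surface
        return f
    ids, w = _facet_weights(mesh, group)
    area = w.sum()
    f[3 * ids + 2] = -total_force * w / area
    return f


def apply_moment(mesh: Mesh, group: str, moment_vector: np.ndarray
                 ) -> np.ndarray:
    """Self-equilibrated nodal force couple with the requested net moment.

    Forces follow the rigid-rotation velocity field v x r weighted by the
    consistent nodal areas, so the net force vanishes and the net moment
    about the surface centroid equals ``moment_vector``.
    """
    m = np.asarray(moment_vector, dtype=float)
    f = np.zeros(3 * mesh.n_nodes)
    if not np.any(m):
        _facet_weights(mesh, group)
        return f
    ids, w = _facet_weights(mesh, group)
    x = mesh.nodes[ids]
    centroid = (w[:, None] * x).sum(0) / w.sum()
    r = x - centroid
    A = (w[:, None, None]
         * ((r ** 2).sum(1)[:, None, None] * np.eye(3)
            - r[:, :, None] * r[:, None, :])).sum(0)
    try:
        v = np.linalg.solve(A, m)
    except np.linalg.LinAlgError:
        raise MeshingError(
            f"surface {group!r} nodes are collinear; cannot carry a moment")
    if np.linalg.cond(A) > 1e12:
        raise MeshingError(
            f"surface {group!r} nodes are collinear; cannot carry a moment")
    forces = w[:, None] * np.cross(v, r)
    for c in range(3):
        f[3 * ids + c] = forces[:, c]
    return f


def fix_base(mesh: Mesh, group: str = "L1_inferior") -> np.ndarray:
    """All three dofs of every node in the group, constrained to zero."""
    if group not in mesh.node_sets:
        raise MeshingError(f"no node group {group!r} in mesh")
    ids = mesh.node_sets[group]
    if ids.size == 0:
        raise MeshingError(f"node group {group!r} is empty")
    return (3 * ids[:, None] + np.arange(3)[None, :]).ravel()


def build_case(mesh: Mesh, case: LoadCase) -> Tuple[np.ndarray, np.ndarray]:
    """Assembled force vector and fixed dof set for one load case."""
    f = distribute_pressure(mesh, case.surface, case.preload)
    f += apply_moment(mesh, case.surface, case.moment_vector)
    fixed = fix_base(mesh, case.constraint_surface)
    return f, fixed


def resultants(mesh: Mesh, f: np.ndarray, about: Optional[np.ndarray] = None
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Net force and net moment (about ``about`` or the origin) of a load."""
    fv = f.reshape(-1, 3)
    net_f = fv.sum(0)
    x = mesh.nodes if about is None else mesh.nodes - about
    net_m = np.cross(x, fv).sum(0)
    return net_f, net_m
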