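"""Linear-elasticity solver: TET4/TET10 solids plus tension-only trusses.

Small-strain, small-rotation isotropic elasticity.  Element stiffness uses
exact integration for linear tets and a 4-point Gauss rule for quadratic
(straight-sided) tets.  Ligaments are axial trusses that carry tension
only; the nonlinearity is resolved by a fixed-point active-set iteration,
accelerated with a Sherman-Morrison-Woodbury update so the solid stiffness
is factorised once per model.

Units: mm, N, MPa (N/mm^2); moments in N*mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AssemblyError, NonConvergenceError
from .materials import MaterialSpec, material_for
from .meshing import Mesh, Truss

# 4-point Gauss rule for tetrahedra (degree 2)
_GA, _GB = 0.5854101966249685, 0.1381966011250105
_GAUSS4 = np.array([
    [_GA, _GB, _GB, _GB],
    [_GB, _GA, _GB, _GB],
    [_GB, _GB, _GA, _GB],
    [_GB, _GB, _GB, _GA],
])
_EDGE_PAIRS = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])


def elastic_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic Hooke matrix in Voigt order (xx, yy, zz, xy, yz, zx)."""
    c = E / ((1 + nu) * (1 - 2 * nu))
    D = np.zeros((6, 6))
    D[:3, :3] = c * nu
    D[np.diag_indices(3)] = c * (1 - nu)
    D[3:, 3:] = np.eye(3) * c * (1 - 2 * nu) / 2
    return D


def von_mises(stress) -> np.ndarray:
    """Equivalent (von Mises) stress of symmetric tensors.

    Accepts a 3x3 tensor, an array of them (..., 3, 3), or Voigt vectors
    (..., 6) ordered (xx, yy, zz, xy, yz, zx).
    """
    s = np.asarray(stress, dtype=float)
    if s.shape[-1] == 3 and s.ndim >= 2 and s.shape[-2] == 3:
        sxx, syy, szz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
        sxy, syz, szx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    else:
        sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2
                          + (szz - sxx) ** 2)
                   + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))


# ----------------------------------------------------------------------
# element matrices
# ----------------------------------------------------------------------

def _corner_geometry(coords: np.ndarray):
    """Barycentric gradients and volumes for corner tets (E, 4, 3)."""
    E = coords.shape[0]
    M = np.concatenate([np.ones((E, 4, 1)), coords], axis=2)
    vol = np.linalg.det(M) / 6.0
    if np.any(vol <= 0):
        raise AssemblyError(
            f"{int(np.sum(vol <= 0))} inverted/degenerate element(s)")
    C = np.linalg.inv(M)
    grads = C[:, 1:4, :].transpose(0, 2, 1)    # (E, node, xyz)
    return grads, vol


def _b_from_grads(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix from nodal gradients (E, n, 3)."""
    E, n, _ = g.shape
    B = np.zeros((E, 6, 3 * n))
    B[:, 0, 0::3] = g[:, :, 0]
    B[:, 1, 1::3] = g[:, :, 1]
    B[:, 2, 2::3] = g[:, :, 2]
    B[:, 3, 0::3] = g[:, :, 1]
    B[:, 3, 1::3] = g[:, :, 0]
    B[:, 4, 1::3] = g[:, :, 2]
    B[:, 4, 2::3] = g[:, :, 1]
    B[:, 5, 0::3] = g[:, :, 2]
    B[:, 5, 2::3] = g[:, :, 0]
    return B


def _tet10_grads(grads4: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Gradients of the 10 quadratic shape functions at barycentric lam."""
    E = grads4.shape[0]
    g = np.zeros((E, 10, 3))
    for a in range(4):
        g[:, a] = (4 * lam[a] - 1) * grads4[:, a]
    for m, (a, b) in enumerate(_EDGE_PAIRS):
        g[:, 4 + m] = 4 * (lam[a] * grads4[:, b] + lam[b] * grads4[:, a])
    return g


def element_stiffness(coords: np.ndarray, material: MaterialSpec,
                      order: int = 1) -> np.ndarray:
    """Stiffness of a single tet (12x12 for TET4, 30x30 for TET10).

    ``coords`` holds the 4 corner coordinates; TET10 midside nodes are the
    straight-edge midpoints.
    """
    D = elastic_matrix(material.young_modulus, material.poisson_ratio)
    grads, vol = _corner_geometry(coords[None, :4])
    if order == 1:
        B = _b_from_grads(grads)[0]
        return vol[0] * B.T @ D @ B
    K = np.zeros((30, 30))
    for lam in _GAUSS4:
        B = _b_from_grads(_tet10_grads(grads, lam))[0]
        K += 0.25 * vol[0] * B.T @ D @ B
    return K


def truss_stiffness(xi: np.ndarray, xj: np.ndarray, E: float, area: float,
                    active: bool = True) -> np.ndarray:
    """6x6 stiffness of an axial truss between two points (dofs i then j)."""
    d = np.asarray(xj, float) - np.asarray(xi, float)
    L = np.linalg.norm(d)
    if L < 1e-12:
        raise AssemblyError("coincident truss nodes")
    if not active:
        return np.zeros((6, 6))
    n = d / L
    k = E * area / L
    nn = k * np.outer(n, n)
    K = np.empty((6, 6))
    K[:3, :3] = nn
    K[:3, 3:] = -nn
    K[3:, :3] = -nn
    K[3:, 3:] = nn
    return K


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------

def material_table(mesh: Mesh, osteoporotic: bool = True,
                   osteoporotic_cancellous_modulus: float = 34.0
                   ) -> Dict[str, MaterialSpec]:
    return {tag: material_for(tag, osteoporotic,
                              osteoporotic_cancellous_modulus)
            for tag in mesh.region_tags()}


def _element_D(mesh: Mesh, materials: Dict[str, MaterialSpec]) -> np.ndarray:
    Ds = np.zeros((len(mesh.region_names), 6, 6))
    for i, tag in enumerate(mesh.region_names):
        if tag in materials:
            m = materials[tag]
            Ds[i] = elastic_matrix(m.young_modulus, m.poisson_ratio)
    return Ds[mesh.region_ids]


def assemble_stiffness(mesh: Mesh,
                       materials: Dict[str, MaterialSpec]) -> sp.csr_matrix:
    """Global solid stiffness (trusses excluded)."""
    coords = mesh.nodes[mesh.tets[:, :4]]
    grads4, vol = _corner_geometry(coords)
    Del = _element_D(mesh, materials)
    nn = mesh.tets.shape[1]
    if mesh.order == 1:
        B = _b_from_grads(grads4)
        Ke = np.einsum("e,eki,ekl,elj->eij", vol, B, Del, B, optimize=True)
    else:
        Ke = np.zeros((mesh.n_elements, 30, 30))
        for lam in _GAUSS4:
            B = _b_from_grads(_tet10_grads(grads4, lam))
            Ke += np.einsum("e,eki,ekl,elj->eij", 0.25 * vol, B, Del, B,
                            optimize=True)
    dofs = (3 * mesh.tets[:, :, None]
            + np.arange(3)[None, None, :]).reshape(mesh.n_elements, 3 * nn)
    rows = np.repeat(dofs, 3 * nn, axis=1).ravel()
    cols = np.tile(dofs, (1, 3 * nn)).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof))
    return K.tocsr()


def truss_system(mesh: Mesh
                 ) -> Tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Elongation operator G (3N x m), axial stiffnesses and sign flags.

    Column t of G maps displacements to the elongation of element t; the
    internal force vector of the active elements is G_a (k_a * e_a).
    Signs: +1 tension-only (ligaments), -1 compression-only (facet
    contact), 0 bilateral.
    """
    m = len(mesh.trusses)
    ndof = 3 * mesh.n_nodes
    if m == 0:
        return sp.csr_matrix((ndof, 0)), np.zeros(0), np.zeros(0)
    rows, cols, vals, k_ax, signs = [], [], [], [], []
    for t, tr in enumerate(mesh.trusses):
        xi, xj = mesh.nodes[tr.node_i], mesh.nodes[tr.node_j]
        d = xj - xi
        L = np.linalg.norm(d)
        if tr.direction is not None:
            n = np.asarray(tr.direction, dtype=float)
            n = n / np.linalg.norm(n)
        elif L < 1e-12:
            raise AssemblyError(f"coincident truss nodes in {tr.name}")
        else:
            n = d / L
        for c in range(3):
            rows += [3 * tr.node_i + c, 3 * tr.node_j + c]
            cols += [t, t]
            vals += [-n[c], n[c]]
        if tr.stiffness is not None:
            k_ax.append(tr.stiffness)
        else:
            if L < 1e-12:
                raise AssemblyError(f"coincident truss nodes in {tr.name}")
            k_ax.append(tr.young_modulus * tr.area / L)
        signs.append(-1 if tr.compression_only
                     else (+1 if tr.tension_only else 0))
    G = sp.csr_matrix((vals, (rows, cols)), shape=(ndof, m))
    return G, np.asarray(k_ax, dtype=float), np.asarray(signs)


@dataclass
class LinearSystem:
    """Constrained linear system for one model (stiffness, load, supports)."""
    stiffness: sp.csr_matrix
    force: np.ndarray
    fixed_dofs: np.ndarray
    G: Optional[sp.csr_matrix] = None          # truss elongation operator
    k_ax: Optional[np.ndarray] = None
    tension_only: Optional[np.ndarray] = None  # bool per truss
    signs: Optional[np.ndarray] = None         # +1/-1/0; overrides the bool


@dataclass
class SolutionField:
    displacements: np.ndarray          # (N, 3) mm
    element_stress: np.ndarray         # (E, 6) Voigt MPa
    element_vms: np.ndarray            # (E,) MPa
    truss_forces: np.ndarray           # (m,) N, tension positive
    active_trusses: np.ndarray         # (m,) bool
    iterations: int
    reactions: np.ndarray              # (ndof,) at fixed dofs


class FactorisedSolid:
    """Reusable factorisation of the constrained solid stiffness.

    Uses SuperLU in symmetric mode with minimum-degree ordering on
    K + K^T (the matrix is symmetric positive definite after the
    constraints) and one step of iterative refinement per solve.
    """

    def __init__(self, K: sp.csr_matrix, fixed_dofs: np.ndarray):
        self.ndof = K.shape[0]
        self.fixed = np.asarray(fixed_dofs, dtype=np.int64)
        mask = np.ones(self.ndof, dtype=bool)
        mask[self.fixed] = False
        self.free = np.flatnonzero(mask)
        self.Kff = K[self.free][:, self.free].tocsc()
        try:
            self.lu = spla.splu(self.Kff, permc_spec="MMD_AT_PLUS_A",
                                diag_pivot_thresh=0.0,
                                options={"SymmetricMode": True})
        except RuntimeError as exc:   # singular
            raise AssemblyError(f"singular constrained stiffness: {exc}")
        # guard against a silently rank-deficient factorisation
        probe = np.ones(self.Kff.shape[0])
        x = self.lu.solve(probe)
        if not np.all(np.isfinite(x)):
            raise AssemblyError("singular constrained stiffness")
        r = np.linalg.norm(self.Kff @ x - probe) / np.linalg.norm(probe)
        if not np.isfinite(r) or r > 1e-3:
            raise AssemblyError(
                f"singular or ill-conditioned stiffness (residual {r:.1e})")

    def solve_free(self, rhs_free: np.ndarray) -> np.ndarray:
        x = self.lu.solve(rhs_free)
        # one iterative-refinement step restores near machine precision
        x += self.lu.solve(rhs_free - self.Kff @ x)
        return x

    def expand(self, u_free: np.ndarray) -> np.ndarray:
        u = np.zeros(self.ndof)
        u[self.free] = u_free
        return u


class WoodburySolver:
    """Per-model cache for the truss low-rank update.

    Stores K^-1 G and G^T K^-1 G once, so each load case costs one forward
    solve plus a small dense active-set iteration.
    """

    def __init__(self, factor: FactorisedSolid, G: sp.csr_matrix,
                 k_ax: np.ndarray, signs: np.ndarray):
        self.fac = factor
        self.k_ax = np.asarray(k_ax, dtype=float)
        self.signs = np.asarray(signs)
        self.m = G.shape[1]
        self.Gf = G.tocsr()[factor.free, :].toarray() if self.m else None
        if self.m:
            self.Y = factor.solve_free(self.Gf)
            self.S = self.Gf.T @ self.Y

    def solve(self, f: np.ndarray, max_iter: int = 50
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        fac = self.fac
        y0 = fac.solve_free(f[fac.free])
        if not self.m:
            return fac.expand(y0), np.zeros(0), np.zeros(0, bool), 1
        e0 = self.Gf.T @ y0
        active = np.ones(self.m, dtype=bool)
        history: List[frozenset] = []
        for it in range(1, max_iter + 1):
            a = np.flatnonzero(active)
            if a.size:
                A = self.S[np.ix_(a, a)] + np.diag(1.0 / self.k_ax[a])
                z = np.linalg.solve(A, e0[a])
                e = e0 - self.S[:, a] @ z
            else:
                z = np.zeros(0)
                e = e0.copy()
            new_active = (self.signs * e > 0) | (self.signs == 0)
            if np.array_equal(new_active, active):
                u = fac.expand(y0 - (self.Y[:, a] @ z if a.size else 0.0))
                forces = np.where(new_active, self.k_ax * e, 0.0)
                return u, forces, new_active, it
            history.append(frozenset(np.flatnonzero(new_active).tolist()))
            active = new_active
        raise NonConvergenceError(
            f"tension-only iteration did not converge in {max_iter} "
            f"iterations; oscillating active sets: "
            f"{[sorted(h) for h in history[-4:]]}", history)


def solve_tension_only(system: LinearSystem, max_iter: int = 50,
                       method: str = "auto",
                       factor: Optional[FactorisedSolid] = None
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Solve K u = f with tension-only trusses by active-set iteration.

    All trusses start active; after each solve, compressed trusses are
    deactivated and stretched ones reactivated until the active set is
    stable.  Returns (u, truss_forces, active, iterations).

    ``method='woodbury'`` (default for factorisable solids) keeps one
    factorisation of the solid stiffness and folds the truss stiffness in
    through a low-rank update; ``method='direct'`` refactorises per
    iteration and also works when truss nodes are supported only by other
    trusses' constraints.
    """
    K, f = system.stiffness, system.force
    G, k_ax = system.G, system.k_ax
    m = 0 if G is None else G.shape[1]
    if system.signs is not None:
        signs = np.asarray(system.signs)
    elif system.tension_only is not None:
        signs = np.where(np.asarray(system.tension_only, bool), 1, 0)
    else:
        signs = np.ones(m, dtype=int)

    if m == 0:
        fac = factor or FactorisedSolid(K, system.fixed_dofs)
        u = fac.expand(fac.solve_free(f[fac.free]))
        return u, np.zeros(0), np.zeros(0, dtype=bool), 1

    if method == "auto":
        method = "woodbury"

    if method == "woodbury":
        fac = factor or FactorisedSolid(K, system.fixed_dofs)
        solver = WoodburySolver(fac, G, k_ax, signs)
        return solver.solve(f, max_iter=max_iter)

    # direct method: refactorise with the active truss stiffness included
    active = np.ones(m, dtype=bool)
    history = []
    for it in range(1, max_iter + 1):
        a = np.flatnonzero(active)
        Ka = K
        if a.size:
            Ga = G[:, a]
            Ka = K + Ga @ sp.diags(k_ax[a]) @ Ga.T
        fac = FactorisedSolid(Ka.tocsr(), system.fixed_dofs)
        u = fac.expand(fac.solve_free(f[fac.free]))
        e = G.T @ u
        new_active = (signs * e > 0) | (signs == 0)
        if np.array_equal(new_active, active):
            forces = np.where(new_active, k_ax * e, 0.0)
            return u, forces, new_active, it
        history.append(frozenset(np.flatnonzero(new_active).tolist()))
        active = new_active
    raise NonConvergenceError(
        f"tension-only iteration did not converge in {max_iter} iterations",
        history)


def recover_stresses(mesh: Mesh, materials: Dict[str, MaterialSpec],
                     u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Element stress (Voigt) and von Mises stress.

    TET4: constant (centroid) stress.  TET10: average of the four Gauss
    points, which keeps element maxima well defined without nodal
    extrapolation.
    """
    coords = mesh.nodes[mesh.tets[:, :4]]
    grads4, vol = _corner_geometry(coords)
    Del = _element_D(mesh, materials)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(mesh.n_elements, -1)
    if mesh.order == 1:
        B = _b_from_grads(grads4)
        eps = np.einsum("eij,ej->ei", B, ue)
        sig = np.einsum("eij,ej->ei", Del, eps)
    else:
        sig = np.zeros((mesh.n_elements, 6))
        for lam in _GAUSS4:
            B = _b_from_grads(_tet10_grads(grads4, lam))
            eps = np.einsum("eij,ej->ei", B, ue)
            sig += 0.25 * np.einsum("eij,ej->ei", Del, eps)
    return sig, von_mises(sig)


def solve_model(mesh: Mesh, materials: Dict[str, MaterialSpec],
                force: np.ndarray, fixed_dofs: np.ndarray,
                factor: Optional[FactorisedSolid] = None,
                K: Optional[sp.csr_matrix] = None,
                solver: Optional[WoodburySolver] = None,
                max_iter: int = 50) -> SolutionField:
    """Full pipeline for one load case on a meshed model."""
    if K is None:
        K = assemble_stiffness(mesh, materials)
    G, k_ax, signs = truss_system(mesh)
    if solver is not None:
        u, forces, active, iters = solver.solve(force, max_iter=max_iter)
    else:
        system = LinearSystem(K, force, fixed_dofs, G, k_ax, signs=signs)
        u, forces, active, iters = solve_tension_only(
            system, max_iter=max_iter, factor=factor)
    sig, vms = recover_stresses(mesh, materials, u)
    # residual: internal - external force; nonzero only at supports
    r = K @ u - force
    if len(mesh.trusses):
        r += G @ np.where(active, forces, 0.0)
    reactions = np.zeros_like(r)
    reactions[fixed_dofs] = r[fixed_dofs]
    return SolutionField(displacements=u.reshape(-1, 3), element_stress=sig,
                         element_vms=vms, truss_forces=forces,
                         active_trusses=active, iterations=iters,
                         reactions=reactions)


def equilibrium_residual(mesh: Mesh, sol: SolutionField, force: np.ndarray
                         ) -> Tuple[float, float]:
    """Relative force and moment balance of supports vs applied load."""
    fext = force.reshape(-1, 3)
    R = sol.reactions.reshape(-1, 3)
    f_err = np.linalg.norm(fext.sum(0) + R.sum(0)) / max(
        np.linalg.norm(fext, axis=1).sum(), 1e-30)
    mom_ext = np.cross(mesh.nodes, fext).sum(0)
    mom_r = np.cross(mesh.nodes, R).sum(0)
    scale = max(np.linalg.norm(mom_ext), np.linalg.norm(mom_r), 1e-30)
    m_err = np.linalg.norm(mom_ext + mom_r) / scale
    return float(f_err), float(m_err)
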