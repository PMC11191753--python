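"""Element-level and solver-level verification oracles."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import spinefem as sf
from spinefem import fem, loads
from spinefem.materials import MaterialSpec

RNG = np.random.default_rng(20240621)

MAT = MaterialSpec("test", young_modulus=1000.0, poisson_ratio=0.3)


def random_tet():
    while True:
        x = RNG.uniform(-1, 1, size=(4, 3))
        d = x[1:] - x[0]
        if np.linalg.det(d) > 0.1:
            return x


# ----------------------------------------------------------------------
# von Mises closed forms
# ----------------------------------------------------------------------

@pytest.mark.parametrize("tensor,expected", [
    (np.diag([10.0, 0, 0]), 10.0),                       # uniaxial
    (np.diag([7.0, 7.0, 7.0]), 0.0),                     # hydrostatic
    (np.array([[0, 5.0, 0], [5.0, 0, 0], [0, 0, 0]]),    # pure shear
     5.0 * np.sqrt(3.0)),
])
def test_von_mises_closed_forms(tensor, expected):
    assert fem.von_mises(tensor) == pytest.approx(expected, abs=1e-12)


def test_von_mises_voigt_matches_tensor():
    s = RNG.uniform(-5, 5, 6)
    t = np.array([[s[0], s[3], s[5]],
                  [s[3], s[1], s[4]],
                  [s[5], s[4], s[2]]])
    assert fem.von_mises(s) == pytest.approx(float(fem.von_mises(t)),
                                             rel=1e-14)


def test_von_mises_rotation_invariant():
    from scipy.spatial.transform import Rotation
    t = np.array([[3.0, 1.0, -2.0], [1.0, -4.0, 0.5], [-2.0, 0.5, 7.0]])
    for seed in range(5):
        R = Rotation.random(random_state=seed).as_matrix()
        assert fem.von_mises(R @ t @ R.T) == pytest.approx(
            float(fem.von_mises(t)), rel=1e-12)


# ----------------------------------------------------------------------
# element stiffness
# ----------------------------------------------------------------------

@pytest.mark.parametrize("order,size", [(1, 12), (2, 30)])
def test_element_stiffness_symmetric_with_six_rigid_modes(order, size):
    x = random_tet()
    K = fem.element_stiffness(x, MAT, order=order)
    assert K.shape == (size, size)
    assert np.allclose(K, K.T, rtol=1e-12, atol=1e-12 * np.abs(K).max())
    w = np.linalg.eigvalsh(K)
    scale = w.max()
    assert np.sum(np.abs(w) < 1e-9 * scale) == 6
    assert w.min() > -1e-9 * scale


@pytest.mark.parametrize("order", [1, 2])
def test_rigid_translation_gives_zero_force(order):
    x = random_tet()
    K = fem.element_stiffness(x, MAT, order=order)
    n = K.shape[0] // 3
    for c in range(3):
        u = np.zeros(K.shape[0])
        u[c::3] = 1.0
        f = K @ u
        assert np.linalg.norm(f) < 1e-10 * np.abs(K).max()


@pytest.mark.parametrize("order", [1, 2])
def test_constant_strain_patch(order):
    """Linear boundary displacement on a multi-element patch recovers the
    uniform analytic stress tensor (Hooke's law) to 1e-8 relative."""
    mesh = sf.box_mesh((1.0, 1.0, 1.0), (2, 2, 2), order=order)
    A = np.array([[1e-3, 4e-4, -2e-4],
                  [3e-4, -5e-4, 1e-4],
                  [-1e-4, 2e-4, 6e-4]])
    u_imposed = mesh.nodes @ A.T
    eps = 0.5 * (A + A.T)
    D = fem.elastic_matrix(MAT.young_modulus, MAT.poisson_ratio)
    voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                      2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
    sigma_exact = D @ voigt

    mats = {"solid": MAT}
    K = fem.assemble_stiffness(mesh, mats)
    on_boundary = np.zeros(mesh.n_nodes, dtype=bool)
    for name in ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax"):
        on_boundary[mesh.node_sets[name]] = True
    fixed_nodes = np.flatnonzero(on_boundary)
    fixed = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    u = np.zeros(3 * mesh.n_nodes)
    u[fixed] = u_imposed[fixed_nodes].ravel()
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
    rhs = -K[free][:, fixed] @ u[fixed]
    import scipy.sparse.linalg as spla
    u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)

    sig, _ = fem.recover_stresses(mesh, mats, u)
    ref = np.linalg.norm(sigma_exact)
    assert np.abs(sig - sigma_exact).max() < 1e-8 * ref
    # and the displacement field itself is the exact linear field
    assert np.abs(u - u_imposed.ravel()).max() < 1e-8


def test_inverted_element_raises():
    x = random_tet()
    x_bad = x[[0, 2, 1, 3]]  # swapped -> negative volume
    with pytest.raises(sf.AssemblyError):
        fem.element_stiffness(x_bad, MAT, order=1)


# ----------------------------------------------------------------------
# truss stiffness
# ----------------------------------------------------------------------

def test_truss_axial_stiffness_value():
    # E=20 MPa, A=65 mm^2, L=10 mm -> EA/L = 130 N/mm
    K = fem.truss_stiffness(np.zeros(3), np.array([0, 0, 10.0]), 20.0, 65.0)
    assert K[2, 2] == pytest.approx(130.0, rel=1e-12)
    assert K[2, 5] == pytest.approx(-130.0, rel=1e-12)
    # axis along +z -> only z-z entries nonzero
    nz = np.abs(K) > 1e-12
    assert set(zip(*np.nonzero(nz))) == {(2, 2), (2, 5), (5, 2), (5, 5)}


def test_truss_inactive_is_zero_and_coincident_raises():
    assert np.all(fem.truss_stiffness(np.zeros(3), np.ones(3), 10, 1,
                                      active=False) == 0)
    with pytest.raises(sf.AssemblyError):
        fem.truss_stiffness(np.ones(3), np.ones(3), 10, 1)


def test_truss_stiffness_symmetric_psd_random_axes():
    for _ in range(10):
        xj = RNG.uniform(-1, 1, 3)
        K = fem.truss_stiffness(np.zeros(3), xj + 2.0, 7.5, 30.0)
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-12 * max(w.max(), 1)
        assert np.sum(w > 1e-9 * w.max()) == 1   # rank one


# ----------------------------------------------------------------------
# tension-only active set vs brute force
# ----------------------------------------------------------------------

def _toy_block_system(truss_defs, load):
    """A single stiff TET4 block with trusses hung from its corners to
    fixed external anchors (anchor nodes are fully constrained)."""
    base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    anchors = np.asarray([a for a, _, _ in truss_defs])
    nodes = np.vstack([base, anchors])
    mesh = sf.Mesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]], dtype=np.int32),
                   region_ids=np.zeros(1, dtype=np.int16),
                   region_names=["solid"], trusses=[], node_sets={},
                   facet_sets={}, order=1, n_corner_nodes=len(nodes))
    for t, (_anchor, corner, k) in enumerate(truss_defs):
        mesh.trusses.append(sf.Truss(node_i=corner, node_j=4 + t,
                                     name=f"t{t}", area=1.0,
                                     young_modulus=k, tension_only=True))
    mats = {"solid": MaterialSpec("solid", 1e4, 0.3)}
    K = fem.assemble_stiffness(mesh, mats)
    G, k_ax, _signs = fem.truss_system(mesh)
    fixed_nodes = np.arange(4, len(nodes))
    fixed = np.concatenate([
        (3 * fixed_nodes[:, None] + np.arange(3)).ravel(),
        [0, 1, 2],           # pin corner 0 to remove rigid modes
        [3 * 1 + 1, 3 * 1 + 2, 3 * 2 + 2],
    ])
    f = np.zeros(3 * len(nodes))
    f[:12] = np.asarray(load).ravel()
    f[fixed] = 0.0
    return mesh, K, G, k_ax, np.unique(fixed), f


def _brute_force_active_set(K, G, k_ax, fixed, f):
    import scipy.sparse.linalg as spla
    m = G.shape[1]
    ndof = K.shape[0]
    mask = np.ones(ndof, bool)
    mask[fixed] = False
    free = np.flatnonzero(mask)
    valid = []
    for bits in itertools.product([False, True], repeat=m):
        a = np.flatnonzero(bits)
        Ka = K + (G[:, a] @ sp.diags(k_ax[a]) @ G[:, a].T
                  if a.size else 0 * K)
        u = np.zeros(ndof)
        u[free] = spla.spsolve(Ka[free][:, free].tocsc(), f[free])
        e = G.T @ u
        ok = all(e[t] >= -1e-10 for t in a) and all(
            e[t] <= 1e-10 for t in range(m) if t not in a)
        if ok:
            valid.append((frozenset(a.tolist()), u))
    return valid


@pytest.mark.parametrize("pull", [
    (0, 0, 30.0), (25.0, 0, -10.0), (-12.0, 18.0, 5.0), (0, -40.0, 0)])
def test_active_set_matches_brute_force_enumeration(pull):
    """Toy model with 4 tension-only trusses: the fixed-point iteration
    lands on the unique sign-consistent active set found by enumerating
    all 2^4 subsets."""
    truss_defs = [
        (np.array([0.0, 0.0, 3.0]), 3, 50.0),    # above the top corner
        (np.array([2.0, 0.0, 0.0]), 1, 80.0),    # +x anchor
        (np.array([0.0, 2.0, 0.0]), 2, 60.0),    # +y anchor
        (np.array([0.0, -2.0, 1.0]), 3, 40.0),
    ]
    load = np.zeros((4, 3))
    load[3] = pull
    load[1] = (0.4 * np.asarray(pull)).tolist()
    mesh, K, G, k_ax, fixed, f = _toy_block_system(truss_defs, load)
    system = fem.LinearSystem(K, f, fixed, G, k_ax,
                              np.ones(len(k_ax), bool))
    for method in ("woodbury", "direct"):
        u, forces, active, it = fem.solve_tension_only(system, method=method)
        valid = _brute_force_active_set(K, G, k_ax, fixed, f)
        assert valid, "brute force found no consistent active set"
        sets = {s for s, _ in valid}
        assert frozenset(np.flatnonzero(active).tolist()) in sets
        # solution matches the brute-force displacement for that set
        u_ref = dict(valid)[frozenset(np.flatnonzero(active).tolist())]
        assert np.allclose(u, u_ref, atol=1e-10)
        assert np.all(forces[active] >= -1e-9)
        assert np.all(forces[~active] == 0.0)


def test_all_tension_load_equals_plain_linear_solve():
    truss_defs = [(np.array([0.0, 0.0, 3.0]), 3, 50.0),
                  (np.array([2.0, 0.0, 0.0]), 1, 80.0)]
    load = np.zeros((4, 3))
    load[3] = (1.0, 0, -5.0)    # pulls corner 3 away from its anchor
    load[1] = (-8.0, 0, 0)      # pulls corner 1 away from its anchor
    mesh, K, G, k_ax, fixed, f = _toy_block_system(truss_defs, load)
    system = fem.LinearSystem(K, f, fixed, G, k_ax, np.ones(2, bool))
    u, forces, active, it = fem.solve_tension_only(system)
    assert active.all()
    Kfull = K + G @ sp.diags(k_ax) @ G.T
    import scipy.sparse.linalg as spla
    mask = np.ones(K.shape[0], bool)
    mask[fixed] = False
    free = np.flatnonzero(mask)
    u_ref = np.zeros(K.shape[0])
    u_ref[free] = spla.spsolve(Kfull[free][:, free].tocsc(), f[free])
    assert np.abs(u - u_ref).max() < 1e-12 * max(np.abs(u_ref).max(), 1)


def test_compressed_truss_deactivates():
    """A vertical tension-only truss put into compression (its block corner
    pushed toward the anchor) deactivates and carries no force."""
    truss_defs = [(np.array([0.0, 0.0, 3.0]), 3, 50.0)]
    load = np.zeros((4, 3))
    load[3] = (0, 0, 10.0)   # push the top corner toward the anchor
    mesh, K, G, k_ax, fixed, f = _toy_block_system(truss_defs, load)
    system = fem.LinearSystem(K, f, fixed, G, k_ax, np.ones(1, bool))
    u, forces, active, it = fem.solve_tension_only(system)
    assert not active[0]
    assert forces[0] == 0.0


# ----------------------------------------------------------------------
# cantilever oracle
# ----------------------------------------------------------------------

def test_cantilever_tip_deflection_matches_beam_theory():
    """Slender TET10 cantilever under a tip load: deflection within 2% of
    PL^3/(3EI)."""
    L, h = 40.0, 2.0
    E, nu = 1000.0, 0.0
    P = 1.0
    mesh = sf.box_mesh((h, h, L), (2, 2, 24), order=2)
    mats = {"solid": MaterialSpec("solid", E, nu)}
    K = fem.assemble_stiffness(mesh, mats)
    fixed_nodes = mesh.node_sets["zmin"]
    fixed = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    # tip shear load in +x distributed over the top-face nodes
    tip = mesh.node_sets["zmax"]
    f = np.zeros(3 * mesh.n_nodes)
    f[3 * tip + 0] = P / len(tip)
    sol = fem.solve_model(mesh, mats, f, fixed, K=K)
    tip_defl = sol.displacements[tip, 0].mean()
    I = h * h ** 3 / 12.0
    ref = P * L ** 3 / (3 * E * I)
    assert tip_defl == pytest.approx(ref, rel=0.02)


def test_strain_energy_decreases_when_stiffened():
    """Under fixed displacement loading, stiffening a subregion cannot
    increase the stored strain energy."""
    mesh = sf.box_mesh((1.0, 1.0, 2.0), (2, 2, 4), order=1)
    # tag the central half as a separate region
    z = mesh.element_centroids()[:, 2]
    mesh.retag(np.flatnonzero((z > 0.5) & (z < 1.5)), "core")
    u_top = 0.05
    fixed_bot = mesh.node_sets["zmin"]
    fixed_top = mesh.node_sets["zmax"]
    fixed_nodes = np.concatenate([fixed_bot, fixed_top])
    fixed = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    energies = []
    for E_core in (50.0, 500.0, 5000.0):
        mats = {"solid": MaterialSpec("solid", 50.0, 0.2),
                "core": MaterialSpec("core", E_core, 0.2)}
        K = fem.assemble_stiffness(mesh, mats)
        u = np.zeros(3 * mesh.n_nodes)
        u[3 * fixed_top + 2] = -u_top
        free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
        import scipy.sparse.linalg as spla
        rhs = -K[free][:, fixed] @ u[fixed]
        u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
        energies.append(0.5 * u @ (K @ u))
    assert energies[0] < energies[1] < energies[2]
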