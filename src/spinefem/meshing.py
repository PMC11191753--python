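"""Template-based tetrahedral meshing of the parametric segment.

The mesher extrudes a structured 2D cross-section template (elliptical
body rings plus prismatic posterior blocks) through the z-layer stack of
the segment.  Prisms are split into tetrahedra with the classic
lowest-global-index diagonal rule, which guarantees a conforming mesh;
all region interfaces share nodes ("fully bound" contacts).  The 2D
template is built for the y>=0 half and mirrored, so the mesh is exactly
symmetric about the mid-sagittal plane whenever the geometry is.

Cement inclusions are realised by re-tagging elements whose centroid falls
inside a cement cylinder (the template is not re-meshed around cement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .anatomy import Layer, SegmentGeometry
from .errors import MeshingError, UnknownRegionError
from .params import MeshSettings, SegmentParams

# 2D cell kinds
BODY, PED, FACET_I, FACET_C, FACET_O, LAM, SPIN, TPROC = range(8)

_UPPER_OF = {"T12L1": "T12", "T11T12": "T11"}
_LOWER_OF = {"T12L1": "L1", "T11T12": "T12"}


@dataclass
class Truss:
    """One axial truss/spring element (ligament or facet contact).

    Ligaments are finite-length tension-only trusses.  Facet contact
    springs are zero-length compression-only penalty elements with an
    explicit ``direction`` (the joint normal) and prescribed ``stiffness``.
    """
    node_i: int                # lower attachment
    node_j: int                # upper attachment
    name: str
    area: float                # mm^2 share of the ligament group
    young_modulus: float
    tension_only: bool = True
    compression_only: bool = False
    stiffness: Optional[float] = None        # N/mm; overrides E*A/L
    direction: Optional[Tuple[float, float, float]] = None


@dataclass
class Mesh:
    """Conforming tetrahedral mesh with region labels and ligament trusses."""

    nodes: np.ndarray                  # (N, 3) mm
    tets: np.ndarray                   # (E, 4) or (E, 10) int32
    region_ids: np.ndarray             # (E,) int16
    region_names: List[str]            # id -> tag
    trusses: List[Truss]
    node_sets: Dict[str, np.ndarray]
    facet_sets: Dict[str, np.ndarray]  # (F, 3) or (F, 6) corner(+mid) ids
    order: int
    n_corner_nodes: int
    meta: dict = field(default_factory=dict)

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def region_id(self, tag: str) -> int:
        try:
            return self.region_names.index(tag)
        except ValueError:
            raise UnknownRegionError(f"no region {tag!r} in mesh") from None

    def elements_in(self, *tags: str) -> np.ndarray:
        ids = [self.region_id(t) for t in tags]
        return np.flatnonzero(np.isin(self.region_ids, ids))

    def region_tags(self) -> Tuple[str, ...]:
        present = np.unique(self.region_ids)
        return tuple(self.region_names[i] for i in present)

    def retag(self, element_idx: np.ndarray, tag: str) -> None:
        if tag not in self.region_names:
            self.region_names.append(tag)
        self.region_ids[element_idx] = self.region_names.index(tag)

    # -- geometry -------------------------------------------------------
    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.tets[:, :4]]

    def element_volumes(self) -> np.ndarray:
        x = self.corner_coords()
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ei,ei->e", d[:, 0],
                         np.cross(d[:, 1], d[:, 2])) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)

    def region_volume(self, tag: str) -> float:
        return float(self.element_volumes()[self.elements_in(tag)].sum())

    def min_dihedral_deg(self) -> float:
        """Smallest dihedral angle over all elements (corner tetrahedra)."""
        x = self.corner_coords()
        faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        normals = []
        for (i, j, k) in faces:
            n = np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            normals.append(n)
        worst = np.pi
        for a in range(4):
            for b in range(a + 1, 4):
                c = np.clip(-np.einsum("ei,ei->e", normals[a], normals[b]),
                            -1.0, 1.0)
                worst = min(worst, float(np.arccos(c).min()))
        return math.degrees(worst)

    def truss_area_sums(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for t in self.trusses:
            out[t.name] = out.get(t.name, 0.0) + t.area
        return out


# ----------------------------------------------------------------------
# 2D template
# ----------------------------------------------------------------------

_MIRROR_KIND = {BODY: BODY, PED: PED, FACET_I: FACET_I, FACET_C: FACET_C,
                FACET_O: FACET_O, LAM: LAM, SPIN: SPIN, TPROC: TPROC}


class _HalfTemplate:
    """y >= 0 half of the cross-section template."""

    def __init__(self):
        self.xy: List[Tuple[float, float]] = []
        self.tris: List[Tuple[int, int, int]] = []
        self.kind: List[int] = []
        self.band: List[int] = []     # ring band for BODY tris; -1 otherwise
        self.anchors: Dict[str, List[int]] = {}

    def node(self, x: float, y: float) -> int:
        if abs(y) < 1e-9:
            y = 0.0
        self.xy.append((float(x), float(y)))
        return len(self.xy) - 1

    def tri(self, a: int, b: int, c: int, kind: int, band: int = -1) -> None:
        self.tris.append((a, b, c))
        self.kind.append(kind)
        self.band.append(band)

    def quad(self, n00, n10, n11, n01, kind, band=-1):
        self.tri(n00, n10, n11, kind, band)
        self.tri(n00, n11, n01, kind, band)

    def anchor(self, name: str, ids: Sequence[int]) -> None:
        self.anchors.setdefault(name, []).extend(int(i) for i in ids)


def _merge_angles(base: np.ndarray, groups: Sequence[Sequence[float]],
                  keep_frac: float = 0.35) -> List[float]:
    """Insert special angle groups into a uniform fan.

    Base angles falling inside a group's span (or too close to a special
    angle) are dropped so that no hanging node appears on the boundary arc
    of a posterior block.
    """
    dt = base[1] - base[0]
    sp = sorted(set(float(s) for g in groups for s in g))
    spans = [(min(g) - 1e-12, max(g) + 1e-12) for g in groups]
    kept = [t for t in base
            if (all(abs(t - s) > keep_frac * dt for s in sp)
                and not any(lo < t < hi for lo, hi in spans))
            or t in (base[0], base[-1])]
    ts = sorted(set(kept) | set(sp) | {float(base[0]), float(base[-1])})
    return ts


def _subdivide(y0: float, y1: float, edge: float) -> List[float]:
    n = max(1, int(round(abs(y1 - y0) / edge)))
    return list(np.linspace(y0, y1, n + 1))


def build_template(geometry: SegmentGeometry,
                   settings: MeshSettings) -> dict:
    """Construct the full (mirrored) 2D template for the segment."""
    params = geometry.params
    sec = geometry.sections["T12"]
    a, b = sec.a, sec.b
    edge = settings.target_edge_solid
    edge_c = settings.target_edge_cartilage
    post = params.posterior
    fac = params.facets

    H = _HalfTemplate()

    # ---- angular samples ----
    half_perim = math.pi * math.sqrt((a * a + b * b) / 2.0)
    n_ang = max(8, int(round(half_perim / edge)))
    base = np.linspace(0.0, math.pi, n_ang + 1)

    # pedicle attachment arc (y descending from lateral to medial)
    y_top = post.pedicle_attach_y[1]
    y_bot = post.pedicle_attach_y[0]
    ys_ped = _subdivide(y_top, y_bot, edge)

    ped_angles = [math.pi - math.asin(min(y / b, 1.0)) for y in ys_ped]
    d = math.radians(post.transverse_arc_deg)
    tp_angles = [math.pi / 2 - d, math.pi / 2, math.pi / 2 + d]
    ts = _merge_angles(base, [ped_angles, tp_angles])
    k_of_angle = {t: i for i, t in enumerate(ts)}
    nk = len(ts)

    # ---- radial levels ----
    nuc = geometry.nuclei["T11T12"]
    r_nuc = nuc.radius_at(np.array(ts))
    r_ci = sec.radius_inner(np.array(ts))
    r_out = sec.radius_outer(np.array(ts))
    rm = float(np.mean(r_nuc))
    n1 = max(2, int(round(rm / edge)))
    n2 = max(1, int(round(float(np.mean(r_ci - r_nuc)) / edge)))
    n3 = max(1, int(round(sec.thickness / edge)))
    fr1 = np.linspace(0, 1, n1 + 1)[1:]
    fr2 = np.linspace(0, 1, n2 + 1)[1:]
    fr3 = np.linspace(0, 1, n3 + 1)[1:]

    center = H.node(0.0, 0.0)
    ring_ids = np.empty((nk, n1 + n2 + n3), dtype=int)
    for k, t in enumerate(ts):
        radii = np.concatenate([
            fr1 * r_nuc[k],
            r_nuc[k] + fr2 * (r_ci[k] - r_nuc[k]),
            r_ci[k] + fr3 * (r_out[k] - r_ci[k])])
        for i, r in enumerate(radii):
            ring_ids[k, i] = H.node(r * math.cos(t), r * math.sin(t))

    def ring_band(level: int) -> int:
        # band of the cell outside radial level index `level` (0-based cell)
        if level < n1:
            return 0          # nucleus / inner cancellous
        if level < n1 + n2:
            return 1          # outer cancellous / annulus
        return 2              # cortical shell / annulus rim

    for k in range(nk - 1):
        H.tri(center, ring_ids[k, 0], ring_ids[k + 1, 0], BODY, 0)
        for i in range(n1 + n2 + n3 - 1):
            H.quad(ring_ids[k, i], ring_ids[k + 1, i],
                   ring_ids[k + 1, i + 1], ring_ids[k, i + 1],
                   BODY, ring_band(i + 1))

    boundary = ring_ids[:, -1]

    # ---- anchors on the body boundary ----
    all_arc = math.radians(post.all_arc_deg)
    H.anchor("ALL", [boundary[k] for k, t in enumerate(ts) if t <= all_arc])
    H.anchor("PLL", [boundary[k] for k, t in enumerate(ts)
                     if t >= math.pi - math.radians(post.pll_arc_deg)])

    # ---- pedicle block with tongue-in-groove facet column (left, y > 0).
    # Marching posteriorly: pedicle bar, then five facet sub-columns
    # [lower plate | cartilage | upper process | cartilage | lower plate]
    # with contact normals along x.
    x_pe = -(a + post.pedicle_length)
    ped_k = [k_of_angle[t] for t in ped_angles]
    arc_pts = [H.xy[boundary[k]] for k in ped_k]
    L_ped = post.pedicle_length
    D = fac.depth_fraction * L_ped
    t_c = fac.cartilage_thickness
    plate = (D - 2 * t_c) / 3.0
    if plate < 0.5:
        raise MeshingError(
            "facet column too shallow for its cartilage layers "
            "(increase depth_fraction or reduce cartilage_thickness)")
    n_main = max(1, int(round((L_ped - D) / edge)))
    alphas = list(np.linspace(0, (L_ped - D) / L_ped, n_main + 1))
    facet_kinds = [FACET_O, FACET_C, FACET_I, FACET_C, FACET_O]
    for depth in (plate, t_c, plate, t_c, plate):
        alphas.append(alphas[-1] + depth / L_ped)
    alphas[-1] = 1.0
    nm = len(alphas)
    ped_ids = np.empty((len(ys_ped), nm), dtype=int)
    for j, (ap, ye) in enumerate(zip(arc_pts, ys_ped)):
        for m, al in enumerate(alphas):
            if m == 0:
                ped_ids[j, m] = boundary[ped_k[j]]
            else:
                x = (1 - al) * ap[0] + al * x_pe
                y = (1 - al) * ap[1] + al * ye
                ped_ids[j, m] = H.node(x, y)
    facet_m0 = n_main  # cells with m-index >= facet_m0 are the joint column
    for j in range(len(ys_ped) - 1):
        for m in range(nm - 1):
            kind = PED if m < facet_m0 else facet_kinds[m - facet_m0]
            H.quad(ped_ids[j, m], ped_ids[j + 1, m],
                   ped_ids[j + 1, m + 1], ped_ids[j, m + 1], kind)
    H.anchor("CL", ped_ids[:, facet_m0:].ravel())

    ped_end = {round(y, 9): int(ped_ids[j, -1]) for j, y in enumerate(ys_ped)}

    # ---- lamina ----
    w_sp = post.spinous_half_width
    ys_mid = [0.0, w_sp] + _subdivide(w_sp, y_bot, edge)[1:-1]
    ys_lam = sorted(set(round(y, 9) for y in ys_mid) | set(ped_end))
    xs_lam = list(np.linspace(x_pe, x_pe - post.lamina_thickness,
                              max(1, int(round(post.lamina_thickness / edge)))
                              + 1))
    lam_ids = np.empty((len(ys_lam), len(xs_lam)), dtype=int)
    for j, y in enumerate(ys_lam):
        for m, x in enumerate(xs_lam):
            if m == 0 and y in ped_end:
                lam_ids[j, m] = ped_end[y]
            else:
                lam_ids[j, m] = H.node(x, y)
    for j in range(len(ys_lam) - 1):
        for m in range(len(xs_lam) - 1):
            H.quad(lam_ids[j, m], lam_ids[j + 1, m],
                   lam_ids[j + 1, m + 1], lam_ids[j, m + 1], LAM)
    H.anchor("LF", [lam_ids[j, 0] for j, y in enumerate(ys_lam)
                    if y < min(ped_end) - 1e-9])

    # ---- spinous process ----
    x_sp0 = xs_lam[-1]
    xs_sp = list(np.linspace(
        x_sp0, x_sp0 - post.spinous_length,
        max(2, int(round(post.spinous_length / edge))) + 1))
    jy = [ys_lam.index(0.0), ys_lam.index(round(w_sp, 9))]
    sp_ids = np.empty((2, len(xs_sp)), dtype=int)
    for jj, j in enumerate(jy):
        for m, x in enumerate(xs_sp):
            sp_ids[jj, m] = lam_ids[j, -1] if m == 0 else H.node(x, ys_lam[j])
    for m in range(len(xs_sp) - 1):
        H.quad(sp_ids[0, m], sp_ids[1, m], sp_ids[1, m + 1], sp_ids[0, m + 1],
               SPIN)
    H.anchor("SSL", sp_ids[:, -1])
    H.anchor("ISL", sp_ids[:, len(xs_sp) // 2])

    # ---- transverse process ----
    tp_k = [k_of_angle[t] for t in tp_angles]
    y_end = b + post.transverse_length
    n_tp = max(1, int(round(post.transverse_length / edge)))
    tp_ids = np.empty((3, n_tp + 1), dtype=int)
    for j, k in enumerate(tp_k):
        apx, apy = H.xy[boundary[k]]
        for m in range(n_tp + 1):
            al = m / n_tp
            if m == 0:
                tp_ids[j, m] = boundary[k]
            else:
                tp_ids[j, m] = H.node((1 - al) * apx + al * 0.5 * apx,
                                      (1 - al) * apy + al * y_end)
    for j in range(2):
        for m in range(n_tp):
            H.quad(tp_ids[j, m], tp_ids[j + 1, m],
                   tp_ids[j + 1, m + 1], tp_ids[j, m + 1], TPROC)
    H.anchor("ITL", tp_ids[:, -1])

    return _mirror_template(H)


def _mirror_template(H: _HalfTemplate) -> dict:
    """Reorder (plane nodes first) and mirror the half template about y=0."""
    xy = np.asarray(H.xy, dtype=float)
    on_plane = np.abs(xy[:, 1]) < 1e-12
    plane_idx = np.flatnonzero(on_plane)
    off_idx = np.flatnonzero(~on_plane)
    P, Hn = len(plane_idx), len(off_idx)
    newid = np.empty(len(xy), dtype=int)
    newid[plane_idx] = np.arange(P)
    newid[off_idx] = P + np.arange(Hn)

    pts = np.empty((P + 2 * Hn, 2))
    pts[:P] = xy[plane_idx]
    pts[P:P + Hn] = xy[off_idx]
    pts[P + Hn:] = xy[off_idx] * np.array([1.0, -1.0])

    def mirror_id(i: int) -> int:
        return i if i < P else i + Hn

    tris, kinds, bands, sides = [], [], [], []
    for (a0, b0, c0), kd, bd in zip(H.tris, H.kind, H.band):
        a1, b1, c1 = (int(newid[a0]), int(newid[b0]), int(newid[c0]))
        tris.append((a1, b1, c1))
        kinds.append(kd)
        bands.append(bd)
        sides.append(+1)
        tris.append((mirror_id(a1), mirror_id(c1), mirror_id(b1)))
        kinds.append(_MIRROR_KIND[kd])
        bands.append(bd)
        sides.append(-1)

    # drop duplicated triangles that lie entirely on the plane (none should)
    tris = np.asarray(tris, dtype=int)
    # enforce CCW orientation
    v = pts[tris]
    cr = ((v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1])
          - (v[:, 1, 1] - v[:, 0, 1]) * (v[:, 2, 0] - v[:, 0, 0]))
    flip = cr < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    anchors: Dict[str, np.ndarray] = {}
    for name, ids in H.anchors.items():
        left = [int(newid[i]) for i in ids]
        right = [mirror_id(i) for i in left]
        if name in ("ITL", "CL"):
            anchors[name + "_L"] = np.unique(left)
            anchors[name + "_R"] = np.unique(right)
        else:
            anchors[name] = np.unique(left + right)

    return {"pts": pts, "tris": tris,
            "kind": np.asarray(kinds, dtype=np.int8),
            "band": np.asarray(bands, dtype=np.int8),
            "side": np.asarray(sides, dtype=np.int8),
            "anchors": anchors}


# ----------------------------------------------------------------------
# prism -> tet splitting (lowest-global-index diagonal rule)
# ----------------------------------------------------------------------

def _prism_permutations() -> np.ndarray:
    rot = (1, 2, 0, 4, 5, 3)
    flip = (3, 5, 4, 0, 2, 1)

    def compose(p, q):
        return tuple(q[i] for i in p)

    perms = []
    p = tuple(range(6))
    for _ in range(3):
        perms.append(p)
        perms.append(compose(flip, p))
        p = compose(rot, p)
    # order by the position each perm brings to slot 0
    table = np.zeros((6, 6), dtype=int)
    for p in perms:
        table[p[0]] = p
    return table


_PERM_TABLE = _prism_permutations()
_TETS_A = np.array([[0, 1, 2, 5], [0, 1, 5, 4], [0, 4, 5, 3]])
_TETS_B = np.array([[0, 1, 2, 4], [0, 4, 2, 5], [0, 4, 5, 3]])


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (P, 6 global ids; bottom tri then top tri) into tets.

    Uses the minimum-vertex rule so that shared quad faces receive the same
    diagonal in both adjacent prisms, yielding a conforming mesh.
    """
    G = np.asarray(prisms, dtype=np.int64)
    pos = np.argmin(G, axis=1)
    perms = _PERM_TABLE[pos]                      # (P, 6)
    Gp = np.take_along_axis(G, perms, axis=1)
    cond = (np.minimum(Gp[:, 1], Gp[:, 5])
            < np.minimum(Gp[:, 2], Gp[:, 4]))
    out = np.empty((G.shape[0], 3, 4), dtype=np.int64)
    out[cond] = Gp[cond][:, _TETS_A]
    out[~cond] = Gp[~cond][:, _TETS_B]
    return out.reshape(-1, 4)


# ----------------------------------------------------------------------
# extrusion
# ----------------------------------------------------------------------

def _sublayers(layers: Sequence[Layer], settings: MeshSettings) -> List[Layer]:
    out: List[Layer] = []
    for L in layers:
        if L.kind in ("cap", "endplate"):
            n = 1
        else:
            n = max(1, int(round(L.height / settings.target_edge_solid)))
        zs = np.linspace(L.z0, L.z1, n + 1)
        for z0, z1 in zip(zs[:-1], zs[1:]):
            out.append(Layer(float(z0), float(z1), L.kind, L.label, L.sub))
    return out


def _region_table(geometry: SegmentGeometry, tpl: dict,
                  sublayers: Sequence[Layer]) -> np.ndarray:
    """Region tag index per (sublayer, tri); -1 means inactive."""
    params = geometry.params
    kinds = tpl["kind"]
    bands = tpl["band"]
    ntri = len(kinds)
    tags: List[str] = []

    def tid(tag: str) -> int:
        if tag not in tags:
            tags.append(tag)
        return tags.index(tag)

    has_post = {v.level_label: v.posterior_element_flag
                for v in params.vertebrae}
    table = np.full((len(sublayers), ntri), -1, dtype=np.int16)
    for li, L in enumerate(sublayers):
        lab = L.label
        row = table[li]
        if L.kind == "disc":
            up, lo = _UPPER_OF[lab], _LOWER_OF[lab]
            body = kinds == BODY
            row[body & (bands == 0)] = tid(f"nucleus_{lab}")
            row[body & (bands > 0)] = tid(f"annulus_{lab}")
            if has_post[up] and has_post[lo]:
                if L.sub in ("middle", "upper"):
                    row[kinds == FACET_I] = tid(f"posterior_{up}")
                if L.sub == "middle":
                    row[kinds == FACET_C] = tid(f"cartilage_{lab}")
                if L.sub in ("lower", "middle"):
                    row[kinds == FACET_O] = tid(f"posterior_{lo}")
        else:
            body = kinds == BODY
            if L.kind == "endplate":
                row[body] = tid(f"endplate_{lab}_{L.sub}")
            elif L.kind == "cap":
                row[body] = tid(f"cortical_{lab}")
            else:
                row[body & (bands == 2)] = tid(f"cortical_{lab}")
                row[body & (bands < 2)] = tid(f"cancellous_{lab}")
            if has_post[lab]:
                row[kinds != BODY] = tid(f"posterior_{lab}")
    return table, tags


def generate_mesh(geometry: SegmentGeometry,
                  settings: Optional[MeshSettings] = None) -> Mesh:
    """Mesh the tagged geometry into TET4/TET10 elements plus ligament trusses."""
    settings = settings or MeshSettings()
    tpl = build_template(geometry, settings)
    subs = _sublayers(geometry.layers, settings)
    table, tags = _region_table(geometry, tpl, subs)

    pts2d = tpl["pts"]
    tris = tpl["tris"]
    n2d = len(pts2d)
    zb = np.array([subs[0].z0] + [L.z1 for L in subs])

    # active prisms
    li_all, ti_all = np.nonzero(table >= 0)
    if li_all.size == 0:
        raise MeshingError("no active regions in extrusion")
    tri_nodes = tris[ti_all]                       # (P, 3)
    bot = li_all[:, None] * n2d + tri_nodes
    top = (li_all[:, None] + 1) * n2d + tri_nodes
    prisms_raw = np.concatenate([bot, top], axis=1)   # (P, 6) raw vertex keys

    used = np.unique(prisms_raw)
    prisms = np.searchsorted(used, prisms_raw)

    layer_idx = used // n2d
    k2d = used % n2d
    nodes = np.column_stack([pts2d[k2d], zb[layer_idx]])

    tets = split_prisms(prisms).astype(np.int32)
    region_ids = np.repeat(table[li_all, ti_all], 3).astype(np.int16)

    # orientation fix
    x = nodes[tets]
    d = x[:, 1:] - x[:, :1]
    vol = np.einsum("ei,ei->e", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    if np.any(np.abs(vol) < 1e-12):
        raise MeshingError("degenerate (zero-volume) element produced; "
                           "region too thin for the requested density")

    n_corner = nodes.shape[0]
    mesh = Mesh(nodes=nodes, tets=tets, region_ids=region_ids,
                region_names=list(tags), trusses=[], node_sets={},
                facet_sets={}, order=settings.element_order,
                n_corner_nodes=n_corner,
                meta={"spans": dict(geometry.spans),
                      "n2d": n2d, "settings": settings})
    elem_kind = np.repeat(tpl["kind"][ti_all], 3)

    # cement re-tagging (centroids of cancellous elements only)
    if geometry.cement:
        cent = mesh.element_centroids()
        for cyl in geometry.cement:
            canc = mesh.elements_in(f"cancellous_{cyl.vertebra}")
            inside = cyl.contains(cent[canc])
            mesh.retag(canc[inside], f"cement_{cyl.vertebra}")

    if geometry.params.facets.mode == "contact":
        _apply_facet_contact(mesh, geometry, elem_kind)

    # quadratic nodes
    edge_lookup = None
    if settings.element_order == 2:
        edge_lookup = _promote_tet10(mesh)

    _build_surface_sets(mesh, geometry, tpl, subs, li_all, ti_all, tets,
                        used, n2d, zb, edge_lookup)
    _build_trusses(mesh, geometry, tpl, subs, used, n2d, zb)
    mesh.meta["n_prisms"] = int(prisms.shape[0])
    return mesh


def _apply_facet_contact(mesh: Mesh, geometry: SegmentGeometry,
                         elem_kind: np.ndarray) -> None:
    """Detach both cartilage layers from the upper articular process and
    insert frictionless compression-only penalty springs across each face.

    The upper process (FACET_I column) sits between an anterior and a
    posterior cartilage layer.  Shared nodes are duplicated (the cartilage
    keeps the copies) and each original/copy pair is linked by a
    zero-length spring along the face normal (+/-x) that acts only in
    closing, so axial rotation engages facet contact while sagittal and
    frontal rotations glide.
    """
    from .materials import material_for
    fac = geometry.params.facets
    E_cart = material_for("cartilage_x").young_modulus
    cent = mesh.element_centroids()
    iplate_all = np.flatnonzero(elem_kind == FACET_I)
    for disc in ("T11T12", "T12L1"):
        tag = f"cartilage_{disc}"
        if tag not in mesh.region_tags():
            continue
        cart_all = mesh.elements_in(tag)
        for side in (+1, -1):
            cart = cart_all[cent[cart_all, 1] * side > 0]
            ipl = iplate_all[cent[iplate_all, 1] * side > 0]
            if cart.size == 0 or ipl.size == 0:
                raise MeshingError(
                    f"no cartilage/plate interface found for {disc}")
            x_i = cent[ipl, 0].mean()
            for col_sign in (+1, -1):   # anterior (+x of process) / posterior
                col = cart[(cent[cart, 0] - x_i) * col_sign > 0]
                shared = np.intersect1d(np.unique(mesh.tets[col, :4]),
                                        np.unique(mesh.tets[ipl, :4]))
                if shared.size == 0:
                    raise MeshingError(
                        f"no cartilage/plate interface found for {disc}")
                new_ids = np.arange(shared.size) + mesh.n_nodes
                mesh.nodes = np.vstack([mesh.nodes, mesh.nodes[shared]])
                mesh.n_corner_nodes = mesh.nodes.shape[0]
                sub = mesh.tets[col]
                for old, new in zip(shared.tolist(), new_ids.tolist()):
                    sub[sub == old] = new
                mesh.tets[col] = sub
                xs = mesh.nodes[shared]
                area = np.ptp(xs[:, 1]) * np.ptp(xs[:, 2])
                k_pair = (fac.penalty_factor * E_cart * area
                          / fac.cartilage_thickness / shared.size)
                name = (f"facet_{disc}_{'L' if side > 0 else 'R'}"
                        f"{'a' if col_sign > 0 else 'p'}")
                for orig, dup in zip(shared.tolist(), new_ids.tolist()):
                    mesh.trusses.append(Truss(
                        node_i=int(orig), node_j=int(dup), name=name,
                        area=area / shared.size, young_modulus=E_cart,
                        tension_only=False, compression_only=True,
                        stiffness=k_pair,
                        direction=(float(col_sign), 0.0, 0.0)))


def _promote_tet10(mesh: Mesh) -> dict:
    tets = mesh.tets
    # VTK TET10 edge order: (0,1),(1,2),(0,2),(0,3),(1,3),(2,3)
    pairs = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])
    e = tets[:, pairs]                             # (E, 6, 2)
    e = np.sort(e, axis=2).reshape(-1, 2).astype(np.int64)
    key = e[:, 0] * mesh.n_corner_nodes + e[:, 1]
    uniq, inv = np.unique(key, return_inverse=True)
    mid_xyz = 0.5 * (mesh.nodes[uniq // mesh.n_corner_nodes]
                     + mesh.nodes[uniq % mesh.n_corner_nodes])
    mid_ids = mesh.n_corner_nodes + inv.reshape(-1, 6)
    mesh.nodes = np.vstack([mesh.nodes, mid_xyz])
    mesh.tets = np.hstack([tets, mid_ids.astype(np.int32)])
    return {"uniq": uniq, "n_corner": mesh.n_corner_nodes}


def _edge_mid(edge_lookup, i: int, j: int) -> int:
    lo, hi = (i, j) if i < j else (j, i)
    key = lo * edge_lookup["n_corner"] + hi
    pos = np.searchsorted(edge_lookup["uniq"], key)
    if pos >= len(edge_lookup["uniq"]) or edge_lookup["uniq"][pos] != key:
        raise MeshingError("facet edge not present in the tet mesh")
    return edge_lookup["n_corner"] + int(pos)


def _compress_lookup(used: np.ndarray):
    def look(raw_ids: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(used, raw_ids)
        bad = (pos >= len(used)) | (used[np.minimum(pos, len(used) - 1)]
                                    != raw_ids)
        if np.any(bad):
            raise MeshingError("inactive template vertex referenced")
        return pos
    return look


def _build_surface_sets(mesh, geometry, tpl, subs, li_all, ti_all, tets,
                        used, n2d, zb, edge_lookup) -> None:
    look = _compress_lookup(used)
    tris = tpl["tris"]
    kinds = tpl["kind"]

    def face_group(boundary_index: int, from_below: bool) -> np.ndarray:
        """Corner facets of BODY prisms touching a z-boundary index."""
        li = boundary_index - 1 if from_below else boundary_index
        sel = (li_all == li) & (kinds[ti_all] == BODY)
        tn = tris[ti_all[sel]]
        raw = boundary_index * n2d + tn
        return look(raw)

    n_bound = len(zb) - 1
    top_facets = face_group(n_bound, from_below=True)
    if mesh.order == 2:
        mids = np.empty_like(top_facets)
        for r, (a, b, c) in enumerate(top_facets):
            mids[r] = [_edge_mid(edge_lookup, a, b),
                       _edge_mid(edge_lookup, b, c),
                       _edge_mid(edge_lookup, a, c)]
        mesh.facet_sets["T11_superior"] = np.hstack([top_facets, mids])
    else:
        mesh.facet_sets["T11_superior"] = top_facets
    mesh.node_sets["T11_superior"] = np.unique(
        mesh.facet_sets["T11_superior"])

    z0 = zb[0]
    mesh.node_sets["L1_inferior"] = np.flatnonzero(
        np.abs(mesh.nodes[:, 2] - z0) < 1e-9)

    # superior body-face node sets per vertebra (for ROM rigid fits)
    spans = geometry.spans
    for v in ("T11", "T12", "L1"):
        z_top = spans[v][1]
        bi = int(np.argmin(np.abs(zb - z_top)))
        if abs(zb[bi] - z_top) > 1e-9:
            raise MeshingError(f"no layer boundary at top of {v}")
        f = face_group(bi, from_below=True)
        mesh.node_sets[f"{v}_superior_face"] = np.unique(f)

    cart = [t for t in mesh.region_names if t.startswith("cartilage")]
    if cart:
        el = mesh.elements_in(*[t for t in cart
                                if t in mesh.region_tags()])
        mesh.node_sets["facet_surfaces"] = np.unique(mesh.tets[el, :4])


def _build_trusses(mesh, geometry, tpl, subs, used, n2d, zb) -> None:
    look = _compress_lookup(used)
    params = geometry.params
    spans = geometry.spans
    anchors = tpl["anchors"]

    anchor_sets = {
        "ALL": [anchors["ALL"]],
        "PLL": [anchors["PLL"]],
        "LF": [anchors["LF"]],
        "SSL": [anchors["SSL"]],
        "ISL": [anchors["ISL"]],
        "ITL": [anchors["ITL_L"], anchors["ITL_R"]],
        "CL": [anchors["CL_L"], anchors["CL_R"]],
    }

    def snap(z: float, lo: float, hi: float) -> float:
        zc = np.clip(z, lo, hi)
        cand = zb[(zb >= lo - 1e-9) & (zb <= hi + 1e-9)]
        return float(cand[np.argmin(np.abs(cand - zc))])

    def bidx(z: float) -> int:
        i = int(np.argmin(np.abs(zb - z)))
        return i

    for disc in ("T11T12", "T12L1"):
        up, lo_v = _UPPER_OF[disc], _LOWER_OF[disc]
        dz0, dz1 = spans[disc]
        for spec in params.ligaments:
            hv_up = params.vertebra(up).body_height
            hv_lo = params.vertebra(lo_v).body_height
            z_up = snap(dz1 + spec.attachment_inset * hv_up, *spans[up])
            z_lo = snap(dz0 - spec.attachment_inset * hv_lo, *spans[lo_v])
            groups = anchor_sets[spec.name]
            ids2d = np.concatenate(groups)
            n = len(ids2d)
            share = spec.total_area / n
            up_nodes = look(bidx(z_up) * n2d + ids2d)
            lo_nodes = look(bidx(z_lo) * n2d + ids2d)
            for ni, nj in zip(lo_nodes, up_nodes):
                mesh.trusses.append(Truss(int(ni), int(nj), spec.name,
                                          share, spec.young_modulus,
                                          spec.tension_only))


# ----------------------------------------------------------------------
# simple box meshes for verification problems
# ----------------------------------------------------------------------

def box_mesh(lengths: Tuple[float, float, float],
             divisions: Tuple[int, int, int],
             order: int = 1, origin=(0.0, 0.0, 0.0)) -> Mesh:
    """Structured tetrahedral mesh of a box (verification utility)."""
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    pts2d = np.array([(x, y) for y in ys for x in xs])
    nid = lambda i, j: j * (nx + 1) + i
    tris = []
    for j in range(ny):
        for i in range(nx):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    tris = np.asarray(tris)
    n2d = len(pts2d)
    prisms = []
    for l in range(nz):
        for t in tris:
            prisms.append(np.concatenate([l * n2d + t, (l + 1) * n2d + t]))
    prisms = np.asarray(prisms)
    used = np.unique(prisms)
    pr = np.searchsorted(used, prisms)
    nodes = np.column_stack([pts2d[used % n2d], zs[used // n2d]])
    tets = split_prisms(pr).astype(np.int32)
    x = nodes[tets]
    d = x[:, 1:] - x[:, :1]
    vol = np.einsum("ei,ei->e", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0
    tets[vol < 0] = tets[vol < 0][:, [0, 1, 3, 2]]
    mesh = Mesh(nodes=nodes, tets=tets,
                region_ids=np.zeros(len(tets), dtype=np.int16),
                region_names=["solid"], trusses=[], node_sets={},
                facet_sets={}, order=order, n_corner_nodes=len(nodes),
                meta={"box": lengths})
    if order == 2:
        _promote_tet10(mesh)
    # named faces
    tol = 1e-9
    for name, axis, val in (("xmin", 0, origin[0]), ("xmax", 0, origin[0] + lx),
                            ("ymin", 1, origin[1]), ("ymax", 1, origin[1] + ly),
                            ("zmin", 2, origin[2]), ("zmax", 2, origin[2] + lz)):
        mesh.node_sets[name] = np.flatnonzero(
            np.abs(mesh.nodes[:, axis] - val) < tol)
    # top-surface corner facets (for pressure loading in tests)
    topb = nz * n2d
    raw = np.asarray([topb + t for t in tris])
    mesh.facet_sets["zmax"] = np.searchsorted(used, raw)
    if order == 2:
        pairs = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])
        e = np.sort(mesh.tets[:, :4][:, pairs], axis=2).reshape(-1, 2)
        el = {"uniq": np.unique(e[:, 0].astype(np.int64)
                                * mesh.n_corner_nodes + e[:, 1]),
              "n_corner": mesh.n_corner_nodes}
        f = mesh.facet_sets["zmax"]
        mids = np.empty_like(f)
        for r, (a, b, c) in enumerate(f):
            mids[r] = [_edge_mid(el, a, b), _edge_mid(el, b, c),
                       _edge_mid(el, a, c)]
        mesh.facet_sets["zmax"] = np.hstack([f, mids])
    return mesh
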