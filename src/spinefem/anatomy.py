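"""Parametric T11-L1 segment geometry.

This module is the synthetic stand-in for a CT-derived spine model.  Each
vertebral body is an elliptical cylinder with a 1.5 mm cortical shell,
cortical end caps on the free surfaces and 0.5 mm endplates on every
disc-facing surface; discs are annulus rings around a posteriorly offset
nucleus; posterior elements (pedicles, lamina, spinous and transverse
processes) are prismatic blocks carrying cortical properties; facet joints
are vertical articular plates bonded through a sagittally oriented
cartilage layer.  Cement inclusions are vertical elliptical cylinders
placed inside the cancellous bone of T11 and L1.

The geometry is fully described by :class:`~spinefem.params.SegmentParams`
plus a list of cement cylinders; everything downstream (meshing, volumes,
symmetry checks) is derived deterministically from that description.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidParameterError, InvalidPlanError
from .params import (CementPlan, DISC_LEVELS, SegmentParams, VERTEBRA_LEVELS)

#: axial margin (mm) between a cement cylinder and the cancellous cavity
#: end faces.  Zero by default: vertebroplasty cement is placed in contact
#: with both endplates (fully bound interface), which restores the axial
#: load path through the augmented body.
CEMENT_MARGIN = 0.0


class EllipseSection:
    """Outer cross-section of a vertebral body with its cortical inner offset.

    The cortical inner boundary is the true inward parallel curve of the
    ellipse at distance ``thickness`` so the shell is exactly that thick
    everywhere on a transverse plane.
    """

    def __init__(self, a: float, b: float, thickness: float, n_dense: int = 2048):
        self.a = float(a)          # x (anterior-posterior) semi-axis
        self.b = float(b)          # y (lateral) semi-axis
        self.thickness = float(thickness)
        u = np.linspace(0.0, math.pi, n_dense)
        x, y = a * np.cos(u), b * np.sin(u)
        # unit outward normal of the ellipse
        nx, ny = np.cos(u) / a, np.sin(u) / b
        nn = np.hypot(nx, ny)
        xi, yi = x - thickness * nx / nn, y - thickness * ny / nn
        th = np.arctan2(yi, xi)
        th[0], th[-1] = 0.0, math.pi          # guard endpoint round-off
        ri = np.hypot(xi, yi)
        order = np.argsort(th)
        self._th, self._ri = th[order], ri[order]
        if np.any(self._ri <= 0):
            raise InvalidParameterError("cortical offset curve degenerate")

    def radius_outer(self, theta) -> np.ndarray:
        theta = np.abs(np.asarray(theta, dtype=float))
        c, s = np.cos(theta), np.sin(theta)
        return 1.0 / np.sqrt((c / self.a) ** 2 + (s / self.b) ** 2)

    def radius_inner(self, theta) -> np.ndarray:
        """Polar radius of the cortical inner boundary (mirror symmetric)."""
        theta = np.asarray(theta, dtype=float)
        theta = np.abs((theta + math.pi) % (2 * math.pi) - math.pi)
        return np.interp(theta, self._th, self._ri)

    def distance_to_outer(self, pts: np.ndarray) -> np.ndarray:
        """Euclidean distance from 2D points to the outer ellipse (dense)."""
        u = np.linspace(0.0, 2 * math.pi, 4096, endpoint=False)
        bd = np.column_stack([self.a * np.cos(u), self.b * np.sin(u)])
        d = np.linalg.norm(pts[:, None, :] - bd[None, :, :], axis=2)
        return d.min(axis=1)

    def contains(self, pts: np.ndarray, inner: bool = False) -> np.ndarray:
        th = np.arctan2(pts[:, 1], pts[:, 0])
        r = np.hypot(pts[:, 0], pts[:, 1])
        lim = self.radius_inner(th) if inner else self.radius_outer(th)
        return r <= lim

    def area_outer(self) -> float:
        return math.pi * self.a * self.b

    def area_inner(self) -> float:
        # polygon area of the dense inner offset curve (half, mirrored)
        th = np.concatenate([self._th, (2 * math.pi - self._th[::-1])[1:-1]])
        r = np.concatenate([self._ri, self._ri[::-1][1:-1]])
        x, y = r * np.cos(th), r * np.sin(th)
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class NucleusSection:
    """Nucleus boundary: scaled ellipse, posteriorly offset."""

    def __init__(self, a_out: float, b_out: float, area_fraction: float,
                 offset: float):
        s = math.sqrt(area_fraction)
        self.a = s * a_out
        self.b = s * b_out
        self.x0 = -float(offset)   # posterior = -x

    def radius_at(self, theta) -> np.ndarray:
        """Radius along a ray from the body centre (origin) at angle theta."""
        theta = np.asarray(theta, dtype=float)
        c, s = np.cos(theta), np.sin(theta)
        # ((r c - x0)/a)^2 + (r s / b)^2 = 1 ; positive root
        A = (c / self.a) ** 2 + (s / self.b) ** 2
        B = -2.0 * self.x0 * c / self.a ** 2
        C = (self.x0 / self.a) ** 2 - 1.0
        disc = B ** 2 - 4 * A * C
        if np.any(disc <= 0):
            raise InvalidParameterError("nucleus does not enclose body centre")
        return (-B + np.sqrt(disc)) / (2 * A)

    def area(self) -> float:
        return math.pi * self.a * self.b


@dataclass(frozen=True)
class CementCylinder:
    """One vertical elliptical cement cylinder inside a vertebral body."""

    vertebra: str
    side: str                 # 'left' | 'right' | 'midline'
    center: Tuple[float, float, float]
    radius_x: float
    radius_y: float
    height: float

    @property
    def volume(self) -> float:
        return math.pi * self.radius_x * self.radius_y * self.height

    def contains(self, pts: np.ndarray) -> np.ndarray:
        x0, y0, z0 = self.center
        inz = np.abs(pts[:, 2] - z0) <= self.height / 2
        inxy = (((pts[:, 0] - x0) / self.radius_x) ** 2
                + ((pts[:, 1] - y0) / self.radius_y) ** 2) <= 1.0
        return inz & inxy

    def mirrored(self) -> "CementCylinder":
        side = {"left": "right", "right": "left", "midline": "midline"}[self.side]
        x0, y0, z0 = self.center
        return CementCylinder(self.vertebra, side, (x0, -y0, z0),
                              self.radius_x, self.radius_y, self.height)

    def boundary_points(self, n: int = 256) -> np.ndarray:
        phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
        x0, y0, _ = self.center
        return np.column_stack([x0 + self.radius_x * np.cos(phi),
                                y0 + self.radius_y * np.sin(phi)])


@dataclass(frozen=True)
class Layer:
    """One z-slab of the extruded model."""
    z0: float
    z1: float
    kind: str          # 'cap' | 'interior' | 'endplate' | 'disc'
    label: str         # vertebra or disc level
    sub: str = ""      # endplate: 'sup'/'inf'; disc band: 'lower'/'middle'/'upper'

    @property
    def height(self) -> float:
        return self.z1 - self.z0


def _build_layout(params: SegmentParams) -> Tuple[Tuple[Layer, ...],
                                                  Dict[str, Tuple[float, float]]]:
    """Stack L1, disc T12L1, T12, disc T11T12, T11 from z=0 upward."""
    layers: List[Layer] = []
    spans: Dict[str, Tuple[float, float]] = {}
    z = 0.0
    order = ["L1", "T12L1", "T12", "T11T12", "T11"]
    for name in order:
        if name in VERTEBRA_LEVELS:
            v = params.vertebra(name)
            z0, z1 = z, z + v.body_height
            spans[name] = (z0, z1)
            t_cap, t_ep = v.cortical_thickness, v.endplate_thickness
            if name == "L1":
                layers.append(Layer(z0, z0 + t_cap, "cap", name))
                layers.append(Layer(z0 + t_cap, z1 - t_ep, "interior", name))
                layers.append(Layer(z1 - t_ep, z1, "endplate", name, "sup"))
            elif name == "T12":
                layers.append(Layer(z0, z0 + t_ep, "endplate", name, "inf"))
                layers.append(Layer(z0 + t_ep, z1 - t_ep, "interior", name))
                layers.append(Layer(z1 - t_ep, z1, "endplate", name, "sup"))
            else:  # T11
                layers.append(Layer(z0, z0 + t_ep, "endplate", name, "inf"))
                layers.append(Layer(z0 + t_ep, z1 - t_cap, "interior", name))
                layers.append(Layer(z1 - t_cap, z1, "cap", name))
            z = z1
        else:
            d = params.disc(name)
            z0, z1 = z, z + d.height
            spans[name] = (z0, z1)
            ov = params.facets.overlap_fraction
            lo = z0 + d.height * (1 - ov) / 2
            hi = z1 - d.height * (1 - ov) / 2
            layers.append(Layer(z0, lo, "disc", name, "lower"))
            layers.append(Layer(lo, hi, "disc", name, "middle"))
            layers.append(Layer(hi, z1, "disc", name, "upper"))
            z = z1
    return tuple(layers), spans


def _cancellous_span(params: SegmentParams, level: str,
                     spans: Dict[str, Tuple[float, float]]) -> Tuple[float, float]:
    v = params.vertebra(level)
    z0, z1 = spans[level]
    if level == "L1":
        return z0 + v.cortical_thickness, z1 - v.endplate_thickness
    if level == "T11":
        return z0 + v.endplate_thickness, z1 - v.cortical_thickness
    return z0 + v.endplate_thickness, z1 - v.endplate_thickness


class SegmentGeometry:
    """Tagged parametric geometry of the T11-L1 segment.

    Use :func:`build_segment` to construct and
    :func:`place_cement` to add cement inclusions.
    """

    def __init__(self, params: SegmentParams,
                 cement: Tuple[CementCylinder, ...] = ()):
        self.params = params
        self.cement = tuple(cement)
        self.layers, self.spans = _build_layout(params)
        self.sections: Dict[str, EllipseSection] = {}
        self.nuclei: Dict[str, NucleusSection] = {}
        for v in params.vertebrae:
            self.sections[v.level_label] = EllipseSection(
                v.body_width_ap / 2, v.body_width_lat / 2, v.cortical_thickness)
        # discs share the footprint of the (identical) adjacent bodies
        ref = params.vertebrae[0]
        for name, d in zip(DISC_LEVELS, params.discs):
            self.nuclei[name] = NucleusSection(
                ref.body_width_ap / 2, ref.body_width_lat / 2,
                d.nucleus_area_fraction, d.nucleus_center_offset)
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        p = self.params
        widths = {(v.body_width_ap, v.body_width_lat) for v in p.vertebrae}
        if len(widths) != 1:
            raise InvalidParameterError(
                "vertebral bodies must share a footprint for a conforming "
                "column (differing body widths)")
        d0, d1 = p.discs
        if (d0.nucleus_area_fraction != d1.nucleus_area_fraction
                or d0.nucleus_center_offset != d1.nucleus_center_offset):
            raise InvalidParameterError(
                "discs must share nucleus geometry (the column template "
                "uses one nucleus ring boundary)")
        sec = self.sections["T12"]
        for name, nuc in self.nuclei.items():
            th = np.linspace(0, math.pi, 181)
            if np.any(nuc.radius_at(th) >= sec.radius_inner(th) - 1e-9):
                raise InvalidParameterError(
                    f"regions overlap: nucleus_{name} intersects the "
                    f"cortical shell")
        post = p.posterior
        y1 = post.pedicle_attach_y[1]
        if y1 >= sec.b - 1e-9:
            raise InvalidParameterError(
                "regions conflict: pedicle attachment exceeds body width")
        f = p.facets
        if (f.depth_fraction * post.pedicle_length
                <= 2 * f.cartilage_thickness + 1.0):
            raise InvalidParameterError(
                "regions conflict: facet column too shallow for its "
                "cartilage layers")
        for cyl in self.cement:
            self._check_cement_fit(cyl)

    def _check_cement_fit(self, cyl: CementCylinder) -> None:
        sec = self.sections[cyl.vertebra]
        zlo, zhi = _cancellous_span(self.params, cyl.vertebra, self.spans)
        x0, y0, z0 = cyl.center
        if (z0 - cyl.height / 2 < zlo - 1e-9
                or z0 + cyl.height / 2 > zhi + 1e-9):
            raise InvalidPlanError(
                f"cement in {cyl.vertebra} exceeds the cancellous cavity "
                f"axially")
        bd = cyl.boundary_points()
        th = np.arctan2(bd[:, 1], bd[:, 0])
        r = np.hypot(bd[:, 0], bd[:, 1])
        if np.any(r > sec.radius_inner(th) + 1e-9):
            raise InvalidPlanError(
                f"cement cylinder ({cyl.vertebra}, {cyl.side}) would "
                f"intersect the cortical shell")

    # -- derived quantities --------------------------------------------
    @property
    def total_height(self) -> float:
        return self.layers[-1].z1

    def solids(self) -> Tuple[str, ...]:
        tags: List[str] = []
        for v in VERTEBRA_LEVELS:
            tags += [f"cortical_{v}", f"cancellous_{v}"]
            if self.params.vertebra(v).posterior_element_flag:
                tags.append(f"posterior_{v}")
        tags += ["endplate_L1_sup", "endplate_T12_inf", "endplate_T12_sup",
                 "endplate_T11_inf"]
        for d in DISC_LEVELS:
            tags += [f"annulus_{d}", f"nucleus_{d}", f"cartilage_{d}"]
        for cyl in self.cement:
            t = f"cement_{cyl.vertebra}"
            if t not in tags:
                tags.append(t)
        return tuple(tags)

    def cortical_thickness_samples(self, level: str = "T12",
                                   n: int = 64) -> np.ndarray:
        """Shell thickness sampled on the mid-transverse plane.

        Measured as the distance from points on the cortical inner boundary
        to the outer ellipse; equals the prescribed thickness by
        construction of the parallel curve.
        """
        sec = self.sections[level]
        th = np.linspace(0, 2 * math.pi, n, endpoint=False)
        r = sec.radius_inner(th)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        return sec.distance_to_outer(pts)

    def endplate_thicknesses(self) -> Dict[str, float]:
        return {f"endplate_{l.label}_{l.sub}": l.height
                for l in self.layers if l.kind == "endplate"}

    def cement_volume_report(self) -> Dict[str, float]:
        """Analytic cement volume per augmented vertebra, in mL."""
        out: Dict[str, float] = {}
        for cyl in self.cement:
            out[cyl.vertebra] = out.get(cyl.vertebra, 0.0) + cyl.volume / 1000.0
        return out

    def region_volumes(self) -> Dict[str, float]:
        """Analytic volumes (mm^3) of the main tagged regions.

        Posterior-element and facet volumes are reported by the mesh (they
        are prism blocks whose exact volume the template mesher preserves);
        this method covers the analytically defined solids of revolution.
        """
        out: Dict[str, float] = {}
        sec = self.sections["T12"]
        a_out, a_in = sec.area_outer(), sec.area_inner()
        for v in VERTEBRA_LEVELS:
            zc0, zc1 = _cancellous_span(self.params, v, self.spans)
            vp = self.params.vertebra(v)
            z0, z1 = self.spans[v]
            cap_h = vp.body_height - (zc1 - zc0) - vp.endplate_thickness * (
                2 if v == "T12" else 1)
            out[f"cancellous_{v}"] = a_in * (zc1 - zc0)
            out[f"cortical_{v}"] = (a_out - a_in) * (zc1 - zc0) + a_out * cap_h
        for l in self.layers:
            if l.kind == "endplate":
                out[f"endplate_{l.label}_{l.sub}"] = a_out * l.height
        for d in DISC_LEVELS:
            z0, z1 = self.spans[d]
            nuc_a = self.nuclei[d].area()
            out[f"nucleus_{d}"] = nuc_a * (z1 - z0)
            out[f"annulus_{d}"] = (a_out - nuc_a) * (z1 - z0)
        for cyl in self.cement:
            tag = f"cement_{cyl.vertebra}"
            out[tag] = out.get(tag, 0.0) + cyl.volume
            out[f"cancellous_{cyl.vertebra}"] -= cyl.volume
        return out

    # -- transforms -----------------------------------------------------
    def mirrored(self) -> "SegmentGeometry":
        """Reflection about the mid-sagittal plane y=0."""
        return SegmentGeometry(self.params,
                               tuple(c.mirrored() for c in self.cement))

    def describe(self) -> dict:
        """Canonical, deterministic description of the tagged geometry."""
        from dataclasses import asdict
        return {
            "params": asdict_params(self.params),
            "cement": [
                {"vertebra": c.vertebra, "side": c.side,
                 "center": [round(v, 12) for v in c.center],
                 "radius_x": round(c.radius_x, 12),
                 "radius_y": round(c.radius_y, 12),
                 "height": round(c.height, 12)}
                for c in sorted(self.cement,
                                key=lambda c: (c.vertebra, c.side, c.center[1]))
            ],
            "layers": [[l.z0, l.z1, l.kind, l.label, l.sub]
                       for l in self.layers],
        }


def asdict_params(params: SegmentParams) -> dict:
    from dataclasses import asdict
    d = asdict(params)

    def scrub(obj):
        if isinstance(obj, dict):
            return {k: scrub(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [scrub(v) for v in obj]
        return obj

    return scrub(d)


def build_segment(params: Optional[SegmentParams] = None) -> SegmentGeometry:
    """Assemble the tagged T11-L1 geometry (no cement).

    Raises :class:`InvalidParameterError` naming the colliding regions when
    the dimensions are inconsistent.
    """
    return SegmentGeometry(params or SegmentParams())


def _scaled_cylinder(dims: Tuple[float, float, float], target_mm3: float,
                     h_max: float) -> Tuple[float, float, float]:
    """Volume-controlled scaling of a printed cylinder bounding box.

    The box is first scaled isotropically to the target volume; the height
    is then stretched (or capped) to the cancellous cavity height so that
    the cement column contacts both endplates -- the fully-bound,
    load-carrying configuration of vertebroplasty cement -- and the radius
    is rescaled to keep the volume exact.
    """
    rx, ry, h = dims[0] / 2.0, dims[1] / 2.0, dims[2]
    v0 = math.pi * rx * ry * h
    s = (target_mm3 / v0) ** (1.0 / 3.0)
    rx, ry = rx * s, ry * s
    h = h_max
    sr = math.sqrt(target_mm3 / (math.pi * rx * ry * h))
    return rx * sr, ry * sr, h


def place_cement(geometry: SegmentGeometry, plan: CementPlan) -> SegmentGeometry:
    """Add cement cylinders per the plan; returns a new geometry.

    Bilateral placement yields two cylinders mirror-symmetric about y=0
    sharing the per-vertebra target volume; unilateral placement yields one
    cylinder with its centroid offset toward the chosen side (left = +y).
    """
    if geometry.cement:
        raise InvalidPlanError("geometry already contains cement regions")
    target = plan.target_total_volume * 1000.0  # mL -> mm^3
    cylinders: List[CementCylinder] = []
    for vert, mode in sorted(plan.placement.items()):
        sec = geometry.sections[vert]
        zlo, zhi = _cancellous_span(geometry.params, vert, geometry.spans)
        zc = 0.5 * (zlo + zhi)
        h_max = (zhi - zlo) - 2 * CEMENT_MARGIN
        if h_max <= 0:
            raise InvalidPlanError(f"no cancellous cavity in {vert}")
        if mode == "bilateral":
            rx, ry, h = _scaled_cylinder(plan.bilateral_dims, target / 2, h_max)
            off = plan.bilateral_offset_fraction * sec.b
            if off < ry:
                raise InvalidPlanError(
                    f"bilateral cement cylinders in {vert} overlap at the "
                    f"midline (offset {off:.2f} < radius {ry:.2f})")
            for sgn, side in ((+1, "left"), (-1, "right")):
                cylinders.append(CementCylinder(
                    vert, side, (0.0, sgn * off, zc), rx, ry, h))
        else:
            rx, ry, h = _scaled_cylinder(plan.unilateral_dims, target, h_max)
            sgn = +1 if mode == "left" else -1
            # unilateral cement stays on its side of the midline: the
            # centroid offset is at least the cylinder radius
            off = max(plan.unilateral_offset_fraction * sec.b, ry)
            cylinders.append(CementCylinder(
                vert, mode, (0.0, sgn * off, zc), rx, ry, h))
    return SegmentGeometry(geometry.params, tuple(cylinders))
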