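"""Parameter types for the parametric T11-L1 segment.

All lengths are millimetres, forces Newtons, moduli MPa.  The segment
coordinate frame is +x anterior, +y subject-left, +z superior, with the
origin at the centre of the L1 inferior surface.

The shipped defaults are the calibrated desk-scale model: body and disc
dimensions were tuned once against the published range-of-motion corridor
for a T11-L1 segment under a 7.5 N·m moment (see docs/methods.md) and are
frozen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .errors import InvalidParameterError

VERTEBRA_LEVELS = ("T11", "T12", "L1")
DISC_LEVELS = ("T11T12", "T12L1")
LIGAMENT_NAMES = ("ALL", "PLL", "LF", "SSL", "ISL", "ITL", "CL")

#: Ligament cross-sectional areas (mm^2), standard literature values for the
#: thoracolumbar junction.  One entry per ligament group; paired ligaments
#: (LF, ITL, CL) carry the total area split across both sides.
LIGAMENT_AREAS = {
    "ALL": 65.0,
    "PLL": 20.0,
    "LF": 40.0,
    "SSL": 30.0,
    "ISL": 40.0,
    "ITL": 1.8,
    "CL": 30.0,
}

#: Ligament Young's moduli (MPa), matching the material table in materials.py.
LIGAMENT_MODULI = {
    "ALL": 20.0,
    "PLL": 20.0,
    "LF": 19.5,
    "SSL": 15.0,
    "ISL": 12.0,
    "ITL": 59.0,
    "CL": 7.5,
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class VertebraParams:
    """Idealised vertebral body: an elliptical cylinder with posterior elements."""

    level_label: str = "T12"
    body_width_ap: float = 32.0       # anterior-posterior outer diameter
    body_width_lat: float = 42.0      # lateral outer diameter
    body_height: float = 24.0
    cortical_thickness: float = 1.5
    endplate_thickness: float = 0.5
    posterior_element_flag: bool = True

    def __post_init__(self):
        _require(self.level_label in VERTEBRA_LEVELS,
                 f"unknown vertebra level {self.level_label!r}")
        for name in ("body_width_ap", "body_width_lat", "body_height",
                     "cortical_thickness", "endplate_thickness"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.cortical_thickness
                 < min(self.body_width_ap, self.body_width_lat) / 4,
                 "cortical_thickness too large for body widths")
        _require(self.endplate_thickness < self.body_height / 4,
                 "endplate_thickness too large for body height")


@dataclass(frozen=True)
class DiscParams:
    """Intervertebral disc: annulus matrix around a posteriorly-offset nucleus."""

    height: float = 6.3
    nucleus_area_fraction: float = 0.30
    nucleus_center_offset: float = 0.0  # posterior offset of nucleus centroid

    def __post_init__(self):
        _require(self.height > 0, "disc height must be > 0")
        _require(0.0 < self.nucleus_area_fraction < 1.0,
                 "nucleus_area_fraction must lie in (0, 1)")
        _require(self.nucleus_center_offset >= 0,
                 "nucleus_center_offset must be >= 0")


@dataclass(frozen=True)
class LigamentSpec:
    """One ligament group modelled as tension-only trusses.

    ``attachment_pairs`` is filled by the mesh engine with the realised
    (upper point, lower point) coordinate pairs; at specification time it
    may be empty.  ``attachment_inset`` moves the anchors away from the disc
    boundary into the vertebra by this fraction of the body height, which
    sets the free length of the trusses.
    """

    name: str
    total_area: float
    young_modulus: float
    tension_only: bool = True
    attachment_inset: float = 0.0
    attachment_pairs: Tuple[Tuple[Tuple[float, float, float],
                                  Tuple[float, float, float]], ...] = ()

    def __post_init__(self):
        _require(self.name in LIGAMENT_NAMES,
                 f"unknown ligament {self.name!r}")
        _require(self.total_area > 0, "ligament total_area must be > 0")
        _require(self.young_modulus > 0, "ligament modulus must be > 0")
        _require(0.0 <= self.attachment_inset < 0.5,
                 "attachment_inset must lie in [0, 0.5)")


def default_ligaments() -> Tuple[LigamentSpec, ...]:
    """The seven ligament groups with standard areas and moduli."""
    insets = {"ALL": 0.0, "PLL": 0.45, "LF": 0.49, "SSL": 0.49,
              "ISL": 0.49, "ITL": 0.25, "CL": 0.45}
    return tuple(
        LigamentSpec(name=n, total_area=LIGAMENT_AREAS[n],
                     young_modulus=LIGAMENT_MODULI[n],
                     attachment_inset=insets[n])
        for n in LIGAMENT_NAMES
    )


@dataclass(frozen=True)
class PosteriorParams:
    """Simplified posterior elements: pedicle bars, lamina, spinous and
    transverse processes, all prisms carrying cortical bone properties."""

    pedicle_length: float = 9.0        # body wall to lamina anterior face
    pedicle_attach_y: Tuple[float, float] = (10.0, 19.0)
    lamina_thickness: float = 3.0       # anterior-posterior
    spinous_length: float = 6.0
    spinous_half_width: float = 2.0
    transverse_length: float = 12.0
    transverse_arc_deg: float = 12.0    # half-opening of the attachment arc
    all_arc_deg: float = 45.0           # anterior longitudinal lig. arc
    pll_arc_deg: float = 30.0           # posterior longitudinal lig. arc

    def __post_init__(self):
        for name in ("pedicle_length", "lamina_thickness", "spinous_length",
                     "spinous_half_width", "transverse_length",
                     "transverse_arc_deg"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 < self.pedicle_attach_y[0] < self.pedicle_attach_y[1],
                 "pedicle_attach_y must be increasing and positive")


@dataclass(frozen=True)
class FacetParams:
    """Facet joint idealisation: a tongue-in-groove articular column.

    On each side, the inferior articular process of the upper vertebra (a
    vertical plate) slots between two plates of the lower vertebra, with a
    cartilage layer on each face.  The contact normals point along +/-x
    (anterior-posterior), so axial rotation closes one face of each joint
    and is resisted through cartilage compression, while
    flexion/extension and lateral bending let the plates glide -- the
    anatomical selectivity of zygapophyseal joints.

    In the default ``contact`` mode the cartilage faces adjacent to the
    upper process are detached and carry frictionless compression-only
    penalty springs; ``bonded`` ties all faces (shared nodes).
    """

    cartilage_thickness: float = 0.10  # x-thickness of each cartilage layer
    depth_fraction: float = 0.85    # x-depth of the joint column as a
                                    # fraction of the pedicle length
    overlap_fraction: float = 0.88  # z-fraction of disc height where the
                                    # plates overlap through cartilage
    mode: str = "contact"           # 'contact' | 'bonded'
    penalty_factor: float = 10.0    # contact stiffness vs cartilage E*A/t

    def __post_init__(self):
        _require(self.cartilage_thickness > 0, "cartilage_thickness must be > 0")
        _require(0 < self.depth_fraction < 1, "depth_fraction must lie in (0,1)")
        _require(0 < self.overlap_fraction < 1,
                 "overlap_fraction must lie in (0,1)")
        _require(self.mode in ("contact", "bonded"),
                 f"unknown facet mode {self.mode!r}")
        _require(self.penalty_factor > 0, "penalty_factor must be > 0")


@dataclass(frozen=True)
class CementPlan:
    """Which vertebrae receive cement and how it is distributed.

    The printed cylinder footprints (width_ap x width_lat x height, mm) are
    treated as bounding boxes and rescaled so that the total cement volume
    in each augmented vertebra matches ``target_total_volume``; the sandwich
    vertebra T12 never receives cement.
    """

    group_label: str = "B-B"
    placement: Dict[str, str] = field(
        default_factory=lambda: {"T11": "bilateral", "L1": "bilateral"})
    unilateral_dims: Tuple[float, float, float] = (10.5, 10.5, 18.0)
    bilateral_dims: Tuple[float, float, float] = (12.0, 12.0, 14.0)
    target_total_volume: float = 6.0   # mL per augmented vertebra
    unilateral_offset_fraction: float = 0.25  # of the lateral half-width
    bilateral_offset_fraction: float = 0.40

    GROUPS = {
        "B-B": {"T11": "bilateral", "L1": "bilateral"},
        "L-B": {"T11": "left", "L1": "bilateral"},
        "L-R": {"T11": "left", "L1": "right"},
        "L-L": {"T11": "left", "L1": "left"},
        # mirror images, used by the reflection-equivariance checks
        "R-R": {"T11": "right", "L1": "right"},
        "R-L": {"T11": "right", "L1": "left"},
        "B-R": {"T11": "bilateral", "L1": "right"},
        "R-B": {"T11": "right", "L1": "bilateral"},
    }

    def __post_init__(self):
        _require("T12" not in self.placement,
                 "the sandwich vertebra T12 never receives cement")
        for v, p in self.placement.items():
            _require(v in ("T11", "L1"), f"cement vertebra {v!r} not in T11/L1")
            _require(p in ("bilateral", "left", "right"),
                     f"unknown placement {p!r}")
        if self.group_label in self.GROUPS:
            _require(self.placement == self.GROUPS[self.group_label],
                     f"placement inconsistent with group {self.group_label}")
        _require(self.target_total_volume > 0, "target volume must be > 0")
        for dims in (self.unilateral_dims, self.bilateral_dims):
            _require(all(d > 0 for d in dims), "cement dims must be > 0")

    @classmethod
    def for_group(cls, label: str, **kw) -> "CementPlan":
        if label not in cls.GROUPS:
            raise InvalidParameterError(f"unknown cement group {label!r}")
        return cls(group_label=label, placement=dict(cls.GROUPS[label]), **kw)

    def mirrored(self) -> "CementPlan":
        """The plan reflected about the mid-sagittal plane y=0."""
        swap = {"left": "right", "right": "left", "bilateral": "bilateral"}
        placement = {v: swap[p] for v, p in self.placement.items()}
        label = next((g for g, p in self.GROUPS.items() if p == placement),
                     "custom")
        return replace(self, group_label=label, placement=placement)


@dataclass(frozen=True)
class SegmentParams:
    """Full parameter set for the synthetic T11-L1 segment."""

    vertebrae: Tuple[VertebraParams, ...] = tuple(
        VertebraParams(level_label=lv) for lv in VERTEBRA_LEVELS)
    discs: Tuple[DiscParams, ...] = (DiscParams(), DiscParams())
    ligaments: Tuple[LigamentSpec, ...] = field(default_factory=default_ligaments)
    posterior: PosteriorParams = PosteriorParams()
    facets: FacetParams = FacetParams()

    def __post_init__(self):
        _require(len(self.vertebrae) == 3, "exactly three vertebrae required")
        labels = tuple(v.level_label for v in self.vertebrae)
        _require(labels == VERTEBRA_LEVELS,
                 f"vertebrae must be ordered {VERTEBRA_LEVELS}, got {labels}")
        _require(len(self.discs) == 2, "exactly two discs required")
        names = [l.name for l in self.ligaments]
        _require(len(names) == len(set(names)), "duplicate ligament groups")

    def vertebra(self, level: str) -> VertebraParams:
        for v in self.vertebrae:
            if v.level_label == level:
                return v
        raise InvalidParameterError(f"no vertebra {level!r}")

    def disc(self, level: str) -> DiscParams:
        return dict(zip(DISC_LEVELS, self.discs))[level]


@dataclass(frozen=True)
class MeshSettings:
    """Target edge lengths for the template mesher.

    The desk-scale default (5 mm solids / 1.5 mm cartilage) keeps the full
    scenario matrix tractable on one CPU; the reference density used for
    mesh-budget comparisons is 2 mm / 0.5 mm.
    """

    target_edge_solid: float = 5.0
    target_edge_cartilage: float = 1.5
    element_order: int = 2  # 1 = TET4, 2 = TET10

    def __post_init__(self):
        _require(self.target_edge_solid > 0, "target_edge_solid must be > 0")
        _require(self.target_edge_cartilage > 0,
                 "target_edge_cartilage must be > 0")
        _require(self.element_order in (1, 2), "element_order must be 1 or 2")

    @classmethod
    def reference(cls, order: int = 2) -> "MeshSettings":
        """The fine density used by the original study (2 mm / 0.5 mm)."""
        return cls(target_edge_solid=2.0, target_edge_cartilage=0.5,
                   element_order=order)
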