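"""Isotropic linear-elastic material library.

Values follow the standard vertebroplasty finite-element material table:
bone and endplate moduli are reduced to 67% of normal in the osteoporotic
condition, while cement, disc tissue, cartilage and ligaments are
unaffected.  The printed osteoporotic cancellous modulus in that table is
34 MPa (not 67% of 132 = 88.4); we keep the printed value as the default
and expose the arithmetic alternative through
``osteoporotic_cancellous_modulus``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownRegionError


@dataclass(frozen=True)
class MaterialSpec:
    name: str
    young_modulus: float        # MPa
    poisson_ratio: float
    sectional_area: float | None = None   # mm^2, ligaments only
    osteoporotic_flag: bool = False

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


_NORMAL = {
    "cortical": (12000.0, 0.3),
    "posterior": (12000.0, 0.3),   # posterior elements carry cortical bone
    "cancellous": (132.0, 0.2),
    "endplate": (1000.0, 0.4),
    "cartilage": (10.0, 0.4),
    "annulus": (4.2, 0.45),
    "nucleus": (1.0, 0.499),
    "cement": (3000.0, 0.4),
}

_OSTEOPOROTIC = {
    "cortical": 8040.0,   # 67% of normal
    "posterior": 8040.0,
    "endplate": 670.0,    # 67% of normal
    "cancellous": 34.0,   # printed value; see module docstring
}

#: 67% of the normal cancellous modulus, the arithmetically consistent
#: alternative to the printed 34 MPa.
OSTEOPOROTIC_CANCELLOUS_DERIVED = 0.67 * 132.0


def base_kind(region_tag: str) -> str:
    """Map a tagged region name (e.g. ``cancellous_T12``) to its material kind."""
    kind = region_tag.split("_", 1)[0]
    if kind not in _NORMAL:
        raise UnknownRegionError(f"no material for region {region_tag!r}")
    return kind


def material_for(region_tag: str, osteoporotic_flag: bool = True,
                 osteoporotic_cancellous_modulus: float = 34.0) -> MaterialSpec:
    """Material for a tagged region.

    Bone and endplate regions switch to osteoporotic moduli when the flag
    is set (the default: the study population is osteoporotic); cement,
    discs and cartilage are insensitive to the flag.
    """
    kind = base_kind(region_tag)
    E, nu = _NORMAL[kind]
    if osteoporotic_flag and kind in _OSTEOPOROTIC:
        E = (osteoporotic_cancellous_modulus if kind == "cancellous"
             else _OSTEOPOROTIC[kind])
    return MaterialSpec(name=kind, young_modulus=E, poisson_ratio=nu,
                        osteoporotic_flag=osteoporotic_flag and
                        kind in _OSTEOPOROTIC)
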