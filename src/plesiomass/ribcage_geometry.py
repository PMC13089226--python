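"""Ribcage cross-section geometry.

Plesiosaur dorsal ribs articulate only with the transverse processes, so a
rib's spatial orientation can be recovered from vertebral morphology alone.
Each rib is idealised as a planar structure: the minimum bounding rectangle
of the rib in its plane defines the rib plane height (RPH, dorsoventral) and
rib plane width (RPW, mediolateral).  Three slant angles carry the rib from
a vertical transverse plane into its life position:

* ``theta1`` — pump-handle rotation about the mediolateral edge through the
  articulation (deviation from the vertical plane), in [-90, 90] degrees;
* ``theta2`` — bucket-handle rotation about the (already tilted) medial edge,
  in [0, 90] degrees;
* ``theta3`` — tilt of the vertebral centrum from the horizontal, applied to
  the whole costovertebral system, in [-90, 90] degrees.

Projecting the rotated rectangle orthographically onto the transverse plane
gives the projected heights and widths used to size the body cross-sections:

    RPH_P1 = RPH * cos(theta1)              RPW_P1 = RPW
    RPH_P2 = RPH_P1 - RPW sin(theta2) sin(theta1)
    RPW_P2 = RPW * cos(theta2)
    RPH_P3 = RPH_P2 * cos(theta3)           RPW_P3 = RPW_P2

The projected height is measured between the articulation corner and the
diagonally opposite distal corner of the rectangle (the rib runs between
those corners), which is what produces the subtractive ``theta2`` term.

Cross-section outlines are modelled as paired half-superellipses: a dorsal
half (vertebra + ribs + epaxial musculature) and a ventral half (girdle
elements + gastralia), joined at the maximal-width waterline, with the
ventral-most point at y = 0 so that the glenoid and acetabulum sections
share a common ventral horizontal line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "RibPlane",
    "RibProjection",
    "SectionKind",
    "SectionSpec",
    "Contour",
    "project_rib_plane",
    "rib_coefficient",
    "ventral_height_from_girdle",
    "middle_ventral_height",
    "middle_section_width",
    "build_cross_section",
    "rescale_contour",
    "DEFAULT_DORSAL_EXPONENT",
    "DEFAULT_VENTRAL_EXPONENT",
]

#: Default superellipse exponents.  The dorsal exponent (2.2) gives a rounded
#: outline with room for the epaxial/limb-elevator musculature; the ventral
#: exponent (2.5) approximates the flattened, gastralia-supported belly.
DEFAULT_DORSAL_EXPONENT = 2.2
DEFAULT_VENTRAL_EXPONENT = 2.5


@dataclass(frozen=True)
class RibPlane:
    """Bounding rectangle of one dorsal rib plus its slant angles (degrees)."""

    RPH: float
    RPW: float
    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0
    dorsal_position: int = 1

    def __post_init__(self) -> None:
        if self.RPH <= 0 or self.RPW <= 0:
            raise ValueError("rib plane height and width must be positive")
        if not -90.0 <= self.theta1 <= 90.0:
            raise ValueError(f"theta1 must lie in [-90, 90], got {self.theta1}")
        if not 0.0 <= self.theta2 <= 90.0:
            raise ValueError(f"theta2 must lie in [0, 90], got {self.theta2}")
        if not -90.0 <= self.theta3 <= 90.0:
            raise ValueError(f"theta3 must lie in [-90, 90], got {self.theta3}")
        if self.dorsal_position < 1:
            raise ValueError("dorsal_position is 1-based")


@dataclass(frozen=True)
class RibProjection:
    """Projected rib-plane dimensions after each successive rotation (m)."""

    RPH_P1: float
    RPW_P1: float
    RPH_P2: float
    RPW_P2: float
    RPH_P3: float
    RPW_P3: float


def project_rib_plane(rib: RibPlane) -> RibProjection:
    """Project a slanted rib plane onto the vertical transverse plane."""
    t1 = math.radians(rib.theta1)
    t2 = math.radians(rib.theta2)
    t3 = math.radians(rib.theta3)
    rph_p1 = rib.RPH * math.cos(t1)
    rpw_p1 = rib.RPW
    rph_p2 = rph_p1 - rib.RPW * math.sin(t2) * math.sin(t1)
    rpw_p2 = rib.RPW * math.cos(t2)
    rph_p3 = rph_p2 * math.cos(t3)
    rpw_p3 = rpw_p2
    return RibProjection(rph_p1, rpw_p1, rph_p2, rpw_p2, rph_p3, rpw_p3)


def rib_coefficient(arc_glenoid: float, arc_max: float) -> float:
    """Ratio of the glenoid-level rib arc length to the maximum rib arc length.

    The rib coefficient characterises how far the ribcage has narrowed at the
    glenoid level relative to mid-trunk; by definition it lies in (0, 1].
    """
    if arc_glenoid <= 0 or arc_max <= 0:
        raise ValueError("rib arc lengths must be positive")
    if arc_glenoid > arc_max:
        raise ValueError(
            "glenoid rib arc length exceeds the maximum rib arc length; "
            "the rib coefficient is undefined"
        )
    return arc_glenoid / arc_max


def ventral_height_from_girdle(girdle_width: float, section_width: float) -> float:
    """Height of a section's ventral part from a girdle element width.

    The girdle element (coracoid at the glenoid, pubis at the acetabulum)
    spans from the ventral midline to the lateral limb articulation and is
    treated as the hypotenuse of a right triangle whose horizontal side is
    half the cross-section width; the vertical side is the ventral height.
    """
    if girdle_width <= 0:
        raise ValueError("girdle width must be positive")
    if section_width < 0:
        raise ValueError("section width must be non-negative")
    half_w = section_width / 2.0
    if girdle_width <= half_w:
        raise ValueError(
            f"girdle width {girdle_width} does not reach across half the "
            f"section width {half_w}; ventral triangle is infeasible"
        )
    return math.sqrt(girdle_width**2 - half_w**2)


def middle_ventral_height(
    glenoid_vh: float, acetabulum_vh: float, rib_coef: float
) -> float:
    """Ventral height of the middle cross-section.

    The mean of the glenoid and acetabulum ventral heights, inflated by the
    rib coefficient (the mid-trunk ribcage is deeper in proportion to how
    much longer its ribs are than the glenoid-level rib):

        middle_vh = ((glenoid_vh + acetabulum_vh) / 2) / rib_coefficient
    """
    if glenoid_vh <= 0 or acetabulum_vh <= 0:
        raise ValueError("ventral heights must be positive")
    if not 0.0 < rib_coef <= 1.0:
        raise ValueError("rib coefficient must be in (0, 1]")
    return 0.5 * (glenoid_vh + acetabulum_vh) / rib_coef


def middle_section_width(
    ribs: list[RibPlane], intersect_fractions: list[float]
) -> float:
    """Width of the middle cross-section from the ribs it transects.

    The ribs cut by the middle section plane are standardised to the maximum
    rib arc length by the caller; ``intersect_fractions[i]`` gives where the
    plane cuts rib i's plane as a fraction of its width.  Each intersected
    width is projected by cos(theta2) (the centrum tilt theta3 of the middle
    dorsals is taken as zero, matching the gentle dorsal arch of the column)
    and the section width is twice the largest projected half-width.
    """
    if not ribs:
        raise ValueError("at least one rib plane is required")
    if len(intersect_fractions) != len(ribs):
        raise ValueError("one intersect fraction is required per rib")
    half_widths = []
    for rib, frac in zip(ribs, intersect_fractions):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("intersect fractions must lie in [0, 1]")
        half_widths.append(frac * rib.RPW * math.cos(math.radians(rib.theta2)))
    return 2.0 * max(half_widths)


class SectionKind(str, Enum):
    glenoid = "glenoid"
    middle = "middle"
    acetabulum = "acetabulum"
    skull = "skull"


@dataclass(frozen=True)
class SectionSpec:
    """Parametric description of one transverse cross-section."""

    kind: SectionKind
    total_width: float
    dorsal_height: float
    ventral_height: float
    dorsal_exponent: float = DEFAULT_DORSAL_EXPONENT
    ventral_exponent: float = DEFAULT_VENTRAL_EXPONENT

    def __post_init__(self) -> None:
        if min(self.total_width, self.dorsal_height, self.ventral_height) <= 0:
            raise ValueError("section widths and heights must be positive")
        if self.dorsal_exponent < 1 or self.ventral_exponent < 1:
            raise ValueError("superellipse exponents must be >= 1")


@dataclass(frozen=True)
class Contour:
    """Closed, bilaterally symmetric planar cross-section outline.

    Vertices are ordered counterclockwise, the polygon is implicitly closed
    (the first vertex is not repeated), x is lateral with the midline at
    x = 0, and y is dorsal.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs an (n, 2) array with n >= 3")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def width(self) -> float:
        x = self.vertices[:, 0]
        return float(x.max() - x.min())

    @property
    def height(self) -> float:
        y = self.vertices[:, 1]
        return float(y.max() - y.min())

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def symmetry_residual(self) -> float:
        """Max |x_left + x_right| over mirror-paired vertices (0 if symmetric)."""
        v = self.vertices
        mirrored = np.column_stack([-v[:, 0], v[:, 1]])
        resid = 0.0
        for p in v[:: max(1, len(v) // 64)]:
            d = np.hypot(mirrored[:, 0] - p[0], mirrored[:, 1] - p[1])
            resid = max(resid, float(d.min()))
        return resid

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vertices, delimiter=",", header="x,y", comments="")

    def to_svg(self, path, scale: float = 500.0) -> None:
        """Write a minimal SVG of the outline for visual inspection."""
        v = self.vertices * scale
        xmin, ymin = v.min(axis=0) - 10
        xmax, ymax = v.max(axis=0) + 10
        pts = " ".join(f"{x:.3f},{ymax - y + ymin:.3f}" for x, y in v)
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'viewBox="{xmin:.1f} {ymin:.1f} {xmax - xmin:.1f} {ymax - ymin:.1f}">'
            f'<polygon points="{pts}" fill="none" stroke="black"/></svg>\n'
        )
        with open(path, "w") as fh:
            fh.write(svg)


def _superellipse_quarter(t: np.ndarray, exponent: float) -> tuple[np.ndarray, np.ndarray]:
    # unit quarter |X|^n + |Y|^n = 1 traced by (sin t)^(2/n), (cos t)^(2/n);
    # trig residues ~1e-16 at the endpoints would blow up under fractional
    # powers (p < 1), so they are clamped to exact zeros first
    p = 2.0 / exponent
    s, c = np.sin(t), np.cos(t)
    s[np.abs(s) < 1e-15] = 0.0
    c[np.abs(c) < 1e-15] = 0.0
    return s**p, c**p


def build_cross_section(spec: SectionSpec, n_points: int = 256) -> Contour:
    """Trace a closed cross-section contour from a section specification.

    The outline is a dorsal half-superellipse (full section width, dorsal
    height) on top of a ventral half-superellipse (same width, ventral
    height), joined at the maximal-width waterline.  The ventral-most point
    sits at y = 0 and x = 0.  The right half is generated and mirrored so
    bilateral symmetry is exact; vertices run counterclockwise starting from
    the ventral midline point.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    half_w = spec.total_width / 2.0
    m = n_points // 4 + 1
    t = np.linspace(0.0, math.pi / 2.0, m)

    # ventral right quarter: (0, 0) -> (half_w, ventral_height)
    sx, cy = _superellipse_quarter(t, spec.ventral_exponent)
    ventral = np.column_stack([half_w * sx, spec.ventral_height * (1.0 - cy)])
    # dorsal right quarter: (half_w, ventral_height) -> (0, total height)
    sy, cx = _superellipse_quarter(t, spec.dorsal_exponent)
    dorsal = np.column_stack(
        [half_w * cx, spec.ventral_height + spec.dorsal_height * sy]
    )
    right = np.vstack([ventral, dorsal[1:]])  # (0,0) ... apex, inclusive
    left = right[1:-1][::-1].copy()
    left[:, 0] = -left[:, 0]
    return Contour(np.vstack([right, left]))


def rescale_contour(c: Contour, new_width: float, new_height: float) -> Contour:
    """Anisotropically rescale a contour about its ventral midline point.

    Used both to derive the acetabulum section from the glenoid profile and
    to apply the uniform soft-tissue enlargement.  Areas transform by the
    affine law ``area * (new_width/old_width) * (new_height/old_height)``.
    """
    if new_width <= 0 or new_height <= 0:
        raise ValueError("target width and height must be positive")
    sx = new_width / c.width
    sy = new_height / c.height
    y0 = float(c.vertices[:, 1].min())
    v = c.vertices.copy()
    v[:, 0] *= sx
    v[:, 1] = y0 + (v[:, 1] - y0) * sy
    return Contour(v)
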