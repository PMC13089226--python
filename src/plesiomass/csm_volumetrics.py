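"""Cross-sectional method (CSM) volume integration and mass conversion.

The CSM partitions a body into axial slabs bounded by transverse
cross-sections and assumes linear transitions in cross-sectional shape and
size at a small scale.  Each slab is sliced into subslabs (100 by default,
far more than needed for stable estimates); the cross-section at an interior
station is the pointwise linear blend of the bounding contours, and slab
volume is the trapezoidal sum of subslab section areas times thickness.

A plesiosaur's main body is partitioned into five slabs by the four
transverse cross-sections (skull/quadrate, glenoid, middle, acetabulum).
The two end slabs taper to a point at the snout and tail tips while keeping
the shape of their bounding section (a generalised cone); a literal
constant-size end prism would leave the body unclosed.  Each limb is a
single slab built from a hydrofoil planform.  Mass is volume times an
assumed density of 1027 kg/m^3 (1.027 g/cm^3, surface seawater: aquatic
tetrapods near neutral buoyancy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .ribcage_geometry import Contour

__all__ = [
    "POINT",
    "Slab",
    "LimbPlanform",
    "SoftTissueConfig",
    "BodyModel",
    "contour_area",
    "resample_contour",
    "blend_contours",
    "slab_volume",
    "limb_volume",
    "apply_soft_tissue",
    "body_mass",
    "DEFAULT_DENSITY",
    "DEFAULT_SUBSLABS",
    "DEFAULT_SECTION_COEFFICIENT",
    "DEFAULT_THICKNESS_FRACTIONS",
]

DEFAULT_DENSITY = 1027.0  # kg/m^3, surface seawater
DEFAULT_SUBSLABS = 100

#: Streamlined (hydrofoil) section area coefficient: section area =
#: coefficient * chord * max thickness.  0.685 is typical of low-drag foil
#: sections used for flipper reconstructions.
DEFAULT_SECTION_COEFFICIENT = 0.685

#: Relative soft-tissue thickness (max thickness / chord) at the six
#: planform stations of a flipper divided into five equal spanwise segments,
#: root to tip, following penguin flipper proportions.
DEFAULT_THICKNESS_FRACTIONS = (0.22, 0.19, 0.16, 0.13, 0.10, 0.07)


class _TaperPoint:
    """Sentinel marking a slab end that tapers to a point."""

    def __repr__(self) -> str:  # pragma: no cover
        return "POINT"


POINT = _TaperPoint()


@dataclass(frozen=True)
class Slab:
    """One axial slab: bounding contours (either may taper to a point)."""

    front: Contour | _TaperPoint
    back: Contour | _TaperPoint
    length: float
    n_subslabs: int = DEFAULT_SUBSLABS
    name: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("slab length must be positive")
        if self.n_subslabs < 1:
            raise ValueError("n_subslabs must be >= 1")
        if isinstance(self.front, _TaperPoint) and isinstance(self.back, _TaperPoint):
            raise ValueError("a slab cannot taper to a point at both ends")


@dataclass(frozen=True)
class LimbPlanform:
    """Flipper planform: span, chords at evenly spaced stations, thickness.

    Section area at each station is
    ``section_area_coefficient * chord * (thickness_fraction * chord)`` and
    the limb volume is the trapezoidal integral of area along the span.
    """

    span: float
    chords: tuple[float, ...]
    thickness_fractions: tuple[float, ...] = DEFAULT_THICKNESS_FRACTIONS
    section_area_coefficient: float = DEFAULT_SECTION_COEFFICIENT
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chords", tuple(float(c) for c in self.chords))
        object.__setattr__(
            self, "thickness_fractions",
            tuple(float(f) for f in self.thickness_fractions),
        )
        if self.span <= 0:
            raise ValueError("span must be positive")
        if len(self.chords) < 2:
            raise ValueError("at least two chord stations are required")
        if any(c < 0 for c in self.chords):
            raise ValueError("chords must be >= 0")
        if len(self.thickness_fractions) != len(self.chords):
            raise ValueError("one thickness fraction per chord station")
        if any(not 0 < f < 1 for f in self.thickness_fractions):
            raise ValueError("thickness fractions must lie in (0, 1)")


@dataclass(frozen=True)
class SoftTissueConfig:
    """Soft-tissue staging constants.

    ``section_linear_scale`` enlarges the three ribcage cross-sections
    uniformly in both planar dimensions (default 1.25: the in-vivo trunk
    outline is 25% wider than the ribcage, after the soft-tissue halo of
    *Mauriciosaurus fernandezi*).  ``tail_extension_fraction`` appends soft
    tissue past the last caudal (default 0.05, after the tail traces of
    *Seeleyosaurus*).  The skull section is never scaled.
    """

    section_linear_scale: float = 1.25
    tail_extension_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.section_linear_scale < 1:
            raise ValueError("section scale must be >= 1")
        if self.tail_extension_fraction < 0:
            raise ValueError("tail extension fraction must be >= 0")


@dataclass(frozen=True)
class BodyModel:
    """Ordered axial slabs plus limb slabs: the CSM integrand.

    Plesiosaur reconstructions use exactly five axial slabs with the first
    and last tapering to a point (see :meth:`validate_plesiosaur_layout`);
    closed-form oracle bodies may use any number of slabs.
    """

    axial_slabs: tuple[Slab, ...]
    limb_slabs: tuple[LimbPlanform, ...] = ()
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "axial_slabs", tuple(self.axial_slabs))
        object.__setattr__(self, "limb_slabs", tuple(self.limb_slabs))
        if not self.axial_slabs:
            raise ValueError("at least one axial slab is required")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def validate_plesiosaur_layout(self) -> None:
        slabs = self.axial_slabs
        if len(slabs) != 5:
            raise ValueError("a plesiosaur body model has exactly five axial slabs")
        if not isinstance(slabs[0].front, _TaperPoint):
            raise ValueError("the first slab must taper to a point at the snout")
        if not isinstance(slabs[-1].back, _TaperPoint):
            raise ValueError("the last slab must taper to a point at the tail tip")

    def to_json(self, path) -> None:
        doc = {
            "density_kg_m3": self.density,
            "axial_slabs": [
                {
                    "name": s.name,
                    "length_m": s.length,
                    "n_subslabs": s.n_subslabs,
                    "front": "POINT" if isinstance(s.front, _TaperPoint)
                    else s.front.vertices.tolist(),
                    "back": "POINT" if isinstance(s.back, _TaperPoint)
                    else s.back.vertices.tolist(),
                }
                for s in self.axial_slabs
            ],
            "limb_slabs": [
                {
                    "name": p.name,
                    "span_m": p.span,
                    "chords_m": list(p.chords),
                    "thickness_fractions": list(p.thickness_fractions),
                    "section_area_coefficient": p.section_area_coefficient,
                }
                for p in self.limb_slabs
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")


# ---------------------------------------------------------------------------
# contour operations
# ---------------------------------------------------------------------------

def contour_area(c: Contour) -> float:
    """Shoelace area of a simple counterclockwise contour (m^2)."""
    poly = Polygon(c.vertices)
    if not poly.is_valid:
        raise ValueError("contour polygon is self-intersecting")
    area = c.area
    if area <= 0:
        raise ValueError("contour must be counterclockwise with positive area")
    return area


def _ventral_midline_start(vertices: np.ndarray) -> np.ndarray:
    """Roll/augment a closed CCW vertex loop to start at the ventral midline.

    The start point is the crossing of the outline with the midline x = 0
    that has the smallest y; it is inserted exactly at x = 0 if it falls
    inside a segment.
    """
    v = vertices
    n = len(v)
    best = None  # (y, index, point)
    for i in range(n):
        p, q = v[i], v[(i + 1) % n]
        x0, x1 = p[0], q[0]
        if x0 == 0.0:
            cand = (p[1], i, p.copy(), True)
        elif (x0 < 0.0 < x1) or (x1 < 0.0 < x0):
            t = -x0 / (x1 - x0)
            y = p[1] + t * (q[1] - p[1])
            cand = (y, i, np.array([0.0, y]), False)
        else:
            continue
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise ValueError("contour does not cross the midline x = 0")
    y, i, point, on_vertex = best
    if on_vertex:
        return np.roll(v, -i, axis=0)
    return np.vstack([point, v[i + 1:], v[: i + 1]])


def resample_contour(c: Contour, n: int = 256) -> Contour:
    """Resample a contour to ``n`` points equally spaced by perimeter arc
    length, starting at the ventral midline point, counterclockwise.

    Establishes point correspondence for shape blending.  The sampling is
    iterated to a fixed point so that the returned vertices are equally
    spaced in the arc length of the polygon *they themselves* define; as a
    consequence resampling an already-resampled contour with the same ``n``
    is the identity to float precision.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    if c.area < 0:
        raise ValueError("contour must be counterclockwise")
    v = _ventral_midline_start(c.vertices)
    scale = max(c.width, c.height)
    for _ in range(12):
        new = _equal_arclength_pass(v, n)
        if len(v) == len(new) and np.max(np.abs(new - v)) < 1e-14 * scale:
            v = new
            break
        v = new
    return Contour(v)


def _equal_arclength_pass(v: np.ndarray, n: int) -> np.ndarray:
    loop = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(loop, axis=0).T)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("degenerate zero-perimeter contour")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n, endpoint=False)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    with np.errstate(invalid="ignore"):
        t = np.where(seg[idx] > 0, (targets - cum[idx]) / seg[idx], 0.0)
    pts = loop[idx] + (loop[idx + 1] - loop[idx]) * t[:, None]
    pts[0] = v[0]
    return pts


def blend_contours(
    front: Contour, back: Contour, t: float, n: int | None = None
) -> Contour:
    """Pointwise linear interpolation between two cross-sections.

    Correspondence: contours that already share a vertex count (e.g. two
    sections built with the same point budget, or a previously blended
    intermediate) are blended index-by-index, which makes blending exactly
    associative — splitting a slab at an interior blend changes nothing.
    Otherwise both contours are resampled to a common count ``n`` (default
    the larger of the two, at least 256) by arc length with a matched
    ventral-midline start.  The blend is ``(1 - t) * front + t * back``.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    a, b = _common_correspondence(front, back, n)
    return Contour((1.0 - t) * a + t * b)


def _common_correspondence(
    front: Contour, back: Contour, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    if n is None and len(front.vertices) == len(back.vertices):
        return front.vertices, back.vertices
    if n is None:
        n = max(len(front.vertices), len(back.vertices), 256)
    return resample_contour(front, n).vertices, resample_contour(back, n).vertices


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _slab_section_areas(s: Slab) -> np.ndarray:
    """Section areas at the n_subslabs+1 stations of a slab."""
    ts = np.linspace(0.0, 1.0, s.n_subslabs + 1)
    if isinstance(s.front, _TaperPoint) or isinstance(s.back, _TaperPoint):
        # generalised cone: constant shape, size tapering linearly to a point
        base = s.back if isinstance(s.front, _TaperPoint) else s.front
        base_area = contour_area(base)
        scale = ts if isinstance(s.front, _TaperPoint) else (1.0 - ts)
        return base_area * scale**2
    front_area = contour_area(s.front)
    back_area = contour_area(s.back)
    a, b = _common_correspondence(s.front, s.back)
    areas = np.empty(len(ts))
    for i, t in enumerate(ts):
        if t == 0.0:
            areas[i] = front_area
        elif t == 1.0:
            areas[i] = back_area
        else:
            areas[i] = Contour((1.0 - t) * a + t * b).area
    return areas


def slab_volume(s: Slab) -> float:
    """Trapezoidal CSM volume of one axial slab (m^3)."""
    areas = _slab_section_areas(s)
    delta = s.length / s.n_subslabs
    return float(np.trapezoid(areas, dx=delta))


def limb_volume(p: LimbPlanform) -> float:
    """Volume of a flipper slab from its planform (m^3)."""
    chords = np.asarray(p.chords)
    fracs = np.asarray(p.thickness_fractions)
    areas = p.section_area_coefficient * chords * (fracs * chords)
    dx = p.span / (len(chords) - 1)
    return float(np.trapezoid(areas, dx=dx))


def _scale_contour_linear(c: Contour, scale: float) -> Contour:
    """Scale a contour by a linear factor about its ventral midline anchor."""
    y0 = float(c.vertices[:, 1].min())
    v = c.vertices.copy()
    v[:, 0] *= scale
    v[:, 1] = y0 + (v[:, 1] - y0) * scale
    return Contour(v)


def apply_soft_tissue(
    model: BodyModel,
    cfg: SoftTissueConfig | None = None,
) -> BodyModel:
    """Apply the soft-tissue stage to a skeletal plesiosaur body model.

    The glenoid, middle and acetabulum contours are enlarged linearly (areas
    grow by scale^2) about their ventral midline anchors; the tail slab is
    lengthened by the tail extension fraction; the skull section is left
    unscaled.  Slabs are identified by their names as produced by the
    reconstruction pipeline ("snout", "neck", "front_trunk", "rear_trunk",
    "tail"); ribcage sections are the contours bounding the trunk slabs.
    """
    cfg = cfg or SoftTissueConfig()
    model.validate_plesiosaur_layout()
    snout, neck, front_trunk, rear_trunk, tail = model.axial_slabs
    k = cfg.section_linear_scale
    glenoid = _scale_contour_linear(neck.back, k)
    middle = _scale_contour_linear(front_trunk.back, k)
    acetabulum = _scale_contour_linear(rear_trunk.back, k)
    new_slabs = (
        snout,
        replace(neck, back=glenoid),
        replace(front_trunk, front=glenoid, back=middle),
        replace(rear_trunk, front=middle, back=acetabulum),
        replace(tail, front=acetabulum,
                length=tail.length * (1.0 + cfg.tail_extension_fraction)),
    )
    return replace(model, axial_slabs=new_slabs)


def body_mass(model: BodyModel) -> tuple[float, float]:
    """Total CSM volume (m^3) and mass (kg) of a body model."""
    volume = sum(slab_volume(s) for s in model.axial_slabs)
    volume += sum(limb_volume(p) for p in model.limb_slabs)
    return volume, volume * model.density


def volume_report(model: BodyModel) -> pd.DataFrame:
    """Per-slab volume breakdown with totals and mass, as a DataFrame."""
    rows = []
    for i, s in enumerate(model.axial_slabs):
        rows.append({"slab": s.name or f"axial_{i}", "kind": "axial",
                     "volume_m3": slab_volume(s)})
    for i, p in enumerate(model.limb_slabs):
        rows.append({"slab": p.name or f"limb_{i}", "kind": "limb",
                     "volume_m3": limb_volume(p)})
    df = pd.DataFrame(rows)
    total = df["volume_m3"].sum()
    df.loc[len(df)] = {"slab": "total", "kind": "total", "volume_m3": total}
    df["mass_kg"] = df["volume_m3"] * model.density
    return df
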