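"""Body-axis assembly: cartilage-adjusted segment lengths, trunk spinal
curvature, the skull cross-section, and the axial stations of the four
transverse cross-sections.

The trunk is defined as the distance from the anterior margin of the scapula
to the acetabulum.  During reconstruction that distance is laid out as a
horizontal chord and the vertebral column arches gently above it: the arch
is modelled as a circular arc whose inscribed polyline — one segment per
vertebra-plus-cartilage unit — starts and ends exactly on the chord
endpoints.  A circular arc is the minimal-assumption smooth curve satisfying
the endpoint and length constraints, and it makes the solve a well-posed
one-dimensional root find on curvature.

Axial stations are measured in meters from the snout tip:
``snout_tip < quadrate < glenoid < middle < acetabulum < tail_tip``, with
the middle section positioned midway between the glenoid and acetabulum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .ribcage_geometry import Contour, SectionKind, SectionSpec, build_cross_section
from .skeleton_io import SkeletonSpec, VertebralCentrum

__all__ = [
    "SpinalCurve",
    "BodyAxis",
    "effective_segment_lengths",
    "solve_trunk_curve",
    "skull_section",
    "assemble_body_axis",
]


def effective_segment_lengths(
    vertebrae: list[VertebralCentrum],
    cartilage_fraction: float,
    by_region: dict[str, float] | None = None,
) -> list[float]:
    """Centrum lengths inflated by the intervertebral-cartilage fraction.

    Intervertebral spacing scales with centrum size, so each vertebra
    contributes ``length * (1 + fraction)`` to the axial column.  Per-region
    overrides (e.g. a larger intercervical fraction in short-necked clades)
    take precedence over the global fraction.
    """
    if cartilage_fraction < 0:
        raise ValueError("cartilage fraction must be >= 0")
    by_region = by_region or {}
    out = []
    for v in vertebrae:
        frac = by_region.get(v.region.value, cartilage_fraction)
        if frac < 0:
            raise ValueError("cartilage fraction must be >= 0")
        out.append(v.length * (1.0 + frac))
    return out


@dataclass(frozen=True)
class SpinalCurve:
    """A trunk arch: circular arc plus the inscribed vertebral polyline."""

    chord: float
    arc_length: float
    radius: float  # inf for the straight-line degenerate case
    subtended_angle: float  # radians
    vertex_chain: np.ndarray = field(repr=False)  # (n+1, 2), endpoints on chord

    @property
    def sagitta(self) -> float:
        return float(self.vertex_chain[:, 1].max())


_FLAT_TOL = 1e-12


def solve_trunk_curve(chord: float, segment_lengths: list[float]) -> SpinalCurve:
    """Arch the vertebral polyline over the trunk chord.

    Finds the circular arc through ``(0, 0)`` and ``(chord, 0)`` such that a
    polyline of the prescribed segment lengths, inscribed in the arc (every
    vertex on the circle), lands exactly on the far endpoint.  With curvature
    ``k = 1/R`` each segment of length ``L`` subtends an angle
    ``2 asin(L k / 2)``, so the root condition is

        (2/k) * sin( sum_i asin(L_i k / 2) ) = chord.

    The root is bracketed and solved to a 1e-10 endpoint-miss tolerance.
    Requires ``chord <= sum(L_i) < (pi/2) * chord`` (gentle arch).
    """
    seg = np.asarray(segment_lengths, dtype=float)
    if chord <= 0 or np.any(seg <= 0):
        raise ValueError("chord and segment lengths must be positive")
    total = float(seg.sum())
    if total < chord * (1.0 - 1e-12):
        raise ValueError(
            f"segments sum to {total}, shorter than the chord {chord}; "
            "the polyline cannot reach the far endpoint"
        )
    if total >= (math.pi / 2.0) * chord:
        raise ValueError(
            "segments exceed the gentle-arch limit (pi/2 times the chord)"
        )

    if total - chord <= _FLAT_TOL * chord:
        # degenerate straight column
        x = np.concatenate([[0.0], np.cumsum(seg)]) * (chord / total)
        chain = np.column_stack([x, np.zeros_like(x)])
        return SpinalCurve(chord, total, math.inf, 0.0, chain)

    def miss(k: float) -> float:
        half_angles = np.arcsin(np.clip(seg * k / 2.0, -1.0, 1.0))
        return (2.0 / k) * math.sin(float(half_angles.sum())) - chord

    # bracket: miss -> (total - chord) > 0 as k -> 0+; decrease k_hi until the
    # polyline overshoots past the half-circle or the endpoint distance drops
    # below the chord
    k_lo = 1e-9 / chord
    k_hi = 1.9999 / float(seg.max())  # asin argument stays < 1
    while miss(k_hi) > 0:  # pragma: no cover - gentle-arch precondition
        k_hi *= 0.5
        if k_hi < k_lo:
            raise RuntimeError("failed to bracket the trunk-curve curvature")
    k = brentq(miss, k_lo, k_hi, xtol=1e-14, rtol=8.881784197001252e-16)
    radius = 1.0 / k

    half_angles = np.arcsin(seg * k / 2.0)
    theta_total = 2.0 * float(half_angles.sum())
    # circle through (0,0) and (chord,0), arching to y > 0: center below the
    # midpoint at (chord/2, -sqrt(R^2 - (chord/2)^2)) for theta_total < pi
    cx = chord / 2.0
    cy = -math.sqrt(max(radius**2 - cx**2, 0.0))
    start_angle = math.atan2(0.0 - cy, 0.0 - cx)
    cum = np.concatenate([[0.0], np.cumsum(2.0 * half_angles)])
    angles = start_angle - cum  # march clockwise: x increases, y arches up
    chain = np.column_stack([cx + radius * np.cos(angles),
                             cy + radius * np.sin(angles)])
    chain[0] = (0.0, 0.0)
    chain[-1, 1] = 0.0  # endpoint lies on the chord to solver tolerance
    if abs(chain[-1, 0] - chord) > 1e-8 * max(1.0, chord):
        raise RuntimeError(
            f"trunk-curve solve missed the endpoint by "
            f"{abs(chain[-1, 0] - chord):.3e} m"
        )
    chain[-1, 0] = chord
    return SpinalCurve(chord, total, radius, theta_total, chain)


def skull_section(width: float, height: float, n_points: int = 256) -> Contour:
    """Elliptical skull cross-section at the quadrate level.

    The ellipse axes equal the skull width and height at the quadrates;
    minimal craniofacial soft tissue means this section is never enlarged by
    the soft-tissue stage.
    """
    if width <= 0 or height <= 0:
        raise ValueError("skull section dimensions must be positive")
    spec = SectionSpec(
        kind=SectionKind.skull,
        total_width=width,
        dorsal_height=height / 2.0,
        ventral_height=height / 2.0,
        dorsal_exponent=2.0,
        ventral_exponent=2.0,
    )
    return build_cross_section(spec, n_points)


@dataclass(frozen=True)
class BodyAxis:
    """Axial stations (m from snout tip) and per-region segment lengths."""

    stations: dict[str, float]
    segment_lengths: dict[str, float]

    _ORDER = ("snout_tip", "quadrate", "glenoid", "middle", "acetabulum", "tail_tip")

    def __post_init__(self) -> None:
        pos = [self.stations[k] for k in self._ORDER]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("axial stations must be strictly increasing")

    @property
    def total_length(self) -> float:
        return self.stations["tail_tip"] - self.stations["snout_tip"]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"stations_m": self.stations,
                 "segment_lengths_m": self.segment_lengths,
                 "total_length_m": self.total_length},
                fh, indent=1,
            )
            fh.write("\n")


def assemble_body_axis(
    spec: SkeletonSpec,
    *,
    skull_length: float | None = None,
    neck_length: float | None = None,
    tail_length: float | None = None,
) -> BodyAxis:
    """Lay out the axial stations of a validated skeleton.

    Explicit keyword overrides take precedence over the measurement set
    (they are how the pipeline injects regression-estimated missing
    elements).  The neck segment spans quadrate to glenoid; if no neck
    length is available it is summed from the cartilage-adjusted cervical
    and pectoral centra.  Total length is skull + neck + trunk + tail,
    before the soft-tissue tail extension.
    """
    m = spec.measurements
    skull = skull_length if skull_length is not None else m.skull_length
    neck = neck_length if neck_length is not None else m.neck_length
    tail = tail_length if tail_length is not None else m.tail_length
    trunk = m.trunk_length

    if neck is None:
        cerv = spec.vertebrae_in("cervical") + spec.vertebrae_in("pectoral")
        if cerv:
            neck = sum(
                effective_segment_lengths(
                    cerv, spec.cartilage_fraction, spec.cartilage_fraction_by_region
                )
            )
    if tail is None:
        caud = spec.vertebrae_in("caudal")
        if caud:
            tail = sum(
                effective_segment_lengths(
                    caud, spec.cartilage_fraction, spec.cartilage_fraction_by_region
                )
            )
    for name, value in (("skull", skull), ("neck", neck),
                        ("trunk", trunk), ("tail", tail)):
        if value is None:
            raise ValueError(
                f"cannot assemble body axis: the {name} segment is "
                "unresolved after all fallbacks"
            )

    glenoid = skull + neck
    acetabulum = glenoid + trunk
    stations = {
        "snout_tip": 0.0,
        "quadrate": skull,
        "glenoid": glenoid,
        "middle": 0.5 * (glenoid + acetabulum),
        "acetabulum": acetabulum,
        "tail_tip": acetabulum + tail,
    }
    segments = {"skull": skull, "neck": neck, "trunk": trunk, "tail": tail}
    return BodyAxis(stations=stations, segment_lengths=segments)
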