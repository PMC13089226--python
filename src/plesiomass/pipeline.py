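"""End-to-end reconstruction pipeline.

Ties the stages together in the order a reconstruction proceeds: validate
the skeleton, fill missing elements from the published regressions, lay out
the body axis, derive the four transverse cross-sections from rib
orientation and girdle widths, stage the soft tissue, and integrate volume
and mass with the cross-sectional method.  The command-line interface in
:mod:`plesiomass.cli` is a thin wrapper over :func:`reconstruct`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .axial_assembly import (
    BodyAxis,
    SpinalCurve,
    assemble_body_axis,
    effective_segment_lengths,
    skull_section,
    solve_trunk_curve,
)
from .csm_volumetrics import (
    DEFAULT_DENSITY,
    DEFAULT_SUBSLABS,
    DEFAULT_THICKNESS_FRACTIONS,
    POINT,
    BodyModel,
    LimbPlanform,
    Slab,
    SoftTissueConfig,
    apply_soft_tissue,
    body_mass,
    volume_report,
)
from .reference_predictors import predict_missing_element
from .ribcage_geometry import (
    DEFAULT_DORSAL_EXPONENT,
    DEFAULT_VENTRAL_EXPONENT,
    Contour,
    RibPlane,
    SectionKind,
    SectionSpec,
    build_cross_section,
    middle_section_width,
    middle_ventral_height,
    project_rib_plane,
    rib_coefficient,
    ventral_height_from_girdle,
)
from .skeleton_io import SkeletonSpec, validate_skeleton

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "SkeletonValidationError",
    "reconstruct",
    "build_sections",
]


class SkeletonValidationError(ValueError):
    """Raised when a skeleton fails validation; carries the report."""

    def __init__(self, report) -> None:
        msgs = "; ".join(f"{f}: {m}" for f, m in report.errors)
        super().__init__(f"skeleton failed validation: {msgs}")
        self.report = report


@dataclass(frozen=True)
class ReconstructionConfig:
    """Tunable constants of a reconstruction run.

    Defaults mirror the published protocol: 100 subslabs per slab, ribcage
    sections enlarged 25% linearly, 5% tail soft-tissue extension, seawater
    density 1027 kg/m^3, 10% intervertebral cartilage.  The superellipse
    exponents shape the dorsal and ventral halves of the ribcage sections.
    ``skull_width_fraction`` / ``skull_height_fraction`` are used when the
    skull section dimensions must be inferred from skull length.
    """

    soft_tissue: SoftTissueConfig = field(default_factory=SoftTissueConfig)
    n_subslabs: int = DEFAULT_SUBSLABS
    n_contour_points: int = 256
    density: float = DEFAULT_DENSITY
    dorsal_exponent: float = DEFAULT_DORSAL_EXPONENT
    ventral_exponent: float = DEFAULT_VENTRAL_EXPONENT
    default_rib_coefficient: float = 0.78
    skull_width_fraction: float = 0.52
    skull_height_fraction: float = 0.38
    limb_chord_profile: tuple[float, ...] = (1.3, 1.6, 1.5, 1.2, 0.8, 0.3)
    limb_thickness: tuple[float, ...] = DEFAULT_THICKNESS_FRACTIONS


@dataclass(frozen=True)
class ReconstructionResult:
    """Everything a reconstruction run produces."""

    taxon: str
    axis: BodyAxis
    sections: dict[str, Contour]
    skeletal_model: BodyModel
    model: BodyModel  # after soft tissue
    trunk_curve: SpinalCurve | None
    volume_m3: float
    mass_kg: float
    fallbacks: tuple[str, ...]
    warnings: tuple[str, ...]

    def report(self) -> pd.DataFrame:
        return volume_report(self.model)

    def summary(self) -> dict:
        return {
            "taxon": self.taxon,
            "total_length_m": round(self.axis.total_length, 6),
            "stations_m": {k: round(v, 6) for k, v in self.axis.stations.items()},
            "volume_m3": round(self.volume_m3, 9),
            "mass_kg": round(self.mass_kg, 6),
            "density_kg_m3": self.model.density,
            "fallbacks": list(self.fallbacks),
            "warnings": list(self.warnings),
        }


def _fill_missing(spec: SkeletonSpec, cfg: ReconstructionConfig):
    """Resolve nullable measurements via the published fallback equations."""
    m = spec.measurements
    fallbacks: list[str] = []
    trunk = m.trunk_length
    skull = m.skull_length
    neck = m.neck_length
    tail = m.tail_length
    max_ral = m.max_rib_arc_length

    if neck is None:
        cerv = spec.vertebrae_in("cervical") + spec.vertebrae_in("pectoral")
        if not cerv:
            raise ValueError("neck length missing and no cervical series to sum")
        neck = sum(
            effective_segment_lengths(
                cerv, spec.cartilage_fraction, spec.cartilage_fraction_by_region
            )
        )
        fallbacks.append("neck_length: summed from cervical series + cartilage")
    if max_ral is None:
        est_mm, _, eq = predict_missing_element(
            "max_ral", {"trunk": trunk * 1000.0}
        )
        max_ral = est_mm / 1000.0
        fallbacks.append(f"max_rib_arc_length: estimated from trunk via {eq}")
    if tail is None:
        caud = spec.vertebrae_in("caudal")
        if caud:
            tail = sum(
                effective_segment_lengths(
                    caud, spec.cartilage_fraction, spec.cartilage_fraction_by_region
                )
            )
            fallbacks.append("tail_length: summed from caudal series + cartilage")
        else:
            est_mm, _, eq = predict_missing_element(
                "tail", {"trunk": trunk * 1000.0}
            )
            tail = est_mm / 1000.0
            fallbacks.append(f"tail_length: estimated from trunk via {eq}")
    if skull is None:
        skull, _, eq = predict_missing_element(
            "skull_length",
            {"neck": neck, "cervical_count": m.cervical_count},
        )
        fallbacks.append(f"skull_length: estimated from neck and CN via {eq}")

    skull_w = m.skull_width_at_quadrate
    skull_h = m.skull_height_at_quadrate
    if skull_w is None:
        skull_w = cfg.skull_width_fraction * skull
        fallbacks.append("skull_width_at_quadrate: fraction of skull length")
    if skull_h is None:
        skull_h = cfg.skull_height_fraction * skull
        fallbacks.append("skull_height_at_quadrate: fraction of skull length")

    if spec.rib_coefficient is not None:
        rc = spec.rib_coefficient
    elif m.glenoid_rib_arc_length is not None:
        rc = rib_coefficient(m.glenoid_rib_arc_length, max_ral)
    else:
        rc = cfg.default_rib_coefficient
        fallbacks.append("rib_coefficient: clade default used")

    return {
        "trunk": trunk, "skull": skull, "neck": neck, "tail": tail,
        "max_ral": max_ral, "skull_w": skull_w, "skull_h": skull_h,
        "rib_coefficient": rc,
    }, fallbacks


def build_sections(
    spec: SkeletonSpec,
    filled: dict,
    cfg: ReconstructionConfig,
) -> dict[str, Contour]:
    """Construct the four transverse cross-sections of the body.

    The glenoid section aligns with the most anterior dorsal rib, so only
    the centrum tilt (theta3) applies to its rib plane; its ventral height
    comes from the coracoid via the Pythagorean construction.  The
    acetabulum section shares the glenoid width (common ventral line), its
    dorsal height follows the last dorsal rib, and its ventral height comes
    from the pubis.  The middle section takes its width from the ribs it
    transects (standardised to the largest rib plane, theta3 ~ 0) and its
    ventral height from the rib-coefficient relation.
    """
    ribs = sorted(spec.rib_planes, key=lambda r: r.dorsal_position)
    first, last = ribs[0], ribs[-1]

    # glenoid: only the centrum tilt applies at the anteriormost dorsal
    g_proj = project_rib_plane(replace(first, theta1=0.0, theta2=0.0))
    glen_width = 2.0 * g_proj.RPW_P3
    glen_dorsal = g_proj.RPH_P3
    glen_ventral = ventral_height_from_girdle(
        spec.measurements.coracoid_width, glen_width
    )

    # acetabulum: same width, posterior rib height, pubis ventral triangle
    a_proj = project_rib_plane(last)
    acet_dorsal = min(a_proj.RPH_P3, glen_dorsal)
    acet_ventral = ventral_height_from_girdle(
        spec.measurements.pubic_width_max, glen_width
    )

    # middle: ribs of the middle third, standardised to the largest plane
    n = len(ribs)
    mid_ribs = ribs[n // 3: max(n // 3 + 1, 2 * n // 3)] or ribs
    rph_std = max(r.RPH for r in ribs)
    rpw_std = max(r.RPW for r in ribs)
    std_ribs = [
        RibPlane(RPH=rph_std, RPW=rpw_std, theta1=r.theta1, theta2=r.theta2,
                 theta3=0.0, dorsal_position=r.dorsal_position)
        for r in mid_ribs
    ]
    mid_width = middle_section_width(std_ribs, [1.0] * len(std_ribs))
    mid_dorsal = max(project_rib_plane(r).RPH_P3 for r in std_ribs)
    mid_ventral = middle_ventral_height(
        glen_ventral, acet_ventral, filled["rib_coefficient"]
    )

    n_pts = cfg.n_contour_points
    mk = lambda kind, w, hd, hv: build_cross_section(  # noqa: E731
        SectionSpec(kind=kind, total_width=w, dorsal_height=hd,
                    ventral_height=hv, dorsal_exponent=cfg.dorsal_exponent,
                    ventral_exponent=cfg.ventral_exponent),
        n_pts,
    )
    return {
        "skull": skull_section(filled["skull_w"], filled["skull_h"], n_pts),
        "glenoid": mk(SectionKind.glenoid, glen_width, glen_dorsal, glen_ventral),
        "middle": mk(SectionKind.middle, mid_width, mid_dorsal, mid_ventral),
        "acetabulum": mk(SectionKind.acetabulum, glen_width, acet_dorsal,
                         acet_ventral),
    }


def _limb_planforms(spec: SkeletonSpec, cfg: ReconstructionConfig
                    ) -> tuple[list[LimbPlanform], list[str]]:
    m = spec.measurements
    planforms: list[LimbPlanform] = []
    warnings: list[str] = []
    pairs = (
        ("forelimb", m.forelimb_length, m.humerus_distal_width),
        ("hindlimb", m.hindlimb_length, m.femur_distal_width),
    )
    for name, span, root_width in pairs:
        if span is None or root_width is None:
            warnings.append(
                f"{name}: length or propodial width missing; limb slab skipped"
            )
            continue
        chords = tuple(f * root_width for f in cfg.limb_chord_profile)
        planforms.append(
            LimbPlanform(span=span, chords=chords,
                         thickness_fractions=cfg.limb_thickness,
                         name=f"{name}_left")
        )
        planforms.append(replace(planforms[-1], name=f"{name}_right"))
    return planforms, warnings


def reconstruct(
    spec: SkeletonSpec,
    cfg: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Run the full reconstruction for one skeleton.

    Raises :class:`SkeletonValidationError` if validation reports errors.
    """
    cfg = cfg or ReconstructionConfig()
    report = validate_skeleton(spec)
    if report.errors:
        raise SkeletonValidationError(report)
    warnings = [f"{f}: {msg}" for f, msg in report.warnings]

    filled, fallbacks = _fill_missing(spec, cfg)
    axis = assemble_body_axis(
        spec, skull_length=filled["skull"], neck_length=filled["neck"],
        tail_length=filled["tail"],
    )

    trunk_curve = None
    trunk_verts = (
        spec.vertebrae_in("pectoral") + spec.vertebrae_in("dorsal")
        + spec.vertebrae_in("sacral")[:1]
    )
    if trunk_verts:
        segs = effective_segment_lengths(
            trunk_verts, spec.cartilage_fraction, spec.cartilage_fraction_by_region
        )
        total = sum(segs)
        if filled["trunk"] <= total < (math.pi / 2) * filled["trunk"]:
            trunk_curve = solve_trunk_curve(filled["trunk"], segs)
        else:
            warnings.append(
                "trunk curve skipped: segment sum incompatible with the chord"
            )

    sections = build_sections(spec, filled, cfg)
    st = axis.stations
    slabs = (
        Slab(POINT, sections["skull"], st["quadrate"] - st["snout_tip"],
             cfg.n_subslabs, name="snout"),
        Slab(sections["skull"], sections["glenoid"],
             st["glenoid"] - st["quadrate"], cfg.n_subslabs, name="neck"),
        Slab(sections["glenoid"], sections["middle"],
             st["middle"] - st["glenoid"], cfg.n_subslabs, name="front_trunk"),
        Slab(sections["middle"], sections["acetabulum"],
             st["acetabulum"] - st["middle"], cfg.n_subslabs, name="rear_trunk"),
        Slab(sections["acetabulum"], POINT, st["tail_tip"] - st["acetabulum"],
             cfg.n_subslabs, name="tail"),
    )
    limbs, limb_warnings = _limb_planforms(spec, cfg)
    warnings.extend(limb_warnings)
    skeletal = BodyModel(axial_slabs=slabs, limb_slabs=tuple(limbs),
                         density=cfg.density)
    skeletal.validate_plesiosaur_layout()
    model = apply_soft_tissue(skeletal, cfg.soft_tissue)
    volume, mass = body_mass(model)
    return ReconstructionResult(
        taxon=spec.taxon, axis=axis, sections=sections,
        skeletal_model=skeletal, model=model, trunk_curve=trunk_curve,
        volume_m3=volume, mass_kg=mass,
        fallbacks=tuple(fallbacks), warnings=tuple(warnings),
    )
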