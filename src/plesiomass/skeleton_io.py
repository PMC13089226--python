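"""Skeletal measurement data model, validation, and readers/writers.

Two on-disk formats are supported:

* a measurement CSV with one row per specimen, header names matching the
  :class:`MeasurementSet` field names, and an optional leading metadata line
  ``# units: m|cm|mm`` (values are converted to meters on load);
* a versioned skeleton JSON (``schema_version`` field) carrying the full
  per-specimen reconstruction input: the measurement set, the ordered
  vertebral column, per-dorsal rib planes, cartilage fractions and limb
  planform chords.

Internally everything is in meters.  Only ``taxon`` and the cervical count
``CN`` are strictly required; every other field is nullable and either has a
documented downstream fallback (a published regression equation) or causes
the corresponding reconstruction stage to be skipped.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .ribcage_geometry import RibPlane

__all__ = [
    "SCHEMA_VERSION",
    "Region",
    "VertebralCentrum",
    "MeasurementSet",
    "SkeletonSpec",
    "ValidationReport",
    "load_measurements",
    "write_measurements",
    "load_skeleton",
    "write_skeleton",
    "validate_skeleton",
]

SCHEMA_VERSION = 1

_UNIT_FACTORS = {"m": 1.0, "cm": 0.01, "mm": 0.001}

#: anatomical ordering of vertebral regions, cranial to caudal
REGION_ORDER = ("cervical", "pectoral", "dorsal", "sacral", "caudal")


class Region(str, Enum):
    cervical = "cervical"
    pectoral = "pectoral"
    dorsal = "dorsal"
    sacral = "sacral"
    caudal = "caudal"


class VertebralCentrum(BaseModel):
    """One vertebral centrum: region, 1-based position, and dimensions (m)."""

    region: Region
    position: int = Field(ge=1)
    length: float = Field(gt=0)
    width: float = Field(gt=0)
    height: float = Field(gt=0)


class MeasurementSet(BaseModel):
    """Per-specimen linear measurements (meters; nullable unless noted).

    ``cervical_count`` (CN) is the only required numeric field.  The girdle
    and propodial dimensions feed the ribcage ventral-height construction
    and the limb planforms; the axial lengths feed the body-axis assembly.
    """

    cervical_count: int = Field(ge=1)
    skull_length: Optional[float] = None
    skull_width_at_quadrate: Optional[float] = None
    skull_height_at_quadrate: Optional[float] = None
    neck_length: Optional[float] = None
    trunk_length: Optional[float] = None
    tail_length: Optional[float] = None
    max_rib_arc_length: Optional[float] = None
    glenoid_rib_arc_length: Optional[float] = None
    coracoid_length: Optional[float] = None
    coracoid_width: Optional[float] = None
    pubic_length: Optional[float] = None
    pubic_width_max: Optional[float] = None
    ischium_length: Optional[float] = None
    ischium_width: Optional[float] = None
    humerus_length: Optional[float] = None
    humerus_distal_width: Optional[float] = None
    femur_length: Optional[float] = None
    femur_distal_width: Optional[float] = None
    forelimb_length: Optional[float] = None
    hindlimb_length: Optional[float] = None
    dorsal_centrum_mean_length: Optional[float] = None
    dorsal_centrum_mean_width: Optional[float] = None
    dorsal_centrum_mean_height: Optional[float] = None

    @field_validator("*", mode="after")
    @classmethod
    def _positive(cls, v, info):
        if info.field_name == "cervical_count":
            return v
        if v is not None and v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v


_MEASUREMENT_FIELDS = list(MeasurementSet.model_fields)


class SkeletonSpec(BaseModel):
    """Full per-specimen input driving one body reconstruction."""

    taxon: str
    specimen: str = ""
    clade: str = ""
    measurements: MeasurementSet
    vertebrae: list[VertebralCentrum] = Field(default_factory=list)
    rib_planes: list[RibPlane] = Field(default_factory=list)
    cartilage_fraction: float = Field(default=0.10, ge=0)
    cartilage_fraction_by_region: dict[str, float] = Field(default_factory=dict)
    rib_coefficient: Optional[float] = None
    limb_planforms: dict[str, list[float]] = Field(default_factory=dict)
    maturity_flag: bool = True

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("rib_planes", mode="before")
    @classmethod
    def _coerce_rib_planes(cls, v):
        return [RibPlane(**p) if isinstance(p, dict) else p for p in v]

    def vertebrae_in(self, region: str | Region) -> list[VertebralCentrum]:
        region = Region(region)
        return [v for v in self.vertebrae if v.region == region]


class ValidationReport(BaseModel):
    """Validation outcome; empty ``errors`` means the spec is reconstructable."""

    errors: list[tuple[str, str]] = Field(default_factory=list)
    warnings: list[tuple[str, str]] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# measurement CSV
# ---------------------------------------------------------------------------

def _read_units_line(path: Path) -> float:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        decl = first.lstrip("#").strip().lower()
        if decl.startswith("units:"):
            unit = decl.split(":", 1)[1].strip()
            if unit not in _UNIT_FACTORS:
                raise ValueError(f"unknown unit declaration {unit!r}")
            return _UNIT_FACTORS[unit]
        raise ValueError(f"unrecognised metadata line: {first!r}")
    return 1.0


def load_measurements(path) -> tuple[list[str], list[MeasurementSet], list[str]]:
    """Read a measurement CSV.

    Returns ``(taxa, measurement_sets, warnings)``; linear measurements are
    converted to meters according to the optional ``# units:`` metadata line.
    Unknown columns are ignored with a warning.
    """
    path = Path(path)
    factor = _read_units_line(path)
    df = pd.read_csv(path, comment="#")
    if "taxon" not in df.columns or "cervical_count" not in df.columns:
        raise ValueError("measurement CSV must carry 'taxon' and 'cervical_count'")
    warnings = [
        f"ignoring unknown column {c!r}"
        for c in df.columns
        if c not in _MEASUREMENT_FIELDS and c != "taxon"
    ]
    taxa: list[str] = []
    records: list[MeasurementSet] = []
    for idx, row in df.iterrows():
        kwargs = {}
        for name in _MEASUREMENT_FIELDS:
            if name not in df.columns or pd.isna(row[name]):
                continue
            value = row[name]
            try:
                value = float(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"non-numeric value {value!r} in row {idx}, column {name!r}"
                ) from exc
            if name == "cervical_count":
                kwargs[name] = int(value)
            else:
                kwargs[name] = value * factor
        try:
            records.append(MeasurementSet(**kwargs))
        except Exception as exc:
            raise ValueError(f"invalid measurements in row {idx}: {exc}") from exc
        taxa.append(str(row["taxon"]))
    return taxa, records, warnings


def write_measurements(path, taxa: list[str], records: list[MeasurementSet]) -> None:
    """Write a measurement CSV (meters) readable by :func:`load_measurements`."""
    rows = []
    for taxon, rec in zip(taxa, records):
        row = {"taxon": taxon}
        row.update(rec.model_dump())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["taxon"] + _MEASUREMENT_FIELDS)
    with open(path, "w") as fh:
        fh.write("# units: m\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# skeleton JSON
# ---------------------------------------------------------------------------

def load_skeleton(path) -> SkeletonSpec:
    """Read a versioned skeleton JSON document into a :class:`SkeletonSpec`."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported skeleton schema_version {version!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    spec = SkeletonSpec(**doc)
    report = validate_skeleton(spec)
    order_errors = [e for e in report.errors if e[0] == "vertebrae"]
    if order_errors:
        raise ValueError("; ".join(msg for _, msg in order_errors))
    return spec


def write_skeleton(path, spec: SkeletonSpec) -> None:
    doc = {"schema_version": SCHEMA_VERSION}
    doc.update(spec.model_dump(exclude={"rib_planes"}))
    doc["rib_planes"] = [vars(p) for p in spec.rib_planes]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_skeleton(spec: SkeletonSpec) -> ValidationReport:
    """Check a skeleton specification against its structural invariants.

    Errors mark violations that prevent reconstruction (out-of-order
    vertebral regions, cervical-count mismatch, out-of-range rib
    coefficient); warnings name nullable fields that downstream stages will
    fill by a published fallback equation (maximum rib arc length and tail
    length from trunk length; skull length from neck length and cervical
    count).
    """
    errors: list[tuple[str, str]] = []
    warnings: list[tuple[str, str]] = []
    m = spec.measurements

    seen = [v.region.value for v in spec.vertebrae]
    order = [r for r in REGION_ORDER if r in seen]
    compact = [r for r, _ in _dedupe_runs(seen)]
    if compact != order or len(compact) != len(set(compact)):
        errors.append(
            ("vertebrae", "vertebral regions must be ordered "
             "cervical -> pectoral -> dorsal -> sacral -> caudal without "
             "interleaving")
        )
    for region in set(seen):
        positions = [v.position for v in spec.vertebrae if v.region.value == region]
        if sorted(positions) != list(range(1, len(positions) + 1)):
            errors.append(
                (f"vertebrae[{region}]",
                 "positions must be consecutive 1-based indices")
            )
    n_cerv = seen.count("cervical")
    if n_cerv and n_cerv != m.cervical_count:
        errors.append(
            ("cervical_count",
             f"cervical_count={m.cervical_count} but {n_cerv} cervical "
             "centra listed")
        )
    if spec.rib_coefficient is not None and not 0 < spec.rib_coefficient <= 1:
        errors.append(("rib_coefficient", "rib coefficient must be in (0,1]"))
    for region, frac in spec.cartilage_fraction_by_region.items():
        if region not in REGION_ORDER:
            errors.append(("cartilage_fraction_by_region",
                           f"unknown region {region!r}"))
        elif frac < 0:
            errors.append(("cartilage_fraction_by_region",
                           f"fraction for {region} must be >= 0"))

    if m.max_rib_arc_length is None:
        if m.trunk_length is not None:
            warnings.append(
                ("max_rib_arc_length",
                 "missing; will be estimated from trunk length via the "
                 "published trunk-to-maxRAL regression")
            )
        else:
            errors.append(
                ("max_rib_arc_length",
                 "missing and trunk_length unavailable for the fallback")
            )
    if m.tail_length is None and not spec.vertebrae_in("caudal"):
        if m.trunk_length is not None:
            warnings.append(
                ("tail_length",
                 "no caudal series or tail length; will be estimated from "
                 "trunk length via the published trunk-to-tail regression")
            )
        else:
            errors.append(("tail_length", "missing with no fallback input"))
    if m.skull_length is None:
        if m.neck_length is not None:
            warnings.append(
                ("skull_length",
                 "missing; will be estimated from neck length and cervical "
                 "count via the published log-logistic skull-neck relation")
            )
        else:
            errors.append(("skull_length", "missing with no fallback input"))
    if m.trunk_length is None:
        errors.append(("trunk_length", "required for body-axis assembly"))
    for name in ("coracoid_width", "pubic_width_max"):
        if getattr(m, name) is None:
            errors.append((name, "required for the ventral-height construction"))
    if not spec.rib_planes:
        errors.append(("rib_planes", "at least one dorsal rib plane is required"))
    return ValidationReport(errors=errors, warnings=warnings)


def _dedupe_runs(seq):
    out = []
    for item in seq:
        if not out or out[-1][0] != item:
            out.append((item, 1))
        else:
            out[-1] = (item, out[-1][1] + 1)
    return out
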