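"""Published predictor equations for plesiosaur reconstruction and body mass.

Ships, as versioned package data, the full set of published regression
equations for Plesiosauria:

* 13 missing-element equations — maximum rib arc length from trunk length,
  tail length from trunk/femur dimensions (OLS and PGLS variants), and the
  skull-to-(skull+neck) ratio as a function of cervical count (straight-line
  and four-parameter log-logistic variants);
* 14 OLS body-mass equations (one per skeletal proxy) and the 14 PGLS
  counterparts fitted on pruned datasets.

The preferred estimators are the OLS trunk-to-maxRAL and trunk-to-tail
equations, the whole-dataset log-logistic skull-neck curve, and — for body
mass — the OLS table (trunk length and dorsal centrum volume being the most
reliable proxies).  The missing-element equations operate in millimeters:
with trunk = 1 m a meter reading of the trunk-to-tail equation would give a
tail three times the trunk, anatomically impossible for a plesiosaur,
whereas millimeters give tail ~ 1.0x trunk.  The body-mass equations take
meters and return kilograms.  Every record carries its own units so the
scales cannot be misapplied.

These packaged coefficients are authoritative constants; this module never
refits them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

from .allometry import PredictionInterval, prediction_interval

__all__ = [
    "EquationRecord",
    "MassEstimate",
    "packaged_equations",
    "get_equation",
    "evaluate_equation",
    "predict_missing_element",
    "predict_body_mass",
    "MASS_PROXIES",
]

EQUATION_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class EquationRecord:
    """One published equation with its fit statistics and units."""

    id: str
    response: str
    predictors: tuple[str, ...]
    form: str  # "log-linear" | "log-logistic"
    method: str  # "OLS" | "PGLS" | "LL4"
    coefficients: dict[str, float]
    units_in: str
    units_out: str
    n: int
    r_squared: Optional[float]
    mean_abs_pe: Optional[float]
    sd_abs_pe: Optional[float]
    aicc: Optional[float]
    preferred: bool

    def evaluate_log10(self, x_log10: float) -> float:
        """Evaluate the model on the log10 scale of its predictor."""
        c = self.coefficients
        if self.form == "log-linear":
            return c["slope"] * x_log10 + c["intercept"]
        if self.form == "log-logistic":
            return c["offset"] + c["numerator"] / (
                1.0 + (x_log10 / c["scale"]) ** c["exponent"]
            )
        raise ValueError(f"unknown equation form {self.form!r}")


@lru_cache(maxsize=1)
def packaged_equations() -> tuple[EquationRecord, ...]:
    """The full versioned equation table shipped with the package."""
    text = (
        resources.files("plesiomass").joinpath("data/equations.json").read_text()
    )
    doc = json.loads(text)
    if doc.get("schema_version") != EQUATION_SCHEMA_VERSION:
        raise RuntimeError("equation table schema version mismatch")
    return tuple(
        EquationRecord(
            id=r["id"],
            response=r["response"],
            predictors=tuple(r["predictors"]),
            form=r["form"],
            method=r["method"],
            coefficients=dict(r["coefficients"]),
            units_in=r["units_in"],
            units_out=r["units_out"],
            n=r["n"],
            r_squared=r["r_squared"],
            mean_abs_pe=r["mean_abs_pe"],
            sd_abs_pe=r["sd_abs_pe"],
            aicc=r["aicc"],
            preferred=r["preferred"],
        )
        for r in doc["records"]
    )


def get_equation(equation_id: str) -> EquationRecord:
    for rec in packaged_equations():
        if rec.id == equation_id:
            return rec
    raise KeyError(f"no packaged equation with id {equation_id!r}")


def evaluate_equation(equation_id: str, value: float) -> float:
    """Antilog-scale evaluation of a log-linear record at a predictor value
    given in the record's input units."""
    import math

    rec = get_equation(equation_id)
    if value <= 0:
        raise ValueError("predictor value must be positive")
    return 10.0 ** rec.evaluate_log10(math.log10(value))


# ---------------------------------------------------------------------------
# missing elements
# ---------------------------------------------------------------------------

#: preferred equation per estimable element
_ELEMENT_EQUATIONS = {"max_ral": "eq9", "tail": "eq15", "skull_length": "eq20"}


def predict_missing_element(
    element: str,
    inputs: dict[str, float],
    limb_coefficients: tuple[float, float] | None = None,
) -> tuple[float, PredictionInterval, str]:
    """Estimate a missing skeletal element from the preferred published
    equation.

    Elements and required inputs (units as stated):

    * ``max_ral`` — ``trunk`` in mm; returns maximum rib arc length in mm;
    * ``tail`` — ``trunk`` in mm; returns tail length in mm;
    * ``skull_length`` — ``neck`` in m and ``cervical_count``; inverts the
      log-logistic skull-to-(skull+neck) ratio r into
      ``SKL = neck * r / (1 - r)`` (m);
    * ``limb_length`` — ``propodial_distal_width`` in mm plus externally
      supplied log-linear ``limb_coefficients`` (slope, intercept); the
      coefficients are not part of the packaged table.

    Returns ``(estimate, symmetric interval, equation id)``; the interval
    uses the equation's mean |%PE| where published.
    """
    import math

    if element in ("max_ral", "tail"):
        rec = get_equation(_ELEMENT_EQUATIONS[element])
        trunk = inputs.get("trunk")
        if trunk is None or trunk <= 0:
            raise ValueError(f"{element} estimation needs 'trunk' in mm (> 0)")
        value = 10.0 ** rec.evaluate_log10(math.log10(trunk))
        return value, prediction_interval(value, rec.mean_abs_pe or 0.0), rec.id

    if element == "skull_length":
        rec = get_equation(_ELEMENT_EQUATIONS[element])
        neck = inputs.get("neck")
        cn = inputs.get("cervical_count")
        if neck is None or neck <= 0 or cn is None or cn < 1:
            raise ValueError(
                "skull_length estimation needs 'neck' in m and 'cervical_count'"
            )
        ratio = 10.0 ** rec.evaluate_log10(math.log10(cn))
        if ratio >= 1.0:
            raise ValueError(
                f"skull-to-(skull+neck) ratio {ratio:.4f} >= 1 is infeasible"
            )
        skl = neck * ratio / (1.0 - ratio)
        return skl, prediction_interval(skl, rec.mean_abs_pe or 0.0), rec.id

    if element == "limb_length":
        if limb_coefficients is None:
            raise ValueError(
                "limb_length estimation requires external regression "
                "coefficients (slope, intercept); none are packaged"
            )
        width = inputs.get("propodial_distal_width")
        if width is None or width <= 0:
            raise ValueError("limb_length estimation needs 'propodial_distal_width'")
        slope, intercept = limb_coefficients
        value = 10.0 ** (slope * math.log10(width) + intercept)
        return value, prediction_interval(value, 0.0), "external_limb_equation"

    raise ValueError(
        f"unknown element {element!r}; choose from "
        "max_ral, tail, skull_length, limb_length"
    )


# ---------------------------------------------------------------------------
# body mass
# ---------------------------------------------------------------------------

MASS_PROXIES = (
    "skl_cn", "trunk", "vertebral_volume", "vertebral_area",
    "humerus_length", "humerus_width", "femur_length", "femur_width",
    "coracoid_length", "coracoid_width", "pubic_length", "pubic_width_max",
    "ischium_length", "ischium_width",
)

#: composite proxies assembled from components before the table lookup
_COMPOSITES = {
    "skl_cn": ("skull_length", "cervical_count"),
    "vertebral_volume": (
        "dorsal_centrum_mean_length",
        "dorsal_centrum_mean_width",
        "dorsal_centrum_mean_height",
    ),
    "vertebral_area": (
        "dorsal_centrum_mean_width",
        "dorsal_centrum_mean_height",
    ),
}


@dataclass(frozen=True)
class MassEstimate:
    """A body-mass prediction with its symmetric error interval."""

    mass: float  # kg
    interval: PredictionInterval
    proxy_used: str
    equation_id: str


def composite_proxy_value(proxy: str, components: dict[str, float]) -> float:
    """Assemble a composite proxy (product of its components, meters)."""
    names = _COMPOSITES[proxy]
    missing = [nm for nm in names if nm not in components]
    if missing:
        raise ValueError(f"composite proxy {proxy!r} missing components {missing}")
    value = 1.0
    for nm in names:
        v = float(components[nm])
        if v <= 0:
            raise ValueError(f"component {nm} must be positive")
        value *= v
    return value


def predict_body_mass(
    proxy: str,
    value: float | None = None,
    components: dict[str, float] | None = None,
    table_choice: str = "OLS",
) -> MassEstimate:
    """Predict body mass (kg) from a skeletal proxy measured in meters.

    ``table_choice`` selects the OLS table (the recommended default) or the
    PGLS table (retained for comparison; no published prediction errors, so
    its intervals collapse to the point estimate).  Composite proxies
    (``skl_cn``, ``vertebral_volume``, ``vertebral_area``) may be given
    either as a precomputed ``value`` or as their ``components``.
    """
    import math

    if proxy not in MASS_PROXIES:
        raise ValueError(
            f"unknown proxy {proxy!r}; available proxies: {', '.join(MASS_PROXIES)}"
        )
    if table_choice not in ("OLS", "PGLS"):
        raise ValueError("table_choice must be 'OLS' or 'PGLS'")
    if value is None:
        if proxy in _COMPOSITES and components:
            value = composite_proxy_value(proxy, components)
        else:
            raise ValueError("a proxy value (or its components) is required")
    if value <= 0:
        raise ValueError("proxy value must be positive")
    prefix = "table2" if table_choice == "OLS" else "table3"
    rec = get_equation(f"{prefix}_{proxy}")
    mass = 10.0 ** rec.evaluate_log10(math.log10(value))
    interval = prediction_interval(mass, rec.mean_abs_pe or 0.0)
    return MassEstimate(mass=mass, interval=interval, proxy_used=proxy,
                        equation_id=rec.id)
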