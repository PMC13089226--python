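"""Seeded generators for every input the pipeline consumes.

No machine-readable plesiosaur measurement compendium is distributed with
the package, so these generators emulate the statistical structure of the
real datasets: log-linear allometries with multiplicative lognormal noise
(normal on the log10 scale, the space the models are fitted in), the
log-logistic skull-neck relation over cervical counts ~12-76, Brownian
trait evolution on dated pure-birth trees, fully specified synthetic
skeletons for three clade archetypes, and parametric bodies with
closed-form volumes for exercising the volume integrator.

Generating parameters default to the packaged published coefficients, so
noiseless parameter-recovery tests double as checks that the equation table
is encoded correctly.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .allometry import DatedTree, brownian_covariance
from .csm_volumetrics import POINT, BodyModel, Slab
from .reference_predictors import get_equation
from .ribcage_geometry import (
    Contour,
    RibPlane,
    SectionKind,
    SectionSpec,
    build_cross_section,
)
from .skeleton_io import MeasurementSet, Region, SkeletonSpec, VertebralCentrum

__all__ = [
    "SyntheticConfig",
    "gen_allometric_dataset",
    "gen_skullneck_dataset",
    "gen_phylo_dataset",
    "gen_skeleton",
    "gen_parametric_body",
    "SKELETON_TEMPLATES",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for the tabular generators.

    ``noise_sigma`` is the standard deviation of the additive normal noise
    on the log10 scale; ``x_range`` bounds the predictor on the antilog
    scale; ``generating_params`` are the equation coefficients the data are
    drawn from (default: the packaged preferred equations).
    """

    seed: int = 0
    n: int = 50
    noise_sigma: float = 0.05
    x_range: tuple[float, float] = (0.5, 10.0)
    generating_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.x_range[0] <= 0 or self.x_range[1] <= self.x_range[0]:
            raise ValueError("x_range must be a positive, increasing interval")


def gen_allometric_dataset(cfg: SyntheticConfig) -> pd.DataFrame:
    """Antilog (x, y) pairs from a log-linear allometry with lognormal noise.

    x is log-uniform on ``x_range``;
    ``log10 y = slope * log10 x + intercept + N(0, sigma)``.
    Default generating coefficients: the trunk-to-mass equation of the
    published OLS body-mass table.
    """
    params = cfg.generating_params or dict(get_equation("table2_trunk").coefficients)
    slope, intercept = params["slope"], params["intercept"]
    rng = np.random.default_rng(cfg.seed)
    lo, hi = np.log10(cfg.x_range[0]), np.log10(cfg.x_range[1])
    logx = rng.uniform(lo, hi, cfg.n)
    logy = slope * logx + intercept + rng.normal(0.0, cfg.noise_sigma, cfg.n)
    return pd.DataFrame({"x": 10.0**logx, "y": 10.0**logy})


def gen_skullneck_dataset(
    cfg: SyntheticConfig,
    cn_range: tuple[int, int] = (12, 76),
    max_retries: int = 100,
) -> pd.DataFrame:
    """Synthetic (cervical_count, skull_length, neck_length) records.

    The skull-to-(skull+neck) ratio follows the packaged log-logistic curve
    over the cervical-count range with noise on the log10 scale; draws whose
    noisy ratio reaches 1 are resampled (bounded retries).  Skull and neck
    lengths are materialised from a lognormally drawn skull+neck total.
    """
    if not (5 <= cn_range[0] < cn_range[1] <= 80):
        raise ValueError("cervical-count range must lie within [5, 80]")
    rec = get_equation("eq20")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for _ in range(cfg.n):
        cn = int(rng.integers(cn_range[0], cn_range[1] + 1))
        log_ratio_mean = rec.evaluate_log10(math.log10(cn))
        for _attempt in range(max_retries):
            log_ratio = log_ratio_mean + rng.normal(0.0, cfg.noise_sigma)
            ratio = 10.0**log_ratio
            if ratio < 1.0:
                break
        else:
            raise RuntimeError("could not draw a feasible skull-neck ratio")
        total = 10.0 ** rng.normal(0.5, 0.3)  # skull+neck total, m
        rows.append(
            {"cervical_count": cn, "skull_length": ratio * total,
             "neck_length": (1.0 - ratio) * total, "ratio": ratio}
        )
    return pd.DataFrame(rows)


def gen_phylo_dataset(
    n_taxa: int,
    birth_rate: float = 0.1,
    trait_params: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[DatedTree, pd.DataFrame]:
    """A dated pure-birth tree plus regression traits with Brownian residuals.

    The response is ``slope * x + intercept`` plus residuals drawn from
    MVN(0, sigma2 * C) where C is the tree's Brownian covariance; the
    predictor x is drawn i.i.d. normal.  ``trait_params`` keys: ``slope``
    (default 1.0), ``intercept`` (0.0), ``sigma2`` (0.01 per Myr).
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    params = {"slope": 1.0, "intercept": 0.0, "sigma2": 0.01}
    params.update(trait_params or {})
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    rng = np.random.default_rng(seed)
    # the simulation stops at the event creating the last tip, which leaves
    # a zero-length cherry; extend every pendant edge by one extra waiting
    # time so the tips stay contemporaneous and the covariance is full rank
    extra = rng.exponential(1.0 / (birth_rate * n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    dated = DatedTree(tree=tree, tip_ages={f"t{i + 1}": 0.0 for i in range(n_taxa)})
    taxa = dated.taxon_labels()
    C = brownian_covariance(dated, taxa)
    x = rng.normal(0.0, 1.0, n_taxa)
    if params["sigma2"] > 0:
        L = np.linalg.cholesky(params["sigma2"] * C)
        resid = L @ rng.normal(0.0, 1.0, n_taxa)
    else:
        resid = np.zeros(n_taxa)
    y = params["slope"] * x + params["intercept"] + resid
    traits = pd.DataFrame({"taxon": taxa, "x": x, "y": y})
    return dated, traits


# ---------------------------------------------------------------------------
# whole skeletons
# ---------------------------------------------------------------------------

#: Clade archetypes: vertebral counts, proportions and maximum slant angles
#: chosen to bracket the documented range (max bucket-handle angle ~9 deg in
#: cryptoclidids up to ~30 deg in elasmosaurids; cervical counts ~13-76).
SKELETON_TEMPLATES: dict[str, dict] = {
    "elasmosaurid-like": {
        "cervical": 62, "dorsal": 19, "caudal": 30,
        "centrum_length": 0.055, "theta1_max": 25.0, "theta2_max": 30.0,
        "rib_height_factor": 5.2, "clade": "Elasmosauridae",
    },
    "cryptoclidid-like": {
        "cervical": 30, "dorsal": 20, "caudal": 28,
        "centrum_length": 0.045, "theta1_max": 10.0, "theta2_max": 9.0,
        "rib_height_factor": 6.0, "clade": "Cryptoclididae",
    },
    "pliosaurid-like": {
        "cervical": 20, "dorsal": 22, "caudal": 30,
        "centrum_length": 0.060, "theta1_max": 15.0, "theta2_max": 20.0,
        "rib_height_factor": 6.5, "clade": "Pliosauridae",
    },
}

_N_PECTORALS = 3
_N_SACRALS = 3


def gen_skeleton(
    template: str = "cryptoclidid-like",
    size_scale: float = 1.0,
    seed: int = 0,
) -> SkeletonSpec:
    """An internally consistent synthetic skeleton for one clade archetype.

    All linear dimensions are proportional to ``size_scale`` (the same seed
    at two scales yields geometrically similar skeletons, so downstream
    mass estimates obey the s^3 similarity law).  Rib slant angles increase
    gradually from 0 in the anterior dorsals to the template maximum in the
    mid-to-posterior dorsal region, and rib lengths rise then fall along
    the series.  Girdle widths are drawn wide enough that the ventral
    Pythagorean construction is always feasible.
    """
    if template not in SKELETON_TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; choose from "
            f"{sorted(SKELETON_TEMPLATES)}"
        )
    if size_scale <= 0:
        raise ValueError("size_scale must be positive")
    tpl = SKELETON_TEMPLATES[template]
    rng = np.random.default_rng(seed)
    s = size_scale
    cl = tpl["centrum_length"]

    vertebrae: list[VertebralCentrum] = []
    jitter = lambda: float(rng.normal(1.0, 0.02))  # noqa: E731

    def add_series(region: Region, count: int, lengths: np.ndarray) -> None:
        for i in range(count):
            ln = lengths[i] * jitter() * s
            vertebrae.append(
                VertebralCentrum(
                    region=region, position=i + 1, length=ln,
                    width=ln * 1.15, height=ln * 0.95,
                )
            )

    n_c, n_d, n_t = tpl["cervical"], tpl["dorsal"], tpl["caudal"]
    add_series(Region.cervical, n_c,
               cl * (0.8 + 0.4 * np.sin(np.linspace(0.2, 2.6, n_c))))
    add_series(Region.pectoral, _N_PECTORALS, np.full(_N_PECTORALS, cl * 1.05))
    add_series(Region.dorsal, n_d, np.full(n_d, cl * 1.1))
    add_series(Region.sacral, _N_SACRALS, np.full(_N_SACRALS, cl * 0.95))
    add_series(Region.caudal, n_t,
               cl * np.linspace(0.9, 0.25, n_t))

    cart = 0.10
    neck = sum(v.length for v in vertebrae if v.region == Region.cervical)
    neck *= 1.0 + cart
    trunk_arc = sum(
        v.length for v in vertebrae
        if v.region in (Region.pectoral, Region.dorsal)
    )
    trunk_arc += vertebrae[n_c + _N_PECTORALS + n_d].length  # first sacral
    trunk_arc *= 1.0 + cart
    trunk = trunk_arc / 1.01  # gentle dorsal arch: arc 1% longer than chord
    tail = (1.0 + cart) * sum(
        v.length for v in vertebrae if v.region == Region.caudal
    )

    # skull consistent with the published skull-neck relation
    ratio = 10.0 ** get_equation("eq20").evaluate_log10(math.log10(n_c))
    skull = neck * ratio / (1.0 - ratio)

    # dorsal rib planes: lengths rise then fall, slants ramp up from zero
    max_ral = tpl["rib_height_factor"] * cl * 1.1 * s
    rib_planes = []
    for i in range(n_d):
        u = i / (n_d - 1)
        length_frac = 0.55 + 0.45 * math.sin(math.pi * min(u / 0.55, 1.0) * 0.5) \
            if u <= 0.55 else 1.0 - 0.35 * (u - 0.55) / 0.45
        ramp = min(u / 0.6, 1.0)
        rib_planes.append(
            RibPlane(
                RPH=0.80 * max_ral * length_frac,
                RPW=0.45 * max_ral * length_frac,
                theta1=tpl["theta1_max"] * ramp,
                theta2=tpl["theta2_max"] * ramp,
                theta3=8.0 * (1.0 - min(u / 0.4, 1.0)),
                dorsal_position=i + 1,
            )
        )

    rib_coef = 0.78
    glenoid_half_width = rib_planes[0].RPW
    acetab_half_width = glenoid_half_width  # sections share a width
    coracoid_w = glenoid_half_width * 1.45
    pubis_w = acetab_half_width * 1.40

    hum_l = 1.35 * max_ral
    fem_l = 1.30 * max_ral
    measurements = MeasurementSet(
        cervical_count=n_c,
        skull_length=skull,
        skull_width_at_quadrate=0.52 * skull,
        skull_height_at_quadrate=0.38 * skull,
        neck_length=neck,
        trunk_length=trunk,
        tail_length=tail,
        max_rib_arc_length=max_ral,
        glenoid_rib_arc_length=rib_coef * max_ral,
        coracoid_length=1.1 * coracoid_w,
        coracoid_width=coracoid_w,
        pubic_length=1.0 * pubis_w,
        pubic_width_max=pubis_w,
        ischium_length=0.8 * pubis_w,
        ischium_width=0.7 * pubis_w,
        humerus_length=hum_l,
        humerus_distal_width=0.45 * hum_l,
        femur_length=fem_l,
        femur_distal_width=0.42 * fem_l,
        forelimb_length=3.6 * hum_l,
        hindlimb_length=3.4 * fem_l,
        dorsal_centrum_mean_length=cl * 1.1 * s,
        dorsal_centrum_mean_width=cl * 1.1 * 1.15 * s,
        dorsal_centrum_mean_height=cl * 1.1 * 0.95 * s,
    )
    return SkeletonSpec(
        taxon=f"synthetic_{template.replace('-like', '')}_{seed}",
        specimen=f"SYN-{seed}",
        clade=tpl["clade"],
        measurements=measurements,
        vertebrae=vertebrae,
        rib_planes=rib_planes,
        cartilage_fraction=cart,
        rib_coefficient=rib_coef,
    )


# ---------------------------------------------------------------------------
# closed-form oracle bodies
# ---------------------------------------------------------------------------

def _bottom_anchored_ellipse(a: float, b: float, n_points: int) -> Contour:
    """Ellipse with semi-axes (a lateral, b vertical), ventral point at y=0."""
    spec = SectionSpec(
        kind=SectionKind.middle, total_width=2.0 * a,
        dorsal_height=b, ventral_height=b,
        dorsal_exponent=2.0, ventral_exponent=2.0,
    )
    return build_cross_section(spec, n_points)


def gen_parametric_body(
    shape: dict,
    seed: int = 0,
    n_vertices: int = 1024,
) -> tuple[BodyModel, float]:
    """A body model from a documented closed-form family plus its exact
    volume.

    Families (``shape["family"]``):

    * ``"cylinder"`` — params r, length; V = pi r^2 L;
    * ``"cone_capped_cylinder"`` — params r, length, cap_length; a cylinder
      with a cone at each end; V = pi r^2 (L + 2 Lcap / 3);
    * ``"spheroid"`` — params a, b, c (semi-axes: lateral, vertical, axial);
      built from proportional elliptical sections on a fine axial grid;
      V = 4/3 pi a b c;
    * ``"lofted_ellipse"`` — params a, b, scale2, length; a proportional
      elliptical frustum from semi-axes (a, b) to (scale2*a, scale2*b);
      V = pi a b L (1 + s + s^2) / 3.

    ``seed`` is accepted for interface uniformity (the families are
    deterministic).  The analytic volume uses the true circle constant; the
    polygonal sections introduce a relative area deficit of about
    2 pi^2 / (3 n_vertices^2).
    """
    del seed
    family = shape.get("family")
    if family == "cylinder":
        r, L = float(shape["r"]), float(shape["length"])
        circle = _bottom_anchored_ellipse(r, r, n_vertices)
        model = BodyModel(axial_slabs=(Slab(circle, circle, L, name="cylinder"),))
        return model, math.pi * r * r * L
    if family == "cone_capped_cylinder":
        r = float(shape["r"])
        L = float(shape["length"])
        cap = float(shape["cap_length"])
        circle = _bottom_anchored_ellipse(r, r, n_vertices)
        slabs = (
            Slab(POINT, circle, cap, name="nose_cone"),
            Slab(circle, circle, L, name="cylinder"),
            Slab(circle, POINT, cap, name="tail_cone"),
        )
        return (BodyModel(axial_slabs=slabs),
                math.pi * r * r * (L + 2.0 * cap / 3.0))
    if family == "spheroid":
        a, b, c = (float(shape[k]) for k in ("a", "b", "c"))
        m = int(shape.get("n_stations", 200))
        z = np.linspace(-c, c, m + 1)
        k = np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, 1.0))
        slabs = []
        contours = [
            None if kk == 0.0 else _bottom_anchored_ellipse(a * kk, b * kk, n_vertices)
            for kk in k
        ]
        for j in range(m):
            front = contours[j] if contours[j] is not None else POINT
            back = contours[j + 1] if contours[j + 1] is not None else POINT
            slabs.append(
                Slab(front, back, float(z[j + 1] - z[j]), n_subslabs=8,
                     name=f"spheroid_{j}")
            )
        return (BodyModel(axial_slabs=tuple(slabs)),
                4.0 / 3.0 * math.pi * a * b * c)
    if family == "lofted_ellipse":
        a, b = float(shape["a"]), float(shape["b"])
        s2, L = float(shape["scale2"]), float(shape["length"])
        front = _bottom_anchored_ellipse(a, b, n_vertices)
        back = _bottom_anchored_ellipse(a * s2, b * s2, n_vertices)
        model = BodyModel(axial_slabs=(Slab(front, back, L, name="frustum"),))
        return model, math.pi * a * b * L * (1.0 + s2 + s2 * s2) / 3.0
    raise ValueError(f"unknown parametric body family {family!r}")
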