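# Methods

This note documents the models behind `plesiomass`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices a user extending the package should know about.

## Rib-orientation model

Plesiosaur dorsal ribs are single-headed and articulate only with the
transverse processes, so rib orientation — and with it ribcage width and
depth — can be inferred from vertebral morphology. Each rib is simplified
to a planar structure; the minimum bounding rectangle of the rib in its
plane defines the rib plane height (RPH, dorsoventral) and width (RPW,
mediolateral). Three angles move it out of the vertical transverse plane:
pump-handle rotation θ₁ ∈ [−90°, 90°] about the mediolateral edge through
the articulation, bucket-handle rotation θ₂ ∈ [0°, 90°] about the
(already tilted) medial edge, and the centrum tilt θ₃ ∈ [−90°, 90°] applied
to the whole costovertebral system. The projected height used for section
construction is the vertical separation between the articulation corner and
the diagonally opposite distal corner (the rib spans those corners); this
is what yields the subtractive `RPW·sin θ₂·sin θ₁` term, and it is verified
in the tests against an independent rotation-matrix oracle to 1e−9 over a
dense angle grid. The rotation order is fixed θ₁ → θ₂ → θ₃; 3-D rotations
do not commute, but the alternative order changes height and width in
compensating directions and the difference is not modelled. Caliper
rotation (about the anteroposterior axis) is not modelled — it is rarely
determinable from fossils, and the coracoid width bounds body width at the
glenoid in any case.

## Cross-section construction

Only the *area* of each transverse section enters the volume integral, so
sections are parameterised by a two-exponent family rather than free-form
digitised outlines: a dorsal half-superellipse (full section width ×
dorsal height, default exponent **2.2**, giving a rounded outline with room
for the epaxial and limb-elevator musculature) above a ventral
half-superellipse (default exponent **2.5**, a flattened gastralia-
supported belly), joined at the maximal-width waterline with the
ventral-most point at y = 0 so the glenoid and acetabulum sections share a
ventral horizontal line. Both exponents are configuration values. The
superellipse area converges to the bounding rectangle from below as the
exponent grows (97.85% at exponent 8, 99.0% at 12).

Section dimensions come from the skeleton: the glenoid section takes the
most anterior dorsal rib (only θ₃ applies there), with ventral height
`sqrt(coracoid_width² − (width/2)²)` — the girdle element is read as the
hypotenuse spanning ventral midline to the limb articulation, which keeps
the ventral height below the girdle width; the acetabulum section shares
the glenoid width, uses the last dorsal rib for its dorsal height and the
pubis for its ventral triangle; the middle section takes its width from the
transected ribs (standardised to the largest rib plane, fractions 1.0, θ₃
≈ 0 under the gentle dorsal arch) and its ventral height from the
rib-coefficient relation. The rib coefficient (glenoid rib arc / maximum
rib arc) defaults to **0.78** when neither arcs nor an explicit value are
given.

## Body axis

Intervertebral cartilage scales with centrum size; each vertebra
contributes `centrum length × (1 + fraction)` with a global default
fraction of **0.10** and per-region overrides (short-necked clades tend to
have proportionally thicker intercervical cartilage; the default is a
deliberate middle value, exposed in configuration). The trunk chord
(anterior scapula margin → acetabulum) is laid out horizontally and the
vertebral polyline arches over it as a circular arc: with curvature k each
segment of length L subtends `2·asin(Lk/2)`, and the root of
`(2/k)·sin(Σ asin(Lᵢk/2)) = chord` is bracketed and solved to an endpoint
miss below 1e−8. A circular arc is the minimal-assumption smooth curve
satisfying the endpoint and length constraints; the solve requires
`chord ≤ Σ segments < (π/2)·chord` (gentle arch). Cervical and caudal
curvature affect figures, not volumes, and are kept as segment-length
bookkeeping only. The skull section is an ellipse with axes equal to skull
width and height at the quadrates.

## Volume integration and soft tissue

The cross-sectional method partitions the main body into five slabs at the
four sections. Each slab is sliced into **100** subslabs (configurable; far
more than needed for stability — the trapezoidal error on the analytic
battery decays as n⁻²). Interior stations are pointwise linear blends of
the bounding contours; contours sharing a vertex count are blended
index-by-index (which makes blending associative and slab subdivision
exactly volume-preserving), otherwise they are resampled to a common count
by perimeter arc length from the ventral midline point, iterated to a fixed
point so resampling is idempotent. End slabs keep their bounding section's
shape while size tapers linearly to a point (a generalised cone): a
constant-*size* end prism would leave the body unclosed, so "constant
shape" is read as shape-preserving taper.

Each flipper is one slab over a planform: section area = 0.685 × chord ×
(thickness fraction × chord), the **0.685** area coefficient being typical
of streamlined hydrofoil sections, with default thickness fractions
(0.22 … 0.07) over six stations, root to tip, following penguin flipper
proportions. Chords default to multiples of the propodial distal width.

Soft tissue: the three ribcage sections are enlarged **25%** linearly
(areas ×1.5625), after the soft-tissue halo preserved around the ribcage of
the polycotylid *Mauriciosaurus fernandezi*; the tail gains **5%** length,
after the tail traces of *Seeleyosaurus*; the skull section is never scaled
(minimal craniofacial soft tissue, as in extant marine reptiles). Density
is **1027 kg/m³** (surface seawater; neutral buoyancy). No tail fluke is
modelled — the pygostyle-like terminal structure is small and its
orientation unknown.

## Regression suite

All linear fits operate on log10-transformed data. OLS uses the
least-squares normal equations; PGLS whitens by the Cholesky factor of the
Brownian covariance `C[i,j] = shared root-to-MRCA path length (Myr)`.
Both ML and REML log-likelihoods are computed for PGLS; **ML is used for
AICc** so OLS/PGLS/LL4 values are comparable (tooling conventions differ
between REML-default GLS and ML OLS; one flavour must be chosen for
cross-model comparison). AICc counts the residual variance as a parameter
(k = 3 for lines, k = 5 for the four-parameter log-logistic). The LL4 model
`y = c + (d−c)/(1+(x/e)^b)` is fitted by bounded nonlinear least squares
from a fixed, documented multi-start grid (7 exponent starts × 3 scale
quantiles × both asymptote orderings), making fits reproducible
bit-for-bit on one platform.

Leave-one-out percent prediction error refits on every n−1 subset,
back-transforms predictions to the antilog scale (plain antilog — no
lognormal smearing correction, matching how the published intervals are
defined) and reports the mean and the (N−1)-denominator standard deviation
of `|obs − pred|/pred × 100`. The symmetric interval
`point × (1 ± mean|%PE|/100)` follows.

Time calibration: cladogram polytomies are resolved randomly under the
given seed, node ages start at the oldest descendant tip's first appearance
and parents are pushed older until every branch is at least the minimum
branch length (default **1 Myr**).

## Packaged equations

The published predictor set ships as versioned JSON: 13 missing-element
equations and 14 OLS + 14 PGLS body-mass equations, with per-record fit
statistics and units. The missing-element equations are encoded in
**millimeters**: their source does not state units, but with a 1 m trunk a
meter reading of the trunk-to-tail equation returns a tail ≈ 3× the trunk
(anatomically impossible), whereas millimeters return ≈ 1.0× trunk,
consistent with plesiosaur proportions. The body-mass tables are explicitly
in meters → kg. The OLS table is the recommended default (its trunk and
dorsal-centrum-volume rows substantially outperform their PGLS
counterparts); the PGLS table is retained for comparison and carries no
published prediction errors, so its intervals collapse to the point. The
external propodial-width → flipper-length equation is represented as a
coefficient slot only; its coefficients are not packaged and must be
supplied by the user.

## Synthetic data

The generators emulate the *statistical structure* of the real datasets,
not their taphonomy: noise is normal on the log10 scale (multiplicative
lognormal, the space the models are fitted in), predictors are log-uniform,
skull/neck totals lognormal, trees pure-birth with all tips extant (every
pendant edge is extended by one extra waiting time so the Brownian
covariance is full-rank). Skeleton templates for three clade archetypes
(elasmosaurid-, cryptoclidid-, pliosaurid-like) encode cervical counts
(62 / 30 / 20), maximum slant angles bracketing the documented range
(θ₂ up to 9° in cryptoclidids, ~30° in elasmosaurids), rib-length profiles
that rise then fall along the dorsal series, and girdle widths that keep
the Pythagorean construction feasible. Generating coefficients default to
the packaged equations, so noiseless recovery tests double as
equation-encoding checks. Passing tests therefore demonstrate internal
consistency and correct implementation of the published constants — not
that any particular fossil's mass is right; real specimens bring
measurement error, taphonomic distortion and missing data that the
generators deliberately do not imitate (only simple field dropout is
supported).

Oracle bodies (cylinder, cone-capped cylinder, spheroid, proportional
elliptical frustum) have closed-form volumes. The spheroid is built from
200 proportional elliptical sections: with five slabs a piecewise-conical
spheroid is ~9% off the analytic volume, so a fine axial grid is the only
honest way to exercise the integrator at the 0.05% level; plesiosaur
reconstructions themselves always use the five-slab layout (enforced by a
dedicated validator).

## Numerical choices and edge cases

Polygonal sections carry a relative area deficit ≈ 2π²/(3m²) for m
vertices (1e−4 at m = 256; oracle tests use 1024). Contours are built by
mirroring a generated right half, so bilateral symmetry is exact. Degenerate
cases: a trunk polyline summing exactly to the chord is returned as a
straight column (infinite radius); a flat-y LL4 fit is flagged degenerate
rather than rejected; AICc is NaN on fits too small to define it (n ≤ k+1)
but the standalone `aicc` function raises. Fits are deterministic; the
CLI's `--seed` feeds polytomy resolution and the generators only.

Problem sizes used by the test suite and acceptance script — 100-tip trees
with 500 Brownian replicates for the PGLS calibration, 24–65-point
noiseless recovery datasets, 200-slab spheroids — were chosen so the full
battery runs in well under a minute each while leaving the statistical
assertions comfortably powered.

## Known limitations

* The rib model assumes planar ribs; taxa with strongly 3-D curved ribs
  (e.g. sauropod posterior dorsals) need full 3-D treatment.
* Section shape is a two-exponent family; the "extra space for
  musculature" of manual reconstructions is absorbed into the dorsal
  exponent default rather than modelled.
* The hydrofoil section coefficient and thickness profile are documented
  defaults, not a digitised foil.
* The PGLS machinery supports only Brownian correlation (no OU or Pagel's
  λ) and no parsimony tree inference; trees must be supplied.
* Packaged equations are authoritative constants — the package never
  refits them, and extrapolation beyond the ~79–12,800 kg calibration
  range of the underlying models deserves caution.
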