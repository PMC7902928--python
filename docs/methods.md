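# Methods

## Surface model

A surface is a triangulated irregular network (TIN): the Delaunay
triangulation of the points' planimetric positions, each vertex keeping
its observed elevation. Elevation inside the convex hull is the
barycentric-linear interpolant of the containing triangle; outside the
hull it is undefined (NaN), never extrapolated. Linear fields are
reproduced exactly (the suite asserts 1e-9 m), and triangulation is
invariant to point order. Duplicate planimetric locations are collapsed
before triangulation — keeping the maximum elevation for canopy clouds
(an SfM cloud represents the visible top surface) and the mean for soil.

The soil **reference** surface stands in for the unobservable ground under
the canopy of a ridged crop: the bare-soil (furrow) TIN raised uniformly
by the block's average ridge height, so that plant height is measured
from the ridge top. The ridge height is primarily a user-supplied scalar;
`estimate_ridge_height` is an optional helper that samples user-digitized
crest polylines every 5 cm, takes the nearest cloud point within a 5 cm
radius as the crest elevation, subtracts the furrow-TIN elevation, and
averages (at least 10 valid samples required). Crest lines must be
digitized on *bare* ridge segments; under canopy the crest is invisible
to SfM and the estimate would absorb plant height. A pre-emergence
bare-field flight can serve as the reference directly by passing
ridge height 0.

## Difference models and exact integrals

A difference model carries Δ = canopy − reference at its vertices,
clipped to a plot polygon. Two construction methods:

- **do not track breaklines** — keeps the canopy vertices strictly inside
  the polygon, interpolates the reference at those locations, and
  re-triangulates. Mesh density equals the canopy cloud's. Canopy
  vertices were chosen as the carrier (rather than soil or merged
  vertices) because canopy density dominates; this choice is documented,
  not asserted as faithful to any external toolchain.
- **trace all triangles** — a full planar overlay: each canopy triangle is
  intersected with the plot polygon (the breakline) and with every
  overlapping soil triangle (bounding-box prefilter + STRtree); each
  resulting piece is ear-clipped into triangles, and triangles whose
  vertex Δ straddle zero are split along the interpolated zero contour.
  Every output face then lies in exactly one canopy and one soil
  triangle, so Δ is exactly linear per face; total face area equals
  area(plot ∩ canopy hull ∩ soil hull) to 1e-9 relative. Numerically
  coincident vertices are snapped at 1e-9 m; faces under 1e-10 m² are
  dropped.

Canopy volume and ground cover are closed-form per-face integrals of the
positive part of the linear field: with sorted vertex values
d₁ ≤ d₂ ≤ d₃ and face area A, the sub- or super-level corner regions are
similar triangles, giving e.g. V = A·d₃³ / (3(d₃−d₁)(d₃−d₂)) when only
d₃ > 0. This is quadrature, not meshing — it applies identically to both
construction methods and matches independent 5-mm midpoint quadrature to
well under 0.5%. Only Δ > 0 contributes ("above the reference"); the area
below the reference is reported separately (`below_reference_area`) as a
senescence/lodging diagnostic. Plots partially outside a surface hull are
clipped, with an error if less than 50% (configurable) remains.

## Height fields and cleanup

Δ is sampled at the centers of a 1-cm grid (configurable within
(0.001, 0.1] m) anchored at the lower-left of the plot bounding box;
cells outside the polygon or the mesh are missing. Cleanup is two
single-pass filters, in order:

1. **hard cap 1.2 m** — potato plants do not reach this height, so
   anything strictly above it is a weed or reconstruction artifact;
2. **SD cutoff** — heights above mean + k·SD (sample SD, ddof = 1) of the
   plot's height distribution are removed; k = 3 by default, with 2 and
   2.5 available. The statistics are computed once on the incoming field
   (no iteration), so removal at k = 2 is a superset of k = 3 by
   construction. The filter operates on grid cells, not raw 3D points,
   because the distribution of interest is area coverage per height.

Metrics: maximum = max of valid cells; average = mean of cells with
value > 0 (the plants' average height, not the plot's); removed
percentage relative to the pre-cleanup cell count; area-per-height
histogram (default 0.02 m bins, cells with value ≤ 0 excluded). Whether
the 1.2-m cap applies to height-above-reference or absolute elevation is
a genuine ambiguity; height-above-reference is used because absolute
elevation is site-dependent. Volume and cover are computed from the
difference model, not the cleaned grid, so a surviving outlier inflates
them slightly — at the default 0.2% outlier rate the effect is ~1–2%.

## Growth patterns

For two flights of one plot, relative deltas (v₂−v₁)/max(v₁, 1e-6) of
volume, cover, mean and max height are combined with the shifts of the
area-weighted height deciles q10…q90 (linear interpolation within
histogram bins). Rules are applied in a fixed priority order —
senescence (volume, cover and mean all down), lodging (mean down, cover
maintained or up), sideways (cover up, max stable), vertical pyramid
(max up, upper-decile shifts ≥ ρ× lower), vertical even with raised base,
vertical even, no change, else mixed — with thresholds τ = 0.10,
τ_small = 0.03, τ_h = 0.05, ρ = 2.0 exposed in `PatternThresholds`.
The pattern taxonomy is qualitative by nature; the defaults were chosen
so that canonical noise-free transitions classify unambiguously.
Senescence outranks lodging precisely when cover also falls — that is
what distinguishes end-of-season decline from a collapsed but living
canopy. The raised-base test is **scale-invariant**: q10-shift is
compared against τ_base × (date-1 median height) with τ_base = 0.5,
rather than an absolute length, so that multiplying all heights, areas
and volumes by a common factor never changes a label (an absolute
threshold in meters would break that invariance). A season profile
labels consecutive intervals and infers maturity: *early* if senescence
appears before 80% of the season span, *late* if the final interval is
still a growth pattern, *intermediate* otherwise, *undetermined* with
fewer than three flights; lodging anywhere is flagged separately.

## Synthetic fields and what they do (not) show

The generator emulates the trial geometry: rows 0.90 m apart, plots of
3 plants at 0.35 m spacing with 0.90 m between plots, a tilted planar
soil base, ridges as raised-cosine (or trapezoid) bumps of height 0.20 m
whose furrow floor is exactly the base plane, and plant canopies as
spherical-cap domes (a dome taller than its radius becomes a hemisphere
on a cylinder so the envelope stays single-valued), boxes, or square
pyramids sitting on the ridge top. The default canopy is a full-grown
dome, height 0.35 m and radius 0.40 m. The canopy cloud samples the
**upper envelope** of soil and plants — SfM sees only the visible
surface — with Gaussian vertical noise (default sd 0.01 m) and sparse
uniform outliers (default 0.2% of points, 0.8–1.5 m above the reference,
exercising both the hard cap and the SD cutoff). The bare-soil cloud
samples only furrow strips outside plant footprints. Point density
defaults to 10,000 pts/m², one point per cm², consistent with ~1 cm
ground-sample-distance imagery; scenarios that need many plots (e.g. the
50-plot method comparison, run at 600 pts/m²) state their reduced density
explicitly as a problem-size choice.

Per-plot truth (volume, cover, max and mean height above the reference)
is computed analytically for disjoint in-plot footprints and otherwise by
midpoint quadrature of the *generating* surface at ≤ 5 mm (refined for
small plants), never through the pipeline under test; closed forms are
cross-checked against the quadrature at generation time. Pattern
transitions for classifier testing are generated at the metrics level:
date-1 cell heights uniform on [0.05, 0.45] m, a per-pattern transform of
the distribution and covered-cell count, and multiplicative Gaussian
noise per cell and per summary metric (default 1.5%, consistent with
centimeter-level height accuracy on ~0.4 m canopies and chosen so that
two-sided conditions such as |Δmax| < τ_h remain decidable).

What passing tests show: the geometry engine is exact (area conservation,
linear reproduction, integral/quadrature agreement), the pipeline
recovers known truth at realistic sampling density, and the cleanup and
classification behave as designed. What they do not show: performance on
real SfM clouds, whose noise is spatially correlated, whose canopies
self-occlude, and whose georeferencing errors have no counterpart here;
no claim about field R² values is made or reproducible without field
data — only the regression/correlation machinery is provided.

## Numerical choices and limitations

- Cover at threshold 0 is ill-conditioned wherever the terrain itself
  touches the reference (ridge crests are *at* the reference by
  construction). The zero contour can then only be localized to about
  one point spacing; with 1-cm spacing this bounds cover accuracy at
  roughly 1–3% for smooth-edged canopies and makes cover of cliff-edged
  shapes (boxes; capsule domes) systematically generous by up to one
  GSD ring. Volume is far less sensitive because the integrand vanishes
  at the contour.
- Polygon containment is strict-interior (`shapely.contains_xy`);
  boundary incidence has measure zero for continuous coordinates and
  half-cell-offset grid centers, so adjacent plots cannot double-count.
- The overlay assumes simple (non-self-intersecting) plot polygons
  without holes; ear clipping falls back to fan triangulation on
  numerically degenerate pieces.
- `compare_methods` reports Spearman correlation with average-rank ties
  (scipy); a zero-variance volume vector yields NaN with a warning.
- LAS reading covers uncompressed 1.x, point formats 0–3, x/y/z only;
  PLY is ASCII. These are deliberate minimal surfaces for an analysis
  package, not general-purpose readers.
- Manual point-cloud editing (the usual first step on real data) is
  replaced by the deterministic hard cap; a reproducible pipeline cannot
  depend on hand edits.
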