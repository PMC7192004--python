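# Methods

This note records the models behind `canopyflux`, their assumptions, the
numerical choices made where the published descriptions leave room, and
what the synthetic-scene tests do and do not establish.

## Per-cell canopy extraction

The extraction treats each grid cell independently. All structural
metrics derive from a 2-D Delaunay triangulation of the class's points
with relative height as elevation ("TIN"). Integration rules:

* **Volume** — per-triangle prism: planimetric area × mean of the three
  vertex heights. This is the exact integral of the piecewise-linear
  surface, so no quadrature tolerance is involved.
* **Surface area** — the sum of 3-D triangle areas. Note this quantity
  is quadratically sensitive to small-scale height noise: white noise of
  standard deviation σ on points spaced *h* apart inflates it by roughly
  (σ/h)². It is therefore the least robust of the four metrics, and the
  recovery tests hold it to looser standards than volume and projected
  area.
* **Projected area** — the sum of planimetric triangle areas. Because a
  Delaunay triangulation covers the convex hull of its points, a class
  whose points form disjoint clusters (two vine rows crossing one cell;
  a row interrupted by gaps) is *bridged*: the projected area includes
  the space between clusters and the volume is integrated under the
  bridge. This is a real property of the algorithm, not an
  implementation bug — it is what makes vine metrics exceed vegetation
  metrics on gapped canopies (below). The optional `max_tin_edge` filter
  (drop triangles with any horizontal edge longer than the threshold;
  default off) suppresses bridging when per-row recovery is wanted; the
  truth-recovery tests set it to 0.5 m, roughly five point spacings.

Boundary conventions, chosen once and documented because the thresholds
are published without inclusivity: NDVI strictly greater than the
threshold (default 0.6) is vegetation; relative height ≥ 0.5 m is vine
(inclusive on the vine side). Duplicate (x, y) positions collapse to the
highest return before triangulation, because photogrammetric clouds
stack returns vertically. Relative heights below −1 cm set a flag; all
negatives are floored at zero. Classes smaller than `min_points`
(default 10) yield zero metrics plus a flag rather than unstable
triangulations — on real acquisitions this is what turns thin data
stripes into flagged cells instead of noise.

### Ground references

Mode I estimates the ground per cell as the minimum elevation of the
spectrally classified ground points and assumes the cell is internally
level. With noisy soil elevations this minimum is biased low by
extreme-value statistics (≈ −3σ for a few hundred points), which biases
all relative heights high by the same amount; the effect is visible in
low-canopy metrics (a 0.15 m cover crop gains ~10 % volume at σ = 5 mm)
and negligible for 2.2 m vines. The mode-equivalence test therefore
isolates the *geometric* claim — both references coincide on level
ground — on a scene with noise-free ground returns; with realistic noise
the two modes still agree to ~1 % on vine metrics.

Mode II attributes a ground elevation to every point from the LiDAR-like
ground cloud. Two attributions are provided: `nearest` (default; the
elevation of the horizontally nearest ground point) and `tin` (linear
interpolation over the ground triangulation, nearest-neighbour outside
its hull). On sloped terrain the nearest rule imprints a sawtooth of
amplitude ≈ slope × mean ground-point spacing on the relative heights;
volume and projected area are insensitive to it, but the 3-D surface
area inflates by a few percent (the σ/h effect above). The slope
invariance of the extraction is therefore demonstrated with the `tin`
attribution, which is exact on planar terrain; `nearest` remains the
default because it is the simplest defensible rule and matches the
documented per-point contract.

## Synthetic scenes

The generator emulates a trellised vineyard acquisition: box-section
canopy strips (top at `vine_height` = 2.2 m above local ground, width
1 m) along rows 3.35 m apart, a grass band (`cover_height` = 0.15 m)
centred in each inter-row covering `cover_fraction` (default 0.4,
mowed-stubble conditions) of it, optional missing vine units
(`gap_fraction`, 1.5 m plant spacing) floored with grass, and a planar
terrain slope. Only the upper canopy envelope is sampled — cameras do
not see beneath the canopy — at `point_density` = 100 points/m²
(10 cm-imagery conditions). Ground returns at 6 points/m² emulate an
airborne LiDAR DTM source. Optical bands are generated at 10 cm and the
thermal band at 60 cm, with the thermal pixel a linear soil/canopy
temperature mixture of the sub-pixel cover fraction evaluated at the
optical pixel centres, so the NDVI–Tr relationship is linear by
construction up to the configured noise (reflectance σ = 0.01,
temperature σ = 0.3 °C, canopy elevation σ = 2 cm, soil σ = 5 mm).
Soil is hot (45 °C) and canopy cool (30 °C), a midday contrast.

Two deliberate departures from naive sampling:

* **Break-line sampling.** Canopy points combine a jittered global grid
  with points along strip edges and along both sides of every
  analysis-grid line crossing a strip. A purely random sample's convex
  hull under-covers its footprint by about the mean point spacing per
  edge (~10 % of a 1 m strip at 100 points/m²), a tessellation artifact
  that would swamp the recovery comparison; sampling the visible canopy
  break lines removes it while remaining physically defensible.
* **Half-pixel canopy bleed in the rasters.** Optical pixels whose
  centres lie within half a pixel of a strip read as vegetation: a mixed
  edge pixel is dominated by the bright canopy signal in the NIR. Without
  this, points on the canopy edge read the soil pixel just outside and
  are misclassified, again clipping the strip by up to half a pixel per
  edge.

The analytic truth is exact for vine metrics on box canopies (footprint
from rectangle intersections; flat top ⇒ surface area = projected area;
volume = area × height; truth is slope-invariant because heights are
relative to local ground). Vegetation-class truth is first-order (flat
tops summed per class), ignoring the transition wedges a TIN builds
between classes, and is used only loosely. What passing these tests
shows: the extraction geometry, classification and integration are
correct under known geometry, realistic densities and modest noise. What
they do not show: robustness to photogrammetric dropouts, registration
error between bands and cloud, non-box crown shapes, or reflectance
regimes where the NDVI threshold fails — real acquisitions add all of
these.

## Component temperatures

Per cell, an ordinary least-squares line through the (NDVI, Tr) pairs at
thermal resolution is evaluated at scene-wide pure-soil and pure-canopy
NDVI endpoints; the cooler value is Tc, the warmer Ts. NDVI is
aggregated (mean) onto the thermal grid since Tr is the coarsest band.
Endpoints come from the scene NDVI histogram (5th/95th percentiles by
default) or fixed user values; an inverted pair is rejected. Cells with
fewer than 3 pixels or zero NDVI variance degenerate to Ts = Tc = mean
Tr with a flag; positive slopes (physically unexpected) are flagged,
not rejected. With 36 pixels per 3.6 m cell and 0.3 °C pixel noise the
endpoint evaluation carries a standard error near 0.15 °C, hence the
0.5 °C recovery demonstrated in the tests.

## LAI models

Three published regression forms map cell metrics to LAI after
normalizing structural metrics by the cell area (volumes → m³/m² = m,
areas → dimensionless). The spectral-only model has an unambiguous
printed form and is checked against an independent symbolic evaluation
to 10⁻¹². The structural and combined models are typographically
ambiguous in their source (fraction and exponent placement), so they are
implemented as *configurable expressions* with one documented default
reading each; no numeric claim from the source is attached to them. The
default combined-model reading contains a 1.54^Tr factor that explodes
for Tr in °C at field magnitudes, making its predictions unusable in
practice — the pipeline therefore defaults to the structural model
(scenario S2), and users who prefer another reading can substitute the
expression via configuration. Negative predictions are reported raw by
default with an opt-in clamp at zero. The OLS refit utility
(statsmodels under the hood) exists for recovery testing of linear
models, not as a replacement for the published search procedure.

## TSEB-2T

Radiation: longwave emissions are grey-body (ε_c = 0.98, ε_s = 0.95)
with Brutsaert clear-sky emissivity for the sky term; partitioning uses
exponential extinction with k_L = 0.95 and clumping Ω (default 1.0,
per-cell values accepted). Shortwave canopy transmittance is
τ_s = exp(−K_be Ω LAI) with the spherical leaf-angle beam extinction
coefficient (K_be ≈ 0.5 at nadir sun; default solar zenith 30°); the
full direct/diffuse split is out of scope. G = c_G Rn_s with c_G = 0.3.

Turbulence: series resistance network. R_x = (C/LAI)√(l_w/U) with
C = 90 s^½ m⁻¹ and leaf width 0.1 m, taking U at height d₀ + z₀M
(d₀ = 0.65 h_c, z₀M = 0.125 h_c) from a log profile with Businger–Dyer
stability corrections above the canopy and Goudriaan exponential
attenuation within it; R_s = 1/(0.004 + 0.012 u_s) with u_s the wind
just above the soil. Air density and specific heat come from (p, Ta,
ea). The in-canopy air temperature is the conductance-weighted mean of
(Ta, Tc, Ts), giving H_c and H_s; the Monin–Obukhov length is updated
from total H and the loop repeats until successive lengths differ by
less than 10⁻⁵ m (cap 100 iterations, flagged if hit). Numerical
safeguards: the stability parameter is clamped to [−5, 0.45], u* floored
at 0.01 m s⁻¹, and |L| ≥ 10⁶ m is treated as exactly neutral so the
near-neutral fixed point exists; none of these bind in ordinary daytime
conditions. Latent heats are residuals, so component closure is exact by
construction — the conservation tests verify the implementation keeps
it. Negative LE_s (condensation-like residuals) passes through by
default; an opt-in clamp zeroes it and rebalances H_s, flagged.

LAI = 0 decouples the canopy (infinite R_x): the model degenerates to a
one-source soil balance with zero canopy net radiation.

## Closure and statistics

Bowen-ratio closure multiplies the residual Rn − G − H − LE into H and
LE proportionally to H/(H+LE) and LE/(H+LE), which preserves H/LE
exactly and closes the balance identically; records with H + LE = 0 are
flagged and skipped. R² may be negative and is not clipped; RRMSE
boundary values (10/20/30 %) fall into the better rating category.

## Problem sizes

Default test scenes are 36 × 36 m (100 cells, ~1.4 × 10⁵ points), which
exercises every code path — multiple rows per cell, partial strips at
cell borders, grass-only cells — while a full extraction runs in about a
second. Monte-Carlo checks use 10³ forcing draws and 10⁵ integration
samples. These sizes are the package's verification conditions, chosen
to make the suite convenient to run anywhere; nothing in the
implementation depends on them.

## Known limitations

* Vegetation-class (not vine-class) truth is first-order; transition
  wedges between canopy and cover crop are untested analytically.
* The NDVI-threshold classifier inherits all mixed-pixel failure modes;
  only the half-pixel bleed regime is modelled.
* The clumping factor is a pass-through parameter; no clumping model is
  fitted from canopy geometry.
* Tower-footprint weighting of fluxes is not implemented; comparisons
  with tower records use plain means over cells.
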