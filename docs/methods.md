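# Methods

This note records the models implemented by `porebiofilm`, the conventions
and defaults that required a decision, and what the synthetic-data tests do
and do not demonstrate about real data.

## Imaging model and segmentation

Frames are transmitted-light rasters of a planar porous device; biofilm
appears as darkening against a bright background. Frame 0 (biofilm-free) is
the reference: correction is the per-pixel absolute difference to it, which
removes fixed illumination structure and the grain pattern.

Binarisation is Otsu on the corrected frame by default, with a `fixed`
override for exact reproducibility. Two guards make Otsu safe on
time-lapse data: a constant frame yields an empty mask with a warning, and
a frame whose Otsu split separates the two intensity classes by fewer than
`min_contrast` counts (default 8 on an 8-bit scale) is also treated as
background-only — without this, a frame containing only shot noise is split
*inside* the noise band and the resulting mask is percolating speckle.
Grain interiors, dilated by 1 px, are always excluded; 8-connected
components under 16 px are removed as noise (at ~5 µm/px this removes shot
noise without erasing early microcolonies). The threshold rule and
despeckle size are stand-ins: the upstream experimental work states that
binarisation was performed but not how.

Coordinates: pixel centres, origin top-left, flow along +x. Angles are
measured from the downstream pole (+x), counterclockwise in the physical
(y-up) frame. All lengths are reported in physical units via the pixel
size.

## Base-biofilm classification and morphometrics

**Ring rule.** BB around a grain is the biomass inside the largest radius
reached by the consecutive run of concentric annuli (width `ring_step`,
default 10 µm), starting at the grain surface, in which biomass covers at
least 35% of the annulus; the comparison is inclusive. The annulus width
and consecutive-run reading are this package's choices: they are local,
monotone, and robust to resolution. A consequence worth knowing: finger
tips protruding beyond the 35% radius are clipped from the BB mask. For
area accounting (coverage series) these clipped fragments are reassigned to
BB, so total biomass = BB + streamer is an exact partition of the
segmented mask; for the per-grain thickness profile they are simply absent
(sub-pixel-scale error at the defaults).

**Thickness profile.** 3600 rays at 0.1° steps from the grain centre;
thickness is the outermost radius of the run of BB samples contiguous with
the grain surface (sampled every 0.5 px; single-sample gaps are bridged to
absorb pixelation, and the run may start up to 2.5 px off the surface
because the pixel ring hugging the grain edge is excluded at segmentation).

**Perimeter and tortuosity.** The external BB boundary is traced as a
marching-squares contour and smoothed with a circular 5-point moving
average before summing segment lengths — the raw staircase polygon of a
digitised circle is ~6% too long, the smoothed one is within ~0.3%.
Tortuosity is normalised by the *expected smooth* outer perimeter:

* closed film (all 3600 bins colonised): `P_BB / 2π(r + h̄)` with `h̄` the
  mean thickness, so a smooth closed annulus scores exactly 1 and fingering
  scores above 1;
* open film: the external boundaries of the BB arcs, excluding
  grain-contact segments, over the grain perimeter `2πr` — below 1 until
  the surface is fully colonised.

This thin-film convention reconciles "ratio of BB perimeter to grain
perimeter" with a value of exactly 1 at closure; the raw ratio of a closed
annulus would be `R/r > 1`. Note that tortuosity measured on a mask is
sensitive to the ring-rule truncation: when fingers are near the pixel
scale, the clipped boundary weaves radially and the measured value exceeds
the analytic tortuosity of the underlying thickness profile. The measure
remains monotone in fingering amplitude, which is what the
architecture-growth analysis uses.

**Streamers.** After BB removal, remaining components are merged by single
linkage whenever their boundary-to-boundary distance is below 45 µm
(transitively); the gap between two components is measured as the minimum
pixel-centre distance minus one pixel, so touching pixels have zero gap.
Components below 16 px are discarded first (the same noise rule as
segmentation; it also sheds ring-rule finger fragments, which would
otherwise attach to streamers and bias their width). Each streamer is
anchored to the nearest grain whose downstream half-plane contains the
streamer's most upstream pixel.

* **Length** is the geodesic diameter of the 8-connected skeleton graph
  (edge weights 1/√2 px) of the morphologically closed streamer, found by
  iterated double-sweep Dijkstra, plus the boundary EDT at the two path
  ends — thinning erodes about half a width from each end, and the end
  correction recovers it (measured on a 100 px bar: 96.4 px uncorrected,
  101.4 px corrected).
* **Width** is twice the mean Euclidean distance transform over skeleton
  pixels of the closed mask.
* **Porosity**: the streamer boundary is the morphological closing with a
  disk of radius 22.5 µm (half the linkage distance) with interior voids
  filled; both the biomass fraction and the void fraction of that region
  are reported, because "porosity" is used in both senses in the
  literature. The oxygen module consumes the cell volume fraction
  explicitly.

## Growth models

Coverage and per-grain BB area follow `y(t) = K/(1 + exp(−r(t − t0)))`,
fitted by nonlinear least squares with multi-start initialisation
(K₀ = 1.05·max y, t0₀ at half-max, r₀ from the early log-linear slope,
8 jittered restarts). `RSE = √(SSR/(n−3))` in response units. Detachment is
deliberately not modelled: the flow regime is steady and laminar. The fit
is scale-equivariant in the response; fits on short or one-sided series are
flagged low-confidence rather than refused.

The normalized carrying capacity is `nK = K / A_ref` with `A_ref` the area
of the annulus from the grain surface to radius r + 200 µm. The reference
width is held fixed across grains so that nK compares how fully each grain
exploits the same near-surface shell; smaller grains with equal K score
higher. This definition is this package's own (the original normalisation
is not available in the main text it derives from) and is flagged as such:
it reproduces the qualitative size dependence and the positive
nK–tortuosity relationship, which the test suite verifies on a synthetic
grain population.

Doubling time is `ln 2 / slope` of the log-linear fit over the first 50 h
(configurable); a flat series reports +∞. Plateau onset is the earliest
time from which the 5-point-smoothed slope stays within a tolerance of zero
for the rest of the series; the series argmax is reported alongside for
overshoot detection.

## Streamer filtration model

`W(t) = 2βvCVt/π`: a streamer intercepting a fraction β of the cells
advected through its cross-section at velocity v grows linearly in width.
Defaults: v = 0.35 mm/s, C = 10⁷ cells/ml, V = 1 µm³ (the cell volume is
not stated in the source experiments; 1 µm³ is a typical aquatic
bacterium). β estimation divides the through-origin slope of W vs t by
`2vCV/π`, restricted to the pre-plateau window (default t ≤ 70 h); beyond
the plateau the model is reported alongside observations without fitting,
since densification reduces permeability and the linear model no longer
applies. Times are accepted in hours and converted internally (the unit
algebra (mm/s)·(cells/mm³)·(mm³)·s → mm is validated at construction).

## Oxygen time scales

With respiration R = 1 fmol O₂ cell⁻¹ h⁻¹ and bulk density
C = 10⁷ cells/ml, the bulk uptake time is `T_u = [O₂]/(R·C)`. The dissolved
oxygen concentration is not printed in the source analysis; 280 µmol/L
(air-saturated water near 20 °C) is the unique value making T_u = 28 h
exact, and is documented as an inferred constant. A streamer at 10% cell
volume fraction and V = 1 µm³ holds 10¹¹ cells/ml, shortening uptake to
`T_us ≈ 10 s`. Transport: `T_d = L²/2D` with D = 2.1×10⁻⁹ m²/s (O₂ in
water, 20 °C, back-calculated the same way) and `T_a = L/v` with
v = 0.01 mm/s in the gap; L defaults to half the mean pore-throat width
(0.305 mm). The space is *limited* iff both T_d and T_a strictly exceed
T_us (ties, to a 10⁻⁹ relative tolerance, count as replenished); the
defaults give ratios ≈ 2.2 and ≈ 3.0.

## Gap and net gain

A gap is the maximal contiguous angular run of bins with thickness below
`depth_fraction` (default 0.25) of the reference level — the median
thickness outside the ±60° downstream search window — centred within the
window and at least 5° wide. These three parameters are this package's
stand-ins; they are configurable and sweep-tested for stability. Missing
biomass is the annular integral of (reference − actual) thickness over the
run, i.e. the gap filled to the surrounding BB level. The net gain of
differentiation is exactly `(S − G)/(B + G) × 100`. The paired comparison
of streamer gain vs gap-filling gain uses the Wilcoxon signed-rank test:
exact p by full sign-flip enumeration for up to 15 non-zero pairs (valid
under tied magnitudes, which the constant-difference case produces), normal
approximation beyond.

## Community statistics

Singletons (global count 1) are removed before rarefaction; each sample is
subsampled to 5000 reads without replacement via the multivariate
hypergeometric distribution, so depths are exact and runs are reproducible
per seed. Jaccard similarity is computed on presence/absence, Bray–Curtis
on relative abundances; both are similarities in [0, 1].

Bootstrap CIs redraw each sample's reads with replacement (a multinomial at
the observed depth) and recompute the metric, 1000 randomisations by
default; an OTU-row resampling variant is available for sensitivity. The
reported interval is the *basic* (reverse-percentile) CI — the empirical
2.5/97.5 percentiles reflected around the point estimate. This choice is
deliberate: plug-in similarities are biased downward by sampling zeros, the
bootstrap distribution doubles that bias, and the raw percentile interval
therefore sits below the truth (measured coverage 40–78% across community
shapes, vs 89–95% for the basic CI). Coverage is nominal only when the
sequencing depth well exceeds community richness; for communities dominated
by rare taxa, any simple bootstrap under-covers, and the rarefaction depth
should be chosen accordingly.

## Synthetic data generator

The generator is the package's test bed and defines the study conditions.
Geometry: truncated-Gaussian grain diameters (0.4–1.4 mm, matching the
device the pipeline targets) placed by dart-throwing with 0.1 mm clearance
so pore throats exist. The desk-scale default used throughout the tests is
a 2 × 2 mm sub-domain at 5 µm/px with four 0.15 mm grains in an upstream
column (so every streamer has free downstream pore space); the full
20 mm/1.01 µm-per-px device is a configuration option, not a default.

Growth defaults: BB thickness logistic with K = 50 µm, r = ln 2/6.5 h⁻¹
(doubling time 6.5 h) and t0 = 66 h. The thickness t0 is back-computed so
that the film closes near 50 h — an inflection as late as the *coverage*
inflection (~110 h) combined with a 6.5 h doubling time would put the film
at sub-nanometre thickness at 50 h, contradicting closure. Before closure
(mean thickness below 5 µm) colonisation is rendered as evenly spaced arcs
(random per-grain rotation) whose union fraction tracks the logistic, so
the film closes continuously; the pre-closure law is not described for the
real system and this is an explicit stand-in. After closure the boundary is
modulated by `1 + 0.12 sin(8θ)` fingers; from 70 h, thickness in the ±20°
downstream sector is suppressed to 15% (the gap). Streamers: two per grain
at ±25°, flow-aligned lobes with constant width and an elliptical tip,
width growing at the filtration rate for β = 0.026 until the 0.04 mm
plateau, length rising to 1.2 mm at 70 h and relaxing to 0.59 mm by 120 h.
Speckle holes (frozen per streamer) are punched only in the lobe interior —
the envelope keeps an intact rim, which is what makes EDT-based width
meaningful. Biomass darkens the bright background in proportion to local
thickness (attenuation 60–180 counts on an 8-bit scale), with Gaussian
noise (sd 2) and a fixed illumination gradient removed by background
subtraction. The 1 px ring hugging each grain edge is treated as occluded
by the pillar wall and not rendered, mirroring the 1 px grain dilation at
segmentation.

Ground truth (analytic thickness profiles, tortuosity, areas, per-streamer
L/W/porosity, per-grain gap deficit) is recorded from the same quantities
used to render, so rendered rasters and truth agree by construction.

OTU tables: a lognormal core community (206 OTUs, σ = 2) shared by
inoculum, BB and streamer samples; 85/136 architecture-specific OTUs appear
only in their sample at ~3 expected reads each; multinomial draws at
50 000 reads per sample.

**What passing tests show — and don't.** The generator produces ideal
circular grains, noise that is Gaussian and stationary, biomass that never
detaches, and streamers that are straight, isolated lobes. Recovery of
ground truth under these conditions validates the measurement chain
(segmentation → partition → morphometrics → models), not its robustness to
drift, uneven illumination, overlapping or meandering streamers, or
out-of-plane structure — none of which the desk-scale model emulates.

## Numerical choices and degenerate inputs

* Perimeter smoothing window: 5 boundary points (good circle/finger
  compromise; larger windows shave genuine fingers).
* Skeleton diameter: iterated double-sweep Dijkstra (exact on trees;
  skeletons of closed lobes are near-trees), three sweeps.
* Streamer-length fallback for masks whose closing skeletonises to nothing:
  √area, flagged by construction (single compact blobs).
* Empty profile → no gap (an uncolonised grain is not a gapped grain);
  all-low profiles are likewise not gaps (no reference level exists).
* Logistic fit on a strictly decreasing series converges to r ≤ 0 or fails;
  both surface as low-confidence/error, never as a silent "fit".
* Rarefaction drops under-depth samples with a warning rather than erroring
  the whole table.
* Geometry rendering guard: rasters above 3×10⁷ pixels are refused with a
  pointer to sub-domain rendering.

## Known limitations

* The ring rule clips finger tips beyond the 35% radius; per-grain BB area
  therefore underestimates the rendered BB layer by up to ~2–3% at strong
  fingering (the clipped pixels are reassigned to BB only in the coverage
  accounting).
* Measured tortuosity exaggerates analytic boundary tortuosity when finger
  amplitude is near the pixel scale (truncation-induced excursions); it is
  a rank-preserving proxy, not an unbiased estimate.
* The nK normalisation and the gap-criterion parameters are this package's
  documented stand-ins for under-specified steps of the original analysis.
* Bootstrap CIs are first-order bias-corrected only; communities dominated
  by unsampled rare taxa still under-cover.
* The filtration model is strictly linear pre-plateau; no clogging feedback
  or mechanistic interception calculation is attempted.
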