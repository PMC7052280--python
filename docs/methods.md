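# Methods

`thermofield` implements, end to end, the analysis chain used for
UAV-based high-throughput phenotyping of crop canopy temperature (CT):
orthomosaicking of overlapping thermal frames under two blending modes,
plot-level CT extraction with air-temperature normalization, a P-spline
spatial mixed model with effective-dimension heritability, and agreement
statistics between processing modes.  Because campaigns of this kind rarely
come with deposited raw data, the package ships a fully specified synthetic
scene generator that emulates a wheat field trial; every quantitative claim
in the test suite is made against that generator's known ground truth.

## Trial design and virtual grid

The emulated experiment is a 2-replicate augmented design: 354 winter-wheat
genotypes of which 3 are checks, each replicate a 21-row x 18-range grid of
378 plots.  Checks are placed once per complete 7 x 6 block (nine blocks per
replicate, 27 check plots), re-randomized until every row and every range of
the replicate contains at least one check; the 351 test genotypes are then
augmented onto the remaining cells in random order.  Rejection sampling is
applied per block band: the row-coverage constraint couples only the three
blocks sharing a band of rows and the range constraint only the three blocks
sharing a band of ranges, so band-wise rejection draws from exactly the same
uniform distribution over valid placements as global rejection, at a
vanishing fraction of the cost (global rejection has acceptance probability
of order 1e-5 here).  The retry budget is 10,000 draws per band.

Both replicates live on a single *virtual grid* of 74 rows x 18 ranges:
replicate 1 on rows 1-21, replicate 2 on rows 54-74, with 32 empty rows
between them representing the intervening parcel.  The spatial model
operates on this grid so one smooth surface spans both replicates.

Plot geometry: the sown plot is 1.7 m x 1.0 m, but plot cells are laid out
on a 2.7 m x 1.5 m pitch so that the standard 50 cm inward extraction
buffer leaves a usable 1.7 m x 0.5 m interior.  (A 50 cm buffer on the bare
1.0 m-wide sown polygon would be empty; the pitch represents sown plot plus
inter-plot paths.)  Coordinates are planar metric, x along ranges, y along
rows; polygons are closed counter-clockwise rings.

## Synthetic scene

True plot canopy temperature is

    T_i = baseline + g(genotype_i) + s(r_i, c_i) + row(r_i) + eps_i

with genotype, row and plot effects iid normal (defaults sigma_g^2 = 0.6,
sigma_r^2 = 0.1, sigma_p^2 = 0.8 degC^2) and `s` a smooth low-frequency
surface (amplitude 1 degC) over the virtual grid.  The implied
variance-ratio heritability of a 2-replicate mean is sigma_g^2 / (sigma_g^2
+ sigma_p^2 / 2) = 0.6, a realistic midday value for wheat CT.  Baselines:
air 25 degC, canopy 8 degC above air, soil 14 degC above mean canopy -
midday grain-filling conditions with strongly sunlit soil.

### Directional apparent temperature

What a thermal pixel sees is a mixture of canopy and the warmer soil
between the crop rows.  The visible-soil fraction is modelled as

    f_soil(theta_v, dphi) = (1 - cover) * exp(-k tan theta_v)
                            * (1 + a cos(dphi) sin(theta_v)),

apparent T = f_soil T_soil + (1 - f_soil) T_canopy, with view zenith
theta_v and view-minus-sun azimuth difference dphi.  The exponential term is
a gap-fraction model through a row canopy: soil visibility is maximal at
nadir and decays with zenith, producing the *nadir hotspot*.  The cosine
term raises soil visibility (hence apparent temperature) for sun-side
(acute) viewing, producing the gradient along the solar principal plane;
`a <= k` guarantees the hotspot stays at nadir.  Defaults k = a = 3 with
cover 0.70 and soil contrast 14 degC give an apparent-temperature span of
about 3.5 degC across a 25-degree field of view of view angles under the
reference sun position (azimuth 199 deg, zenith 25 deg) - the magnitude
reported for midday wheat flights.  The sign convention (warmer on the
sun side) follows back-scatter hotspot physics.  No functional form for
thermal canopy anisotropy is standard; this is the minimal smooth model
reproducing both phenomena, and the anisotropy diagnostics in
`plot_extraction` recover its parameters from rendered imagery, which is
the closed loop the tests exercise.

Per-plot canopy cover is drawn N(0.70, 0.05^2) clipped to [0, 1], so plots
differ in how strongly viewing geometry moves their apparent temperature -
the mechanism by which blending modes end up with different residual
variances.

### Camera, flight, rendering

The camera is a nadir-gimballed 640 x 512 px microbolometer with a
25 x 20 degree FOV and NETD 0.05 degC, flown at 80 m (GSD 5.5 cm) at 2.2 Hz
and 3 m/s in a lawnmower pattern with >= 70% across-track and >= 90%
(realized ~96%) along-track overlap; the long image axis points along
track.  Default simulations downsample the sensor 4x to 160 x 128 px (GSD
~22 cm) to keep a full campaign (700-800 frames, two mosaics, four model
fits) around ten seconds on one CPU; the full resolution is a flag away and
is used in the GCP-detection tests where target size matters.

Rendering intersects each pixel ray with a flat ground plane at known exact
poses - photogrammetry (SfM, bundle adjustment, DSM) is out of scope, and
georeferencing error is represented separately through GCP detection noise.
Sown-plot interiors receive the directional apparent temperature for that
pixel's individual view geometry; paths, the replicate gap and margins
receive the soil temperature; 16 thermal ground-control targets (warm
aluminium cross on a cool 0.5 m styrofoam plate, rendered as two opposing
triangles) ring the field.  Ambient drift is linear at 0.5 degC per 8-min
flight and is added scene-wide; optional cloud events subtract a step from
the canopy-air contrast.  Gaussian NETD noise is added per pixel.  Frames
are kept in degC (float32); the DN codec (DN = round((T + 273.15) * 25),
16 bit) is exercised separately because no public DN-to-degC mapping exists
for this camera class - any linear radiometric encoding is an assumption.

What the generator does *not* emulate: radiative transfer within the
canopy, emissivity and atmospheric effects, lens distortion, vignetting,
rolling shutter, and camera temperature drift/non-uniformity. Passing tests
therefore demonstrate correctness of the processing chain under a known
forward model, not robustness to all real-sensor artifacts.

## Orthomosaics

Frames are orthoprojected to a regular grid (half-open cells, values at
centers, nearest-neighbor sampling).  Mode `average` takes the unweighted
mean of all covering frame pixels (a wide, conical composite viewing
geometry); mode `disabled` takes the single frame whose view of that ground
point is closest to nadir (narrow, near-directional geometry), with ties
broken toward the lower frame id.  Per-pixel provenance (count, or winning
frame id) supports seamline maps.  The mosaic GSD defaults to the camera
GSD at flight altitude.

GCPs are located by normalized cross-correlation against a template built
from the same cross pattern at mosaic resolution, with quadratic subpixel
refinement of the correlation peak, and the detections are registered to
the surveyed coordinates by a least-squares similarity transform whose
residual RMSE is reported in cm.

## Plot extraction and normalization

Plot CT is the median of mosaic pixels whose *centers* fall inside the plot
polygon after a 50 cm inward buffer (pixel-center zonal statistics keep
counts reproducible; even-count medians average the two central values).
NaN pixels are excluded; zero usable pixels flag the plot as missing rather
than zero.  CT is normalized as delta_t = t_c - t_a with the 2 m air
temperature interpolated linearly to the acquisition time, or the
flight-mean air temperature when per-plot timestamps are unavailable (the
default in mosaics, where pixels mix acquisition times).

For anisotropy diagnostics every (plot, frame) pair with the buffered plot
fully inside the footprint yields the plot median from that single frame
plus the view geometry of the plot center (median/mean is a flag).  Records
are binned 2 deg in zenith x 30 deg in azimuth; the azimuthal first
harmonic of the bin means (weighted least squares, bins above 2 deg zenith)
estimates the principal-plane gradient direction, and a nadir-vs-
perpendicular bin contrast quantifies the hotspot.

## Spatial model

The plot response is modelled as Y = f(r, c) + Z_g c_g + Z_r c_r + eps on
the virtual grid, with random row effects (working-direction pattern plus
within-flight drift) and genotypes either random (heritability) or fixed
(BLUEs).  `f` is a PS-ANOVA tensor-product P-spline: cubic B-splines per
axis with second-order difference penalties, the number of spline segments
set to 2/3 of the axis length (half-up rounding: 49 for 74 rows, 12 for 18
ranges).  Spectral reparameterization moves the penalty null space
(intercept, linear trends, their product) into the fixed part and leaves
five iid smooth random components - f(r), f(c), f(r):c, r:f(c) and
f(r):f(c) - each with its own variance; the smooth-by-smooth interaction is
rescaled by its Kronecker-sum penalty eigenvalues and carries a single
variance (the anisotropic two-parameter variant was judged not worth the
extra REML dimension at these grid sizes).

Two identifiability choices matter in practice:

* **Smooth-term centering.** Each smooth component's columns are centered
  over the observed cells (a sum-to-zero constraint, as is standard in
  penalized-regression software).  Without it, a constant can migrate
  between the intercept and the surface - harmless for fitted values but it
  contaminates "corrected values", which keep the intercept and drop the
  surface.
* **Genotype coding (fixed mode).** Treatment coding with the first level
  as reference; BLUE-plus-intercept sums, corrected values and BLUE/BLUP
  correlations are invariant to this choice.

REML uses the effective-dimension fixed point: solve the Henderson
equations at current variances, compute each term's effective dimension
ED_k = q_k - (sigma^2 / sigma_k^2) tr(C^-1_kk) from the Cholesky factor of
the coefficient matrix, update sigma_k^2 = u_k'u_k / ED_k and sigma^2 =
RSS / (n - rank X - sum ED_k), and stop when the relative REML deviance
change drops below 1e-6 (max 200 iterations; non-convergence is flagged
with the deviance trace, never silently accepted).  All variances start at
var(y)/10 to avoid the zero fixed point.  A zero-variance response returns
the degenerate all-zero fit directly.  Gap rows carry no observations and
no pseudo-observations; the bases span the full 74-row domain so the
surface bridges the gap smoothly.  The row factor has levels only for rows
present in the data (42).  Missing plots are dropped (complete-case) with
counts preserved in the tables.

Generalized heritability is H^2 = ED_g / (n_g - 1): the effective dimension
absorbed by the genotype term relative to its upper bound (one dimension is
lost to the intercept).  Spatially corrected plot values are intercept +
genotypic BLUE + plot residual, i.e. the observation with the fitted
surface and row effects removed.  By construction the surface is
identifiable only up to its component in the unpenalized trend space, so
the invariance test injects a surface orthogonal to that space.

Numerical notes: the coefficient system is dense (~1,000-1,300 unknowns at
full design size) and solved by Cholesky; block traces of the inverse come
from squared column norms of the inverse Cholesky factor, which is the
per-iteration cost driver.  A full-size fit converges in 25-50 iterations,
a few seconds on one CPU.

## Agreement statistics

Bland-Altman analysis uses the difference "average minus disabled" against
the pair mean, with bias, normal-theory 1.96-sd limits of agreement and the
OLS slope of difference on mean; mode regression reports OLS of one mode on
the other with R^2.  Cross-flight repeatability uses pairwise Pearson
correlations of spatially corrected genotype values (BLUEs) over shared
genotypes, cells with fewer than 3 shared genotypes left missing.  The
stay-green subset keeps genotypes scored 0 on every senescence date up to a
cutoff; the senescence generator draws a uniform onset date per genotype
with a linear 12-day ramp to full senescence, which is sufficient structure
for subsetting logic and nothing more.

## Problem sizes used in the shipped checks

The acceptance script and heavy tests run the full 354-genotype,
756-plot design with the 4x-downsampled camera (~750 frames per flight).
Heritability-recovery summaries average 5 (script) or 20 (tests) seeded
replicates; the blending-mode comparison runs 10 seeded campaigns.  Oracle
equivalence checks (mixed-model solve vs dense GLS, mosaic modes vs
exhaustive per-pixel loops) run on grids of at most 48 cells and stacks of
at most 10 frames, where the dense oracles are exact.

## Known limitations

* Flat terrain and exact poses: no SfM/DSM errors; georeferencing quality
  enters only through GCP detection.
* The anisotropy model is phenomenological; real canopies show
  head/leaf-angle effects the generator does not represent.
* The ED-based H^2 is downward-biased by a few percent relative to the
  variance-ratio truth at 2 replicates (intercept absorption); recovery
  tests budget for this.
* Blending mode `average` is an unweighted mean; commercial mosaicking
  software may weight by distance, which is not emulated.
* Because the generator's within-plot field is smooth, overall within-plot
  pixel spread is actually larger in `average` mosaics (systematic
  view-mixture gradients) than in `disabled` ones; what carries over from
  real imagery is the *discontinuity* at seamlines, which is larger in
  `disabled` and is what the tests assert.
* Heritabilities from a single simulated flight inherit the generator's
  idealizations and should not be read as predictions for any particular
  real campaign.
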