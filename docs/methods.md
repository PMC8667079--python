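# Methods

`sliscat` analyses *SLI scatterometry* measurements: a thin, unstained
tissue section is illuminated from below by a square kernel of `n × n` LEDs
that is scanned across an LED display (`m × m` kernel positions), and a
camera above the sample records the transmitted light at normal incidence —
one `H × W` image per kernel position.  Because every image pixel sees every
illumination direction exactly once, transposing the series gives an
`m × m` *scattering pattern* per image pixel: the angular distribution of
light scattered by that sample location, projected gnomonically onto the
display plane.  Myelinated nerve fibers lying in the section plane scatter
light predominantly perpendicular to their axis, so each in-plane fiber
bundle leaves an elongated reflex band through the pattern centre; crossing
bundles leave several bands, and fibers inclined out of the plane displace
and bend their reflex along the fiber direction.

## Geometry

The display has `leds_per_side = 256` LEDs at `pixel_pitch_mm = 1.8`,
`source_sample_distance_mm = 130` below the sample and
`sample_camera_distance_mm = 400` to the camera; the object-space pixel size
is 3 µm.  A kernel at in-plane distance `d` from the point beneath a sample
location illuminates it at polar angle `θ = arctan(d / H)`; the display edge
therefore reaches `θ ≈ 60.6°`.  The azimuth convention is global: `φ = 0`
points to the top of the display/pattern/image and increases clockwise as
displayed, so the unit step in `(row, col)` image coordinates is
`(−cos φ, +sin φ)`.  Kernel centres sit at half-integer offsets when `n` is
even (a square of `n × n` LEDs is centred between LEDs), which reproduces
the 32-position centre-line calibration scan at offsets −15.5 … 15.5 kernel
widths (`θ` up to ±59.8°).  Equal-`θ` rings on pattern figures sit at
`scale · tan θ` — a gnomonic projection, so ring spacing grows with `θ`.
Per-pixel illumination angles are computed exactly from the 3-D geometry of
the pixel's position; across one field of view the difference from the
display-centre approximation is below the LED-pitch scale.

## Forward phantom model (`synthetic`)

The renderer is deliberately phenomenological: it produces patterns with
the features the analysis chain must cope with, under full ground-truth
control, and makes no electromagnetic claims.

* **Reflex band.**  Each fiber bundle contributes an anisotropic Gaussian
  band through the pattern centre, oriented at `direction + 90°`, with
  Gaussian cross-section `reflex_width` (pattern px) and a smooth
  super-Gaussian truncation `exp(−½ (along / halflength)⁶)` at
  `reflex_halflength`.  Width and half-length have no published tissue
  values; fixture defaults (width ≈ 0.10–0.16 of the pattern radius,
  half-length ≈ 0.75–0.95 of it) are chosen so that peaks are resolvable at
  Δφ = 1° and are explicitly arbitrary.
* **Inclination.**  An out-of-plane fiber shifts its band centroid by
  `s = 6 · tan(inclination)` px along the fiber direction and bends it
  parabolically (`curvature 0.02 · tan(inclination)` per px²).  Only the
  qualitative behaviour — displacement and bending grow with inclination —
  is modelled; the coefficients are configurable module constants.
* **Unscattered centre.**  A Gaussian blob (amplitude 2.0, σ 1.5 px)
  marks where unscattered light falls straight into the camera.  Its
  position drifts linearly across the field of view: each image pixel sits
  above a slightly different display position (one kernel per `n · pitch`
  of object distance).
* **Vignetting.**  All intensities are multiplied by `cos^q θ` (default
  `q = 4`), emulating the measured falloff of transmitted intensity with
  illumination angle (1/r² loss plus the limited LED view angle).  The
  calibration-curve computation recovers this generating falloff from a
  rendered diffusor scan to well under 2% RMS.
* **Noise.**  Intensities are scaled to photon counts by
  `shot_scale · illumination_time`, Poisson-sampled per shot, Gaussian read
  noise added, shots averaged, camera gain applied.  Two regimes are used
  throughout, fixed once: single-shot acquisition with
  `shot_scale = 50` photons per intensity unit and read σ 0.05 — a
  high-gain, short-exposure regime in which raw 1° profiles show the
  high-frequency structure that motivates smoothing — and the instrument's
  four-shot averaging (`n_shots = 4`, same camera constants) for
  direction-recovery studies.

What the phantom does **not** emulate: real myelin microstructure,
polarisation, wavelength dependence, lens blur, or inter-pixel intensity
correlations of real tissue.  Passing synthetic suites therefore shows that
the analysis chain is correct and robust under the modelled effects, not
that a given detection rate will be attained on any particular tissue
sample.

## Pattern assembly and profiles

`assemble` pivots the series: `cube[p][i, j] = image_(i,j)[p]`, the first
recorded image (upper-left kernel) filling the upper-left pattern entry.
The pivot is an exact involution (re-serialising the cube reproduces the
input bit for bit) and runs over row chunks with a configurable memory
budget, since a full-frame cube does not fit in memory.  Intensities are
stored as 32-bit floats after shot averaging.

Each pattern is centred on the *centroid of its maximum-intensity pixels*
(patterns are not radially symmetric, so the plain intensity centroid would
be biased by the reflexes), cropped to the largest circle around that
centre, and integrated radially: `I(φ) = Σ_{r=1..⌊R⌋}` of bilinearly
interpolated samples at one-pixel radial steps.  Numerical choices:

* the centre sample `r = 0` is excluded by default so the constant blob
  value does not offset every bin (configurable, `include_center`);
* the fractional final step is dropped rather than weighted ("one pixel
  steps");
* bins sit at bin starts `φ = k·Δφ`, not centres;
* border pixels keep their integration radius in `radius_px` so maps can
  exclude small-radius (border-artefact) profiles;
* an all-equal pattern centres on the geometric middle and is flagged
  degenerate.

Bilinear sampling of a Gaussian ridge systematically underestimates the
crest by ~1% for a 3 px ridge (second-order interpolation bias); the
integration is therefore validated two ways: against a ten-times-denser
azimuthal sampling of the same integrator (agreement ≤ 0.5%, showing 1°
bins lose nothing), and against a continuous evaluation of the analytic
band model along the same rays (agreement ≤ 1.5%, bounding the
interpolation bias itself).

## Smoothing and filter selection

Profiles are smoothed with a soft Fourier low-pass: coefficient at
normalised frequency `g = |f| / f_max` (with `f_max` the Nyquist frequency,
`length/2` cycles per turn) is multiplied by

    M(g) = 1 − [0.5 + 0.5 · tanh((g − cutoff) / width)].

The multiplier is real and even (zero-phase), applied literally to every
coefficient including `f = 0`; the resulting mild DC attenuation is
harmless because all peak logic runs on min–max-normalised profiles.  Two
named presets ship: `sli-1deg` (cutoff 0.04, width 0.125) and `sli-5deg`
(cutoff 0.40, width 0.225).  A width of exactly 0 is rejected — the
expression is undefined there; a step filter must be requested via a tiny
width — which is also why the default search grid starts at width 0.025.

Peak significance uses circular prominence ≥ 0.08 of the normalised
amplitude (configurable; the value is a conventional default for this kind
of profile analysis, not a published constant).  Detection of a known fiber
constellation requires the significant-peak count to match (2 for parallel
in-plane, {1, 2} for strongly inclined, 4 and 6 for two and three
crossings) and, for even counts, all peaks to pair at 180 ± 35° — the
peak-distance check against false positives.  The exact "peak shape"
criterion used in the original pipeline is unspecified; only prominence and
pairability are enforced here, and the hook for further shape checks is
left open.

`optimize_filter` evaluates the detection rate over a cutoff × width grid
per region, divides each region's matrix by its maximum (so every
constellation weighs equally; regions with all-zero matrices are excluded
with a warning), sums, and returns the argmax, ties broken to the lowest
cutoff then the lowest width.  Whether "normalised" means max- or
sum-normalisation was an open choice; divide-by-maximum keeps each region's
best cell at exactly 1.

## Orientation extraction

Peak positions are refined below the sampling step by the centroid of the
peak tip: the contiguous samples within `tip_fraction · prominence`
(default 0.06) of the peak height, weighted by their height *above* that
cut line so edge samples enter smoothly — this attains sub-0.1° agreement
with a 0.01°-resampled oracle, comfortably below the ±1.5° equivariance
budget.  Peaks are matched into pairs with circular separation in
[145°, 215°] by a maximum-cardinality, maximum-weight matching (weight
`C − |separation − 180°|`), which provably maximises the number of pairs
and, among maximal matchings, minimises the total deviation from
opposition.  Each pair's axis (circular mean modulo 180°) rotated by +90°
gives one fiber direction; the rotation is a config switch
(`reflex_rotation: 90|0`) for compatibility with tooling that applies the
perpendicularity convention upstream.  Unpaired peaks contribute no
direction (a lone reflex without its mirror is inconclusive); more than
four distinct directions invalidate the pixel (the 2 × 2-subpixel display
limit).  Profiles whose total azimuthal modulation `(max − min)/max` is
below 5% are classified isotropic before normalisation: min–max scaling
would otherwise amplify sub-percent interpolation ripple into spurious
full-prominence peaks.

## Visualization

Directions map to the HSV hue wheel with `hue = 2 · angle` — the only
injective periodic choice on [0°, 180°) — at full saturation and value.
The orientation map stores up to four directions per pixel in 2 × 2
subpixels: one direction fills all four; two split main/anti-diagonal;
three duplicate the first (lowest) direction in the fourth subpixel; four
get one each, row-major ascending.  Undefined pixels are black.  The
distribution map overlays, per `B × B` block (default 40) whose defined
fraction reaches 8% (inclusive), one low-alpha unit segment per direction
per pixel, centred on the block centre with length `0.9 · B` so neighbour
blocks do not overlap.

## Problem sizes and determinism

The shipped suites use pattern grids of 49 × 49 kernels (odd, so noiseless
axis-aligned fixtures have an integer centre; an even grid puts the centre
exactly between pixel rows, where the symmetric ±0.5 px interpolation dip
splits an axis-aligned crest into twin equal maxima — an artefact of
perfect symmetry, not of the method), 1,600 profiles per region for the
detection-rate suites, 500 fixtures for direction recovery, and a 64 × 64
phantom at 16 × 16 kernels for the exact assembly round trip.  All
randomness flows from explicit seeds; the CLI fans a single global seed out
to per-stage seeds by stable hashing of stage names, so any stage re-run in
isolation reproduces its in-pipeline draw.

## Known limitations

* Out-of-plane inclination is rendered only qualitatively and never
  estimated; strongly inclined bundles whose two profile peaks sit between
  ~90° and 145° apart are counted but fail the 180 ± 35° pairing, which
  caps the out-of-plane detection rate by design.
* The reflex model is additive; physical occlusion, multiple scattering
  and interference between crossing bundles are absent.
* Detection rates measured on the synthetic suites characterise the
  pipeline under the modelled noise, not any particular tissue type.
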