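# Methods

`eggshade` quantifies how the coloration and camouflage of ground-nest eggs
change under solar exposure.  It packages four pieces: a synthetic
nest-scene generator with a dose-driven fading model, a grey-standard
reflectance calibration, a predator cone-catch mapping, and a filter-bank
texture comparison that scores camouflage as a chi-square distance between
egg and microhabitat texture signatures.

## Scene generation and the fading model

A scene is an `(H, W, 4)` reflectance image over the camera bands
(VIS-R, VIS-G, VIS-B, UV).  The background is band-correlated Gaussian
clutter: a shared smooth random field (grain size in cm, default 2 cm;
contrast 0.25) modulates each band's base reflectance, with a configurable
per-band decorrelation component.  Eggs are ellipses (default 3.3 x 2.5 cm)
laid in clutch-like rows of at most four — ten eggs give the 3/4/3
arrangement used for the radiation experiment — carrying random maculation
disks that cover `spot_fraction` (default 0.2) of the egg area.  A square
grey standard of exactly 0.25 reflectance in all four bands sits in the
frame corner.  All geometry is emitted as polygon annotations, and painting
uses the same rasterization as analysis, so the annotations delimit the
painted pixels exactly.  Rendering is a pure function of the scene seed.

Fading is **linear with a cap in cumulative normalized dose**:

    R_b(dose) = min(R_b(0) + s_b * dose_b, cap)

with one dose unit defined as seven days under direct-sun irradiance.  The
linear form follows from the near-perfect linear correlation between
measured reflectance change and received radiation across shading
treatments; the cap (default 0.95) keeps faded shells physical.  VIS and UV
doses are tracked separately — VIS dose scales with illuminance
transmittance, UV dose with UV-index transmittance — because the field
dose-response shows UV fading proportional to UV dose with a different
constant than the visible bands.  Default slopes (0.186 per VIS band, 0.089
in UV per unit dose) are calibrated so that a direct-sun week takes a 0.175
VIS reflectance to 0.361 (+106%) and a 0.124 UV reflectance to 0.213
(+71%), the field averages for exposed eggs.  Values already above the cap
are never pulled down, preserving identity at dose zero.

The five shading treatments (direct sun; one, two and four white cloth
layers; one black layer) are encoded as transmittances anchored to the
measured per-treatment radiation maxima (730 down to 7 W/m²; UV index 7.5
down to 0.1).  Radiation logs are sampled every 5 min over a 12-h window
(145 points/day) as a half-cosine diurnal bell scaled by the transmittance,
with ~2% day-to-day amplitude jitter; only the daily maxima matter
downstream (they are averaged over the recording days, which is how the
field summaries were formed).

The generator emulates geometry, reflectance statistics and dose-response,
not field optics: there is no shadowing, no specularity, no pigment
photochemistry (bands fade independently), and clutter is a stationary
Gaussian field rather than real saltpan substrate.  Tests passing on these
scenes therefore validate the measurement chain and the relative behaviour
of the camouflage metric, not absolute field values.

## Camera model and calibration

The camera is an idealized per-channel power law: `DN = clip(black +
gain * R^(1/gamma) + noise)` at a configurable bit depth (default 16).  Its
only contract is that `linearize` inverts it: subtract the black level,
divide by gain, raise to gamma, clip negatives.  Pixels at full scale are
flagged saturated and excluded from all means, since reflectance is
undefined there.  Calibration divides each channel by the mean linearized
value over the grey-standard polygon and multiplies by the standard's known
0.25 reflectance; this makes reflectance exactly invariant to global
exposure and idempotent, and values above 1 (specular highlights) are
retained rather than clipped.  Region means use the pixel-centre-inside
rasterization rule; the VIS reading of a region is the mean over pixels of
the mean of R, G and B, the UV reading the mean of the UV channel.

## Visual models

Observers are defined by receptor peak wavelengths only: ferret (430,
538 nm), human (420, 533, 562 nm), peafowl (421, 457, 505, 566 nm) and blue
tit (371, 448, 503, 563 nm).  Sensitivities follow the Govardovskii A1
alpha-band template on a fixed 350-700 nm, 1-nm grid, peak-normalized.  The
beta band is omitted: with all peaks at or above 371 nm and the grid
starting at 350 nm its contribution is secondary, and only peaks are
specified for these observers.  The human observer runs through the same
nomogram machinery rather than CIE observer functions, for uniformity
across models.

Camera bands are bridged to spectra by a piecewise-constant reconstruction
over the bands' nominal supports (UV 350-400, blue 400-500, green 500-600,
red 600-700 nm).  This is deliberately the simplest documented bridge; it
makes each cone catch exactly linear in the four band reflectances, so the
mapping is a per-pixel 4 x chromacy matrix product.  Catches are von-Kries
normalized by the catch of the flat 0.25 grey standard under the same
illuminant, so a spectrally flat stimulus maps to 1.0 in every channel of
every observer under any illuminant.  The default illuminant is equal
energy; a Planckian 6500 K radiator is available as a documented daylight
approximation.  Ocular-media transmission is not modelled.

## Texture signatures and the camouflage score

The filter bank holds 14 kernels at each of 4 scales (sigma = 16, 32, 64,
128 px by default; 56 kernels total): odd- and even-symmetric Gaussian
derivative kernels at five orientations evenly spaced over [0, 180)
degrees (0, 36, 72, 108, 144), two Gaussians and two Laplacians of
Gaussian at sigma and sqrt(2) sigma — the sqrt(2) ladder mirroring
standard texton banks.  Oriented envelopes use a 3:1 aspect ratio with the
*long* axis equal to sigma, so supports truncate at +/-3 sigma of the
largest constituent width.  Derivative and LoG kernels are made exactly
zero-sum and L1-normalized; Gaussians sum to one.  Convolution uses reflect
padding (avoiding dark-border artifacts near the frame edge) and is
implemented as true convolution via a shared FFT per channel with kernel
FFTs cached on the bank.  A 3-channel image yields 168 = 3 x 56 response
images.

Per image, the response vectors of the analysis region (egg union plus
microhabitat) are standardized per feature — responses at sigma 128 are
orders of magnitude larger than at sigma 16 — and clustered with K-means
(k = 20, k-means++ with 10 restarts, tolerance 1e-6, fixed seed).  The
vocabulary is fitted per image: the comparison is always between two
regions of the same photograph, so a per-image vocabulary is consistent and
avoids cross-scene nuisance variation.  For regions larger than
`max_fit_pixels` a seeded random subsample is clustered (labels are still
assigned to every pixel); the experiment-2 profile uses 8000.  Every pixel
is labelled with its nearest centre (ties to the lowest index), and a
region's signature is its normalized 20-bin label histogram.

Camouflage is the half-normalized chi-square distance

    D = 1/2 * sum_t (h1_t - h2_t)^2 / (h1_t + h2_t)   in [0, 1]

between the egg-region signature and that of the 45-cm-diameter
microhabitat disk centred on the nest, with egg pixels excluded from the
microhabitat so the regions never self-compare.  Zero-total bins are
skipped.  The bounded definition is used throughout; unnormalized or
aggregated variants can report arbitrarily large values but are not
comparable across regions of different size.

## Desk-scale experiment profiles

Experiment 1 (fading vs radiation): 5 treatments x 10 eggs x days 0/3/7 on
288² scenes at 10 px/cm, full imaging chain, radiation simulated on the
three recording days.  The summary reports day-0/final means, percent
change from unrounded means (rounding the means first changes the percent
in the second decimal — the reports keep full precision), and Pearson
correlations of the VIS change against irradiance and the UV change
against UV index.

Experiment 2 (camouflage degradation): 7 nests x 3 eggs on 416² scenes at
6 px/cm — the pixel scale chosen so the 45-cm microhabitat circle fits the
frame — with the filter bank at `scale_factor = 0.25` (sigma = 4, 8, 16,
32), a geometrically similar bank for the reduced scene scale.  Each
nest/day image is calibrated, mapped to all four visual models and scored.
The day-wise report gives mean +/- SE across nests (the nest is the
experimental unit) and a per-model degradation flag (final-day mean above
day-0 mean).  Formal random-intercept models (score ~ day, nest as group)
are delegated to statsmodels MixedLM on request and recorded verbatim.

## Numerical choices and edge cases

- Polygon rasterization: pixel-centre-inside via `matplotlib.path`,
  oracle-checked against brute-force point-in-polygon; scene polygons are
  placed off the half-integer grid so no pixel centre lies on an edge.
- Camera round trips are exact up to DN quantization (~1.5e-5 relative at
  16 bit); the calibration contract is stated at 1% to cover gamma
  encoding and interpolation of real chains.
- K-means determinism: seeds are fixed and all derived seeds stay below
  2^31; varying only the K-means seed moves the suite-mean camouflage
  score by ~1%, though individual scenes can move more (small egg regions
  sample only a few hundred response vectors).
- Degenerate inputs raise typed errors (geometry, calibration, data,
  shape, domain, config) rather than propagating NaNs: empty masks, too
  few standard pixels (< 100), non-positive standard means, doses < 0,
  reflectance baselines <= 0, histograms that are not normalized.
- Reflectances above 1 are kept in images, but are clipped (with a
  warning) before the arcsine-square-root transform used for normality.

## Known limitations

- The piecewise-constant spectral bridge ignores within-band spectral
  shape; absolute cone catches are therefore nominal, and only contrasts
  within an image are meaningful.
- The bounded chi-square score cannot be compared numerically with
  unnormalized texture-difference scales; only orderings and differences
  across days/models are interpretable.
- The fading model is phenomenological (linear-with-cap per band); it does
  not model pigment photobleaching chemistry or band interactions.
- Egg regions in the desk-scale profile contain a few hundred pixels with
  spatially correlated filter responses, so per-scene signatures carry
  sampling noise; conclusions are drawn on means across nests.
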