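# Methods

## Spectral phasor transform

A pixel spectrum sampled on N contiguous channels (default 32, first bin
starting at 410.5 nm, 8.9 nm bandwidth; `centers[i] = 410.5 + i·8.9` nm
labels each channel) is mapped to

    g = Σ_c I_c cos(2πkc/N) Δλ / Σ_c I_c Δλ,
    s = Σ_c I_c sin(2πkc/N) Δλ / Σ_c I_c Δλ,

with c = 0…N−1 the channel index and k the harmonic. Using the channel
index (not the wavelength itself) in the kernel argument makes a flat
spectrum land exactly at the origin and spans k full periods of the kernel
across the detector — the convention under which the geometric properties
below hold. Properties relied on throughout:

* **Linearity.** The phasor of a·S1 + b·S2 is the intensity-weighted convex
  combination of the pure phasors; mixtures lie on the segment joining
  their components.
* **Boundedness.** Nonnegative spectra map into the closed unit disc.
* **Null pixels.** Zero-intensity pixels have no defined phasor (the
  normalizing denominator vanishes); they carry the sentinel (0, 0), are
  flagged, excluded from the histogram, and rendered black.

Harmonic choice: k = 2 (default) doubles the angular dispersion of similar
spectra and is used for nearly identical spectra; k = 1 suits datasets
whose spectra already spread over a wide phasor arc (it keeps them inside
one palette revolution). k ∈ {1, 2, 3} is supported.

Polar form: θ is the quadrant-aware `atan2(s, g)` mapped to [0, 2π); θ is
undefined at the origin and set to 0 there (tolerance 1e−12 absorbs
floating-point noise in nominally zero coordinates).

## Phasor-space denoising

Median filters (odd square kernel, default 3×3, reflective padding) are
applied to the g and s images independently, per z-slice, for 0–5 cycles
(default 1). Intensities and pixel positions are untouched, so the
operation is spatially lossless; null pixels stay null. Within a
spectrally homogeneous region the phasor-cloud variance shrinks per cycle;
at region *borders* the window necessarily mixes neighboring spectra —
tests therefore assert the shrinking property on eroded region interiors.

## Histogram and reference maps

Non-null phasors are binned on an n_bins × n_bins grid over [−1, 1]²
(default 256; the bin index of every pixel is retained so a bin-indexed
color table can be applied back to the image). The four standard maps
assign HSV colors from (r, θ) as tabulated in the README; hue varies with
the phase angle for the angular and both gradient maps, and everything
outside r = 1 is black. The radial map and the tensor map use a fixed
piecewise-linear jet ramp (anchors 0→(0,0,0.5), 0.125→(0,0,1),
0.375→(0,1,1), 0.625→(1,1,0), 0.875→(1,0,0), 1→(0.5,0,0)) so results do
not depend on a plotting library's colormap revision.

The tensor map differentiates the histogram counts with second-order
central differences (unit bin spacing) in the interior and one-sided
differences on the boundary rows/columns, takes the gradient magnitude D,
and normalizes it to max 1; pixels are colored by the jet ramp at their
bin's D. Bins with equal D share a color, which renders iso-gradient
contours of the phasor plot as flat colors in the image (spectral edge
detection).

## Adaptive modes

**Scale mode.** The occupied bins' bounding box defines the warp: a data
point is translated by the box center and divided by the semi-axes
(a, b) = (width/2, height/2), so the box's inscribed ellipse maps exactly
onto the reference map's unit circle. The automatically computed box
inflates the tight occupied-bin box by √2 about its center: the inscribed
ellipse of the inflated box passes through the tight box's corners, so
every occupied bin — including clusters sitting at box corners — receives
a color. (The inflation factor cancels out of the hue and only rescales
the lookup radius; without it, corner clusters fall outside the ellipse
and render black.) A tight box (`cover="box"`), percentile trimming of
marginal outliers (default 0%), and fully explicit boxes (for palettes
held constant across samples) are available. A box with a zero semi-axis
is rejected.

**Morph mode.** The map is read as the top view of a unit-height cone over
the phasor plane, apex above the origin. Shifting the apex to a
data-derived point A (inside the unit circle) tilts the cone; each
horizontal cut is a circle of radius 1 − α centered at α·A. A data point p
is assigned the α ∈ [0, 1) solving

    (p − αA)·(p − αA) = (1 − α)²,

a quadratic with a unique admissible root in the generic case; when two
roots lie in [0, 1) the smaller (closer to the standard map) is taken. The
lookup coordinate is p − αA. Unit-circle points get α = 0 and are fixed;
apex (0, 0) reproduces the standard map exactly; p exactly at the apex is
special-cased to the map origin. A is the highest-count bin center
(*max morph*) or the count-weighted centroid (*mass morph*). Modes are
exclusive — scale and morph are not composed.

## Baseline renderings

*Gaussian-kernel TrueColor*: per output channel with center wavelength x′
(defaults 650/510/470 nm for R/G/B, σ = 50 nm) the kernel over spectral
channels is K_i = exp(−(λ_i − x′)²/2σ²), normalized to sum 1 across
channels; the channel value is the spectrum–kernel dot product and the
image is normalized by its global maximum. σ is never tied to the detector;
50 nm covers ~5–6 channels of the default axis and yields smooth blending.
The kernel normalization makes the three output channels comparable in
scale regardless of how many spectral channels each center overlaps.
*Adaptive centers* place blue/red at the wavelengths where the normalized
dataset-average spectrum crosses a chosen fraction (0.10/0.20/0.30;
linear interpolation between channels, axis endpoints as fallback) and
green halfway between. *Peak wavelength* colors each pixel by the
piecewise-linear visible-spectrum color of its argmax channel (ties break
to the lowest wavelength; intensity-scale invariant). *Luminance MIP*
projects a z-stack by keeping, per pixel, the full RGB triple of the plane
with maximal NTSC luminance, so projected pixels keep physically
co-located colors rather than mixing channels across depths.

## Quality metrics

Colorfulness (opponent-space log-moment statistic), EME sharpness and AME
contrast (block measures, NTSC weights 0.299/0.587/0.114) and their fixed
linear poll CQE = 0.4358·colorfulness + 0.1722·sharpness + 0.3920·contrast
are computed on the 0–255 intensity scale with natural logarithms; both
scale and log base are conventions of the source metrics literature, are
configurable, and cancel out of the relative comparisons the package
makes. Blocks default to 8×8 (never standardized for these metrics;
reported with the scores). All logarithms and divisions are guarded with
ε = 255·10⁻⁴. AME's printed form is read with the outer sum over block
rows and the inner over block columns.

Separation accuracy uses region-*mean* RGB vectors on [0, 1]: the summed
pairwise Euclidean distances of the three region means divided by 3√2, the
exact maximum attained by pure red/green/blue — this choice makes the
statistic's ceiling exact, whereas per-pixel pairing (also available in
spirit via the mean) would blur it with within-region noise.

## Simulated hyperspectral test chart

The chart is 300×300×32 by default: a 3×3 grid of 100×100 cells, each with
three concentric square regions (outer ring 25 px, middle ring 15 px,
20×20 center square) carrying spectra S1, S2, S3. Because the real
CFP/YFP/RFP emission spectra behind the original chart are not tabulated,
Gaussian surrogates are used — peaks 475/527/580 nm, σ 15 nm, amplitude 1
— with every parameter exposed. S1 is shifted blue-ward by d1 and S3
red-ward by d2 (scalars or per-cell 3×3 arrays; natural steps are channel
bandwidth multiples 0/8.9/17.8/26.7/35.6 nm); the grid's center cell always
carries the unshifted spectra. `overlap_chart` builds the
controlled-overlap variant in which all three spectra derive from the
single YFP-like base peak and every cell (center included) carries the
same shifted triple — the configuration used by the benchmark.

Noise model: the cube is scaled so its brightest sample expects
`photon_scale` photons, each channel draws a Poisson count, zero-mean
Gaussian read noise (sd `read_sigma`) is added, and the result is clipped
at zero. A seed is mandatory. The generator emulates shot and read noise
only — no detector spectral response curves, bleed-through, or spatial
correlations — so passing tests demonstrate the pipeline's behavior under
idealized spectra and noise, not performance on real tissue.

## The separation benchmark

`seerpy.workflows.separation_benchmark` renders `overlap_chart` cubes under
two regimes — maxima separations (0, 8.9) nm ("high overlap") and
(17.8, 35.6) nm ("moderate overlap") — at photon scale 100, read noise
sd 2, over ten seeds, and reports the mean ratio of separation accuracies
between the phasor rendering (gradient-descent map, scale mode, one
denoise cycle, 256 bins, flat color mask) and Gaussian-kernel TrueColor at
default centers. The high-overlap regime is transformed at harmonic 2, the
moderate-overlap regime at harmonic 1 (its spectra already span a wide
phasor arc). Chart size 300×300 keeps a ten-seed regime under ~3 s.

Observed behavior: the fold-improvement is large (~5×) in the high-overlap
regime, where TrueColor collapses the three spectra to nearly one color.
In the moderate-overlap regime the ratio is modest (~1.2×): TrueColor
already resolves 17.8–35.6 nm separations reasonably well, while the
gradient-descent map's value ramp (1 − 0.85 r) dims the extreme phasor
clusters that scale mode necessarily places near the warped unit circle,
capping the attainable region-color distances. Brighter maps (e.g. the
angular map, value ≡ 1) do not share this cap; the benchmark nevertheless
fixes gradient-descent + scale for both regimes to compare one protocol.

## Numerical conventions and limitations

* Cubes are `(z, y, x, λ)` float64 internally; λ always last; readers
  normalize TIFF channel-as-plane layouts.
* RGB files are 8-bit, quantized with round-half-up; round-trips are exact
  to 1/255.
* Histogram bins cover [−1, 1]² half-open, with +1 included in the last
  bin; every pixel's bin index is stored at binning time so LUT rendering
  and histogram counts can never disagree.
* Morph's quadratic is solved in closed form; the discriminant is clamped
  at 0 against rounding; points outside the unit disc pass through
  unchanged and render black downstream.
* The jet ramp, HSV→RGB hexcone, and NTSC weights are fixed constants.
* Vendor microscope formats, FLIM phasors, volumetric ray-casting, and
  movie encoding are out of scope.
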