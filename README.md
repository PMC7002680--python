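# seerpy

Phasor-based **S**pectrally **E**ncoded **E**nhanced **R**epresentations
(SEER) of hyperspectral fluorescence image cubes.

Multispectral fluorescence microscopy produces cubes `I(x, y[, z], λ)` —
typically 32 spectral channels from 410.5 nm at 8.9 nm bandwidth — whose
fluorophores (and intrinsic signals such as NADH, retinoids, folic acid)
overlap heavily in emission. Conventional RGB compressions assign nearly the
same color to spectra whose maxima differ by only a few nanometers. seerpy
implements the phasor alternative for microscopists and image-analysis
developers who need to *see* those differences without unmixing.

## The method

Each pixel spectrum is compressed to its spectral phasor at harmonic *k*
(default 2):

```
g = Σ_c I(λ_c) cos(2πkc/N) Δλ / Σ_c I(λ_c) Δλ
s = Σ_c I(λ_c) sin(2πkc/N) Δλ / Σ_c I(λ_c) Δλ
```

The transform is linear in the spectrum, maps all nonnegative spectra into
the unit disc, and turns nanometer-scale shifts of the emission maximum into
resolvable displacements on the (g, s) plane. Median filtering of the g and
s images (phasor-space denoising) shrinks phasor clusters without moving a
single pixel. A *reference map* then assigns a color to every bin of the 2D
phasor histogram `F(g, s)`:

| map | hue | value |
|---|---|---|
| gradient descent | θ/2π | 1 − 0.85 r |
| gradient ascent | θ/2π | r |
| angular | θ/2π | 1 |
| radial | jet colormap on r | — |

plus a *tensor map* that colors pixels by the normalized gradient magnitude
`D(g,s) = √((∂F/∂g)² + (∂F/∂s)²)` of the histogram counts — a spectral edge
detector. Two dataset-adaptive modes re-spread the palette over the data:
**scale mode** warps the map's unit circle onto the bounding ellipse of the
occupied phasor bins, and **morph mode** shifts the map apex to the
histogram maximum (*max*) or count-weighted centroid (*mass*) through a
shifted-cone geometry that keeps the unit circle anchored.

The package also provides the baselines these renderings are judged against
(Gaussian-kernel TrueColor with fixed or adaptive centers, peak-wavelength
coloring, luminance MIP), the no-reference quality metrics (colorfulness,
EME sharpness, AME contrast, CQE) and the spectral-separation-accuracy
statistic, and a Simulated Hyperspectral Test Chart (SHTC) generator with a
Poisson + detector-read-noise model, so the whole pipeline is testable
without microscope data.

## Worked example

```python
import seerpy as sp
from seerpy.workflows import seer_rendering

# three spectra whose maxima lie within one 8.9 nm channel of each other
cube, masks = sp.overlap_chart((0.0, 8.9))
noisy = sp.add_noise(cube, photon_scale=100, read_sigma=2, seed=1)

rgb = seer_rendering(noisy)             # gradient-descent map, scale mode
tc = sp.truecolor_gaussian(noisy)       # Gaussian-kernel TrueColor baseline

regions = [masks[k][0] for k in ("outer", "middle", "center")]
print(sp.separation_accuracy(rgb[0], regions))   # 0.281
print(sp.separation_accuracy(tc[0], regions))    # 0.053
```

Separation accuracy is the sum of pairwise Euclidean distances between the
region-mean RGB colors, normalized by the pure-red/green/blue maximum 3√2;
1.0 means perfectly separated colors, 0 identical ones. Here the phasor
rendering separates three nearly identical spectra about 5× better than the
TrueColor compression (`examples/compare_baselines.py` prints the full
table including the CQE quality scores).

The `examples/` directory holds one short script per capability: chart
rendering, baseline comparison, the 4 maps × 4 modes gallery, phasor
denoising, and the overlap benchmark. A thin CLI wraps the same calls:

```bash
seer chart --d1 8.9 --d2 17.8 --photons 100 --seed 1 --out shtc.h5
seer render shtc.h5 --map gradient_descent --mode scale --out shtc.png
seer metrics shtc.png
```

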