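"""Phasor-space median denoising: shrink the phasor cloud without touching
intensities or pixel positions.
"""

import numpy as np
from scipy.ndimage import binary_erosion

import seerpy as sp

cube, masks = sp.build_shtc()
noisy = sp.add_noise(cube, photon_scale=50, read_sigma=2, seed=2)

field = sp.spectral_phasor(noisy, harmonic=2)
# measure inside the region: at its borders the median window deliberately
# mixes neighboring spectra
m = np.stack([binary_erosion(sl, iterations=2) for sl in masks["middle"]])
print(f"{'cycles':>6s} {'var(g)+var(s)':>14s}")
for cycles in range(4):
    den = sp.phasor_denoise(field, cycles=cycles)
    var = den.g[m].var() + den.s[m].var()
    print(f"{cycles:6d} {var:14.6f}")
    assert np.array_equal(den.intensity_sum, field.intensity_sum)

print("\nvariance of the middle-region phasor cloud drops with each median cycle;")
print("the intensity image is untouched (spatially lossless).")
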