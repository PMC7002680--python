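"""Compare the phasor rendering against TrueColor and peak-wavelength
baselines on one noisy chart, scoring each with the no-reference metrics.
"""

import seerpy as sp
from seerpy.workflows import seer_rendering

# three spectra whose maxima are within one channel bandwidth of each other:
# the regime where conventional compressions collapse to one color
cube, masks = sp.overlap_chart((0.0, 8.9))
noisy = sp.add_noise(cube, photon_scale=100, read_sigma=2, seed=1)
region_masks = [masks[k][0] for k in ("outer", "middle", "center")]

renderings = {
    "seer_scale": seer_rendering(noisy)[0],
    "truecolor": sp.truecolor_gaussian(noisy)[0],
    "peak_wavelength": sp.peak_wavelength_rgb(noisy)[0],
}

print(f"{'rendering':16s} {'sep.acc':>8s} {'colorful':>9s} {'sharp':>7s} {'contrast':>9s} {'cqe':>7s}")
for name, rgb in renderings.items():
    sep = sp.separation_accuracy(rgb, region_masks)
    q = sp.cqe(rgb)
    print(f"{name:16s} {sep:8.3f} {q.colorfulness:9.3f} {q.sharpness:7.3f} "
          f"{q.contrast:9.4f} {q.cqe:7.3f}")
print("\nsep.acc: pairwise RGB distance of the three spectral regions, 1 = pure RGB.")
print("cqe combines colorfulness, sharpness (EME) and contrast (AME).")
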