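"""Render one chart under all 4 reference maps x 4 contrast modes.

Writes 16 PNGs plus the map legends; every pairing highlights a different
feature of the phasor distribution.
"""

import seerpy as sp
from seerpy.pipeline import RunConfig, render_cube

cube, _ = sp.build_shtc(sp.SHTCSpec(d1=8.9, d2=17.8))
noisy = sp.add_noise(cube, photon_scale=100, read_sigma=2, seed=1)

for map_name in ("gradient_descent", "gradient_ascent", "radial", "angular"):
    sp.write_rgb(sp.map_legend(map_name), f"legend_{map_name}.png")
    for mode in ("standard", "scale", "morph_max", "morph_mass"):
        rgb, _, _ = render_cube(noisy, RunConfig(input="-", map_name=map_name, mode=mode))
        path = f"shtc_{map_name}_{mode}.png"
        sp.write_rgb(rgb[0], path)
        print("wrote", path)
print("\nstandard mode uses the fixed palette; scale stretches it over the data's")
print("bounding ellipse; morph shifts the palette center to the histogram max/centroid.")
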