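"""Render a synthetic kidney-specimen phantom and inspect its spectra.

Builds the default scene (fat rim, NRP interior, RSF pocket, tumor
ellipse), renders a reflectance hypercube with noise and glare, and prints
the per-tissue pixel counts and the absorbance each recipe synthesizes at
the five chromophore peaks.
"""

import numpy as np

from mcidetect import (
    default_scene,
    default_tissue_recipes,
    render_phantom,
    synthesize_signature,
)

layout = default_scene()
recipes = default_tissue_recipes()
cube, mask, reference = render_phantom(
    layout, recipes, noise_sd=0.01, glare_fraction=0.01, seed=0
)

print(f"hypercube: {cube.spatial_shape[0]}x{cube.spatial_shape[1]} pixels, "
      f"{cube.n_bands} bands ({cube.wavelengths_nm[0]:g}-"
      f"{cube.wavelengths_nm[-1]:g} nm)")
print("tissue pixel counts:", mask.class_counts())

peaks = [545.0, 575.0, 755.0, 930.0, 965.0]
print("\nsynthesized absorbance at chromophore peaks "
      "(oxy-Hb, oxy-Hb, deoxy-Hb, lipid, water):")
for name in mask.class_names:
    sig = synthesize_signature(recipes[name], np.array(peaks))
    print(f"  {name:>6}: " + "  ".join(f"{v:.3f}" for v in sig))
print("\nTumor shows the largest water absorption (965 nm); fat and RSF the "
      "largest lipid absorption (930 nm) — the contrast every later stage "
      "exploits.")
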