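"""Calibrate a raw leaf scene to reflectance and segment the blade.

Renders a synthetic half-darkened Nicotiana benthamiana leaf (high blue
light on the right half, so its chloroplasts take the avoidance position),
converts digital numbers to relative reflectance against the in-scene
white standard, and separates leaf from background by NDVI thresholding.
"""

import numpy as np

from chloromotion.hypercube_io import calibrate_reflectance
from chloromotion.leafscene import exclude_veins, segment_leaf, split_halves
from chloromotion.synthsim import GeneratorConfig, generate_scene_cube

cfg = GeneratorConfig(species="nicotiana", genotype="WT", condition="high", seed=42)
cube, truth = generate_scene_cube(cfg, irradiated_side="right")
print(f"raw cube: {cube.shape[0]}x{cube.shape[1]} pixels, {cube.shape[2]} bands, dtype {cube.data.dtype}")

refl = calibrate_reflectance(cube, truth["references"])
white_mean = refl.data[truth["white"]].mean()
print(f"white standard after calibration: mean reflectance {white_mean:.4f} (should be ~1.0)")

leaf = segment_leaf(refl, ndvi_threshold=0.4)
recovered = (leaf & truth["leaf"]).sum() / truth["leaf"].sum()
print(f"leaf mask: {leaf.sum()} px, {100*recovered:.1f}% of true leaf pixels recovered")

darkened, irradiated = split_halves(leaf, "auto", irradiated_side="positive")
print(f"halves along the principal axis: {darkened.sum()} / {irradiated.sum()} px")

analysis, excluded = exclude_veins(refl, leaf)
vein_frac = (excluded & truth["vein"]).sum() / truth["vein"].sum()
print(f"vein exclusion (98th CMI percentile): {excluded.sum()} px excluded, "
      f"{100*vein_frac:.0f}% of the true vein")
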