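# chloromotion

Detecting chloroplast positioning from hyperspectral leaf reflectance.

Chloroplasts relocate under blue light: in low light they move to cell
walls perpendicular to the beam (**accumulation** — the leaf darkens), in
high light to walls parallel to it (**avoidance** — the leaf pales).
These movements change leaf reflectance enough to be measured with a
VNIR (400–1000 nm) hyperspectral camera, to perturb common vegetation
indices, and to be classified from single spectra. `chloromotion`
implements that pipeline for plant photobiologists and remote-sensing
researchers:

- **ENVI I/O and calibration** — raw digital numbers to relative
  reflectance against a white diffuse standard,
  `R = (DN − dark) / (W − dark)` per band.
- **Leaf scene analysis** — NDVI-threshold segmentation, darkened/
  irradiated half splitting along the main vein, vein exclusion by CMI
  percentile, per-pixel index maps.
- **Spectra** — region/block mean spectra, 60×60-px block augmentation,
  L2 normalisation over 400–750 nm, differential reflectance curves
  (irradiated − darkened) and their local extrema.
- **Indices** — the generic normalized difference
  `ND(λ1, λ2) = (R_λ1 − R_λ2)/(R_λ1 + R_λ2)`, the **Chloroplast Movement
  Index** `CMI = (R635 − R555)/(R635 + R555)`, and 17 published
  narrow-band vegetation indices (NDVI, SR, EVI, ARVI, RENDVI, mRENDVI,
  mRESR, SG, VOG1–3, PRI, SIPI, RGRI, PSRI, CAR1, CAR2) with per-leaf
  between-half deltas.
- **Wavelength-pair scan** — point-biserial correlation
  `r = (M1 − M0)/s · √(n1·n0/n²)` between ND(λ1, λ2) and the binary
  positioning label over all band pairs in 400–750 nm, with constrained
  local-maximum candidate selection (search 550–670 nm, exclusion
  [500, 550) nm). This is the scan that singles out the (635, 555) nm
  CMI pair.
- **Classifiers** — linear/poly/sigmoid/RBF SVM, a 21-10-3 multilayer
  perceptron and a four-block 1-D CNN (kernels 11/9/7/5, feature maps
  8/16/32/64, max-pool width 5 stride 2, dense head 64/32/16/3), trained
  with Adam at batch size 64 under a leaf-grouped 25% test split and
  repeated balanced 5-fold cross-validation, including cross-species
  evaluation.
- **Statistics** — Welch two-sample comparisons of per-leaf Δindex
  distributions.
- **Synthetic generator** — calibrated three-class leaf spectra
  (dark / accumulation / avoidance) for two species presets
  (*Nicotiana benthamiana*, *Arabidopsis thaliana*) and five genotypes
  (WT, *phot1*, *phot2*, *phot1phot2*, *jac1*), plus whole-leaf scenes
  with vein, background and white standard. No raw imaging data ship
  with the package; the generator reproduces the reported statistical
  structure (~11 % dark visible reflectance, ~2.3 % avoidance −
  accumulation offset, CMI in [−0.45, −0.1], ΔNDVI ≈ 0.05,
  |ΔRGRI| ≈ 0.1, the 684/695 nm fluorescence features) and serves as the
  package's test surface.

## Worked example

```python
import numpy as np
from chloromotion.dataset import LabeledSpectraSet
from chloromotion.scan import ScanConstraints, biserial_surface, find_candidate_pairs
from chloromotion.synthsim import generate_class_spectra

accum = generate_class_spectra("nicotiana", "accumulation", n_leaves=60, seed=11)
avoid = generate_class_spectra("nicotiana", "avoidance", n_leaves=60, seed=511)
surface = biserial_surface(LabeledSpectraSet.concat([accum, avoid]))
for l1, l2, r in find_candidate_pairs(surface, ScanConstraints())[:2]:
    print(f"({l1:5.1f}, {l2:5.1f}) nm   r = {r:+.3f}")
```

prints

```
(639.8, 562.8) nm   r = +0.949
(650.8, 668.4) nm   r = +0.834
```

The top-ranked pair is the red/green band combination nearest
(635, 555) nm: the ND index over these bands — the CMI — correlates at
r ≈ 0.95 with the avoidance response in this 120-spectrum scan, which is
why it separates accumulation from avoidance so cleanly. The
`examples/` directory holds one short script per capability
(calibration and segmentation, differential curves, indices and Welch
tests, the scan, classification); each prints its results with a line on
what they mean.

A thin command-line interface wraps the same functions:

```bash
chloromotion simulate spectra --condition high --n 30 --seed 1 --out spectra.csv
chloromotion scan spectra.csv --out-dir scanout
chloromotion train spectra.csv --family cnn --epochs 200 --seed 42 --out-dir model
```

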