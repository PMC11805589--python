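"""The Chloroplast Movement Index and its effect on vegetation indices.

CMI = (R635 − R555)/(R635 + R555) is negative for leaves and rises as
chloroplasts move to the avoidance position. The script also shows how the
avoidance response shifts NDVI and RGRI between the darkened and
irradiated halves of the same leaves, and tests the shifts with Welch's t.
"""

import numpy as np

from chloromotion.indices import cmi, index_deltas, vegetation_index
from chloromotion.stats_report import welch_t
from chloromotion.synthsim import generate_class_spectra

for cls in ("dark", "accumulation", "avoidance"):
    ds = generate_class_spectra("nicotiana", cls, n_leaves=30, seed=3)
    values = [cmi(s) for s in ds.spectra]
    print(f"CMI {cls:>12}: mean {np.mean(values):+.3f}  range [{min(values):+.3f}, {max(values):+.3f}]")

dark = generate_class_spectra("nicotiana", "dark", 30, seed=5)
avoid = generate_class_spectra("nicotiana", "avoidance", 30, seed=1005)
accum = generate_class_spectra("nicotiana", "accumulation", 30, seed=2005)

deltas_high = index_deltas(list(zip(dark.spectra, avoid.spectra)), ["NDVI", "RGRI", "CMI"])
deltas_low = index_deltas(list(zip(dark.spectra, accum.spectra)), ["NDVI", "RGRI", "CMI"])
print("\nper-leaf index shifts (darkened − irradiated), mean over 30 leaves:")
for name in ("NDVI", "RGRI", "CMI"):
    hi = [d.delta for d in deltas_high if d.index_name == name]
    lo = [d.delta for d in deltas_low if d.index_name == name]
    res = welch_t(hi, lo, "high", "low")
    print(f"  {name:>4}: high-light {np.mean(hi):+.3f}, low-light {np.mean(lo):+.3f},"
          f"  Welch t={res.t:+.1f}, p={res.p:.2g}")
print("\nΔNDVI ~ +0.05 and |ΔRGRI| ~ 0.1 under avoidance are comparable to")
print("the shifts these indices show for real trait differences.")
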