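"""Reproduce the wavelength-pair scan that selects the CMI bands.

For every band pair (λ1, λ2) in 400-750 nm the normalized difference
ND = (Rλ1 − Rλ2)/(Rλ1 + Rλ2) is correlated (point-biserial) with the
binary accumulation/avoidance label. Strict local maxima inside the
550-670 nm search window — excluding 500-550 nm, where non-movement
blue-light responses bias reflectance — are the candidate index pairs.
"""

from chloromotion.dataset import LabeledSpectraSet
from chloromotion.scan import ScanConstraints, biserial_surface, find_candidate_pairs
from chloromotion.synthsim import generate_class_spectra

accum = generate_class_spectra("nicotiana", "accumulation", n_leaves=60, seed=11)
avoid = generate_class_spectra("nicotiana", "avoidance", n_leaves=60, seed=511)
spectra = LabeledSpectraSet.concat([accum, avoid])

surface = biserial_surface(spectra, positive_class="avoidance")
print(f"surface: {surface.r.shape[0]}x{surface.r.shape[1]} band pairs, "
      f"groups n0={surface.n0} (accumulation) / n1={surface.n1} (avoidance)")

candidates = find_candidate_pairs(surface, ScanConstraints())
print("top candidate pairs (λ1, λ2, r):")
for l1, l2, r in candidates[:5]:
    print(f"  ({l1:5.1f}, {l2:5.1f}) nm   r = {r:+.3f}")
print("the top pair sits near (635, 555) nm — the red/green bands of the CMI;")
print("positive r means the index rises with the avoidance response.")
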