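"""Quarter-wavelength trace resolvability: NSI vs. DAS.

Two microbubbles descend 25 um apart laterally (a quarter of the imaging
wavelength).  The full chain runs for both beamformers on the same
sensitivity-corrected channel data; the lateral power-Doppler cross-section
through the traces is tested with the dip-below-half-maximum criterion.
"""

import numpy as np

from nsidoppler import experiments

result = experiments.trace_pair_resolution(25e-6, seed=1)

for method in ("nsi", "das"):
    profile = result[f"{method}_profile"]
    n_peaks = "two peaks" if result[f"{method}_resolved"] else "one peak"
    print(f"{method.upper():4s}: {n_peaks}  "
          f"(profile max {profile.max():.3g}, "
          f"center dip {profile[len(profile) // 2]:.3g})")

print()
print("NSI separates the 25-um pair because its null-inverted beam is far")
print("narrower than the 98.6-um diffraction-limited DAS beam; DAS merges")
print("both traces into a single peak.")
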