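"""Generate a synthetic mushroom population and inspect its structure.

Draws 200 diffuse-reflectance spectra (450-760 nm, 1 nm) with known
moisture content, browning grade, scatter parameters and whiteness, then
prints the ground-truth summary a real study would have to measure.
"""

import numpy as np

from agarispec import GeneratorConfig, generate_spectra, write_spectra

sset, truth = generate_spectra(GeneratorConfig(n_samples=200, seed=1))
print(f"{len(sset)} spectra on {sset.grid.n_bands} bands "
      f"({sset.grid.start_nm:.0f}-{sset.grid.end_nm:.0f} nm)")
print(f"reflectance range: {sset.values.min():.3f} .. {sset.values.max():.3f}")
print(f"moisture: {truth.moisture.min():.1f} .. {truth.moisture.max():.1f} % "
      f"(mean {truth.moisture.mean():.1f} %)")
print(f"clean whiteness W10: median {np.median(truth.whiteness):.2f}")
print(f"scatter slope b_i: {truth.scatter_slope.min():.3f} .. "
      f"{truth.scatter_slope.max():.3f}")

write_spectra(sset, "synthetic_spectra.csv")
print("wrote synthetic_spectra.csv (reflectance matrix + labels)")
# The labels column moisture_pct is the wet-basis moisture a drying oven
# would measure; downstream models try to recover it from the spectra alone.
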