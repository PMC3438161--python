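"""Compare cell-length variability between two populations.

Mycobacterial three-spot cells are far more variable in length than
C. glutamicum.  The comparison uses a rank-sum test on absolute deviations
from each sample's median — a nonparametric test of spread that needs no
normality assumption.
"""

import numpy as np

from poletrack import length_variability_test
from poletrack.config import SPECIES_LENGTH_PARAMS

rng = np.random.default_rng(1)
smeg = rng.normal(*SPECIES_LENGTH_PARAMS["M_smegmatis_mc2_155"], 60)
cglut = rng.normal(*SPECIES_LENGTH_PARAMS["C_glutamicum"], 60)

w, p = length_variability_test(smeg, cglut)
print(f"M. smegmatis lengths:  {smeg.mean():.2f} +/- "
      f"{smeg.std(ddof=1):.2f} µm (n=60)")
print(f"C. glutamicum lengths: {cglut.mean():.2f} +/- "
      f"{cglut.std(ddof=1):.2f} µm (n=60)")
print(f"rank-sum of deviations W = {w:.1f}, two-sided p = {p:.2e}")
print("\np << 0.01: the mycobacterial population is significantly more "
      "variable in length, mirroring the wide range of sizes at which "
      "these cells divide.")
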