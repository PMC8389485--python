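"""Raup-Crick null-model inference: which site pairs are more (or less)
similar than random assembly from the regional pool would produce?

Builds a community with two deterministically similar sites and two
species-rich background sites, runs 9,999 null replicates, and prints the
rescaled beta_RC in [-1, 1] per pair with its significance class.
"""

import numpy as np

from ventbeta import IncidenceMatrix, percent_significant, raup_crick

occ = np.zeros((4, 20), dtype=bool)
occ[0, :4] = True          # site A: small assemblage ...
occ[1, :4] = True          # site B: ... identical to A
occ[2, ::2] = True         # sites C, D: rich, overlapping backgrounds
occ[3, :] = True
m = IncidenceMatrix(("A", "B", "C", "D"), tuple(f"sp{i}" for i in range(20)), occ)

results = raup_crick(m, n_sim=9999, ci_level=0.95, seed=42)
print(f"{'pair':10s} {'shared':>6s} {'beta_RC':>8s}  class")
for r in results:
    print(f"{r.site_i}-{r.site_j:8s} {r.observed_shared:6d} {r.beta_rc:8.3f}  {r.sig_class}")
print(f"\n% of pairs beyond the 95% band: {percent_significant(results):.1f}")
print(
    "\nbeta_RC near -1 (class 'similar'): the pair shares far more species\n"
    "than richness-matched random draws — deterministic assembly; near +1:\n"
    "far fewer — strong differentiation; 'ns' pairs are indistinguishable\n"
    "from random draws out of the regional pool."
)
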