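"""Richness arithmetic for the three North Pacific vent systems.

Uses the bundled per-site richness (alpha) and system richness (gamma)
summaries to compute Whittaker's multiplicative beta (gamma / mean alpha):
how many "average sites" worth of species the whole system holds.
"""

import numpy as np

from ventbeta.datasets import backarc_checklist, system_alpha, system_gamma
from ventbeta.partition import whittaker_from_alpha

for system in ("backarc", "arc", "jdf"):
    alpha = system_alpha(system)
    gamma = system_gamma(system)
    beta_w = whittaker_from_alpha(alpha.values(), gamma)
    print(
        f"{system:8s}  gamma={gamma:3d}  mean alpha={np.mean(list(alpha.values())):5.1f}"
        f"  Whittaker beta={beta_w:.2f}"
    )

print()
print(f"northern back-arc checklist: {len(backarc_checklist())} macrofaunal species")
print()
print(
    "A Whittaker beta near 2 (back-arc, ridge) means the regional pool is\n"
    "about twice a typical site's richness; the volcanic arc's ~3.5 signals\n"
    "much stronger compositional change from site to site."
)
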