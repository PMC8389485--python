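"""Partition pairwise beta diversity into overlap / replacement / richness
difference on synthetic communities with known structure.

A strictly nested community has zero replacement (R_J = 0, beta_ratio = 1);
a pure-turnover community has zero richness difference (D_J = 0,
beta_ratio = 0).  The summary table is the per-system digest the method
produces for real survey matrices.
"""

from ventbeta import SyntheticSpec, decompose_all, generate_community, summarize_decomposition
from ventbeta.partition import ternary_coordinates

for regime, kwargs in [
    ("nested", {"richness": (32, 28, 24, 20, 16, 12, 8, 4)}),
    ("turnover", {}),
    ("mixed", {"mix_weight": 0.5, "richness": (20,) * 8}),
]:
    m = generate_community(SyntheticSpec(regime=regime, seed=7, **kwargs))
    pairs = decompose_all(m)
    s = summarize_decomposition(pairs)
    print(f"--- {regime} regime ({m.n_sites} sites, {m.gamma()} species) ---")
    print(s.loc[["o_j", "r_j", "d_j", "beta_j", "n_j", "beta_ratio"], ["mean", "median"]].round(3))
    print()

coords = ternary_coordinates(decompose_all(generate_community(SyntheticSpec(seed=7))))
print("first 3 simplex coordinates (barycentric O/R/D and 2-D projection):")
print(coords.head(3).round(3).to_string(index=False))
print()
print(
    "Mean beta_ratio > 0.5 says richness differences dominate dissimilarity\n"
    "(protect the richest sites first); < 0.5 says species replacement\n"
    "dominates (several sites are needed to cover the pool)."
)
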