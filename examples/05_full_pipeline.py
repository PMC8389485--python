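"""End-to-end report bundle on two synthetic vent 'systems'.

Writes per-system pairwise components, Raup-Crick tables, LCBD, minimum
sets, Newick dendrograms and the cross-system permutation tests into an
output directory, exactly as one would for real survey matrices.
"""

import tempfile
from pathlib import Path

from ventbeta import PipelineConfig, SyntheticSpec, generate_community, run_pipeline, write_incidence

workdir = Path(tempfile.mkdtemp(prefix="ventbeta_demo_"))
inputs = {}
for name, regime, kwargs in [
    ("ridge_like", "nested", {"richness": (30, 26, 22, 18, 14, 10, 8, 6)}),
    ("arc_like", "turnover", {"richness": (10,) * 8}),
]:
    m = generate_community(SyntheticSpec(regime=regime, seed=5, **kwargs))
    path = workdir / f"{name}.csv"
    write_incidence(m, path, "wide")
    inputs[name] = path

config = PipelineConfig(
    inputs=inputs,
    outdir=workdir / "report",
    seed=2024,
    n_sim=999,
    n_perm=999,
)
results = run_pipeline(config)

for name, res in results["per_system"].items():
    rich = res["richness"]
    print(f"--- {name}: gamma={rich['gamma']}, Whittaker beta={rich['whittaker']:.2f}")
    print(res["summary"].round(3))
    ms = res["minimum_set"]
    print(f"minimum set: {ms.min_size}/{len(res['lcbd'].site_ids)} sites\n")

anova = results["comparisons"]["beta_j_anova"]
print(f"beta_J permutation ANOVA across systems: F={anova.statistic:.1f}, p={anova.p_value:.4f}")
print(f"\nfull bundle written under {config.outdir}")
print(
    "\nThe nested 'ridge-like' system shows beta_ratio ~1 and a 1-site\n"
    "minimum set; the turnover 'arc-like' system needs many sites to cover\n"
    "its pool — the contrast the cross-system F test quantifies."
)
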