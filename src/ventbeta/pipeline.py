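"""End-to-end analysis pipeline: one call from matrices to a report bundle.

``run_pipeline`` reads one or more incidence matrices, runs every stage
(pairwise decomposition, Raup-Crick, LCBD, richness summary, minimum set,
UPGMA dendrogram, ternary coordinates) per matrix, and — when several
matrices or group labels are supplied — the cross-system comparisons
(permutation ANOVA / t-tests on beta_J, within/between splits, group
overlap).  All outputs are plain CSV/JSON/Newick files under ``outdir``
plus a run log recording the seed and package versions; given the same
config and seed the bundle is byte-identical.
"""

from __future__ import annotations

import json
import platform
import sys
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import to_newick, upgma_from_incidence
from .incidence import IncidenceMatrix, occupancy_summary, read_incidence
from .inference import perm_anova, perm_t_test
from .lcbd import lcbd_permutation_test
from .partition import (
    decompose_all,
    pairs_to_frame,
    summarize_decomposition,
    ternary_coordinates,
    whittaker_ratio,
)
from .raupcrick import percent_significant, raup_crick, results_to_frame
from .selection import group_overlap, minimum_set, subset_pairs

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    ``inputs`` maps a system name to a matrix CSV path; ``layouts`` gives
    the per-input CSV layout (default wide).  ``groups`` optionally labels
    the sites of one input for within/between analyses.  The seed is
    mandatory: every stochastic stage derives its stream from it.
    """

    inputs: Mapping[str, str | Path]
    outdir: str | Path
    seed: int
    layouts: Mapping[str, str] = field(default_factory=dict)
    groups: Mapping[str, str] | None = None
    grouped_input: str | None = None  # which input `groups` labels
    n_sim: int = 9999
    n_perm: int = 9999
    ci_level: float = 0.95
    alpha_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("no input matrices")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.alpha_threshold < 1:
            raise ValueError("alpha_threshold must be in (0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a config from a YAML file (keys mirror PipelineConfig fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _summary_row(pairs, rc_results) -> pd.DataFrame:
    summ = summarize_decomposition(pairs)
    rows = {}
    for comp in ("beta_j", "n_j", "i_j", "rc_j", "beta_ratio"):
        rows[comp] = {
            "mean": summ.loc[comp, "mean"],
            "median": summ.loc[comp, "median"],
        }
    beta_rc = np.array([r.beta_rc for r in rc_results])
    rows["beta_rc"] = {"mean": beta_rc.mean(), "median": float(np.median(beta_rc))}
    rows["pct_significant_beta_rc"] = {
        "mean": percent_significant(rc_results),
        "median": np.nan,
    }
    return pd.DataFrame(rows).T


def _derive_seed(base: int, salt: str) -> int:
    # crc32 keeps the salt deterministic across processes (str hash is not)
    ss = np.random.SeedSequence([base, zlib.crc32(salt.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the results.

    The returned dict holds, per input name, the in-memory stage results;
    stage failures are re-raised with the stage and input named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrices: dict[str, IncidenceMatrix] = {}
    for name, path in config.inputs.items():
        layout = config.layouts.get(name, "wide")
        try:
            matrices[name] = read_incidence(path, layout=layout)
        except Exception as exc:
            raise RuntimeError(f"[read:{name}] {exc}") from exc

    results: dict = {"per_system": {}, "comparisons": {}}
    per_system_pairs = {}

    for name, mat in matrices.items():
        sysdir = outdir / name
        sysdir.mkdir(exist_ok=True)
        stage = "decompose"
        try:
            pairs = decompose_all(mat)
            per_system_pairs[name] = pairs
            pairs_to_frame(pairs).to_csv(sysdir / "pairwise_components.csv", index=False)
            ternary_coordinates(pairs).to_csv(sysdir / "ternary_coordinates.csv", index=False)

            stage = "richness"
            occ = occupancy_summary(mat)
            rich = pd.DataFrame(
                {"site": list(occ["alpha"]), "alpha": list(occ["alpha"].values())}
            )
            rich.to_csv(sysdir / "site_richness.csv", index=False)
            richness_summary = {
                "gamma": occ["gamma"],
                "mean_alpha": occ["mean_alpha"],
                "sd_alpha": occ["sd_alpha"],
                "whittaker": whittaker_ratio(mat),
                "n_ubiquitous": occ["n_ubiquitous"],
                "n_singletons": occ["n_singletons"],
            }

            stage = "raup_crick"
            rc = raup_crick(
                mat,
                n_sim=config.n_sim,
                ci_level=config.ci_level,
                seed=_derive_seed(config.seed, f"rc:{name}"),
            )
            results_to_frame(rc).to_csv(sysdir / "raup_crick.csv", index=False)

            stage = "summary"
            summary = _summary_row(pairs, rc)
            summary.to_csv(sysdir / "diversity_summary.csv")

            stage = "lcbd"
            lc = lcbd_permutation_test(
                mat, n_perm=config.n_perm, seed=_derive_seed(config.seed, f"lcbd:{name}")
            )
            pd.DataFrame(
                {"site": lc.site_ids, "lcbd": lc.lcbd, "p_value": lc.p_values}
            ).to_csv(sysdir / "lcbd.csv", index=False)

            stage = "minimum_set"
            ms = minimum_set(mat)
            (sysdir / "minimum_set.json").write_text(
                json.dumps(
                    {
                        "min_size": ms.min_size,
                        "n_sites": mat.n_sites,
                        "coverage_fraction": ms.coverage_fraction,
                        "solutions": [list(s) for s in ms.solutions],
                    },
                    indent=2,
                )
                + "\n"
            )

            stage = "cluster"
            tree = upgma_from_incidence(mat)
            (sysdir / "dendrogram.nwk").write_text(to_newick(tree) + "\n")

            results["per_system"][name] = {
                "matrix": mat,
                "pairs": pairs,
                "richness": richness_summary,
                "raup_crick": rc,
                "summary": summary,
                "lcbd": lc,
                "minimum_set": ms,
                "dendrogram": tree,
            }
        except Exception as exc:
            raise RuntimeError(f"[{stage}:{name}] {exc}") from exc

    # cross-system comparisons on the pairwise beta_J values
    if len(matrices) >= 2:
        names = list(matrices)
        groups_beta = {
            n: [p.beta_j for p in per_system_pairs[n]] for n in names
        }
        anova = perm_anova(
            list(groups_beta.values()),
            n_perm=config.n_perm,
            seed=_derive_seed(config.seed, "anova:beta_j"),
            labels=names,
        )
        t_tests = {}
        for a, b in combinations(names, 2):
            t_tests[f"{a}_vs_{b}"] = perm_t_test(
                groups_beta[a],
                groups_beta[b],
                n_perm=config.n_perm,
                seed=_derive_seed(config.seed, f"t:{a}:{b}"),
                labels=(a, b),
            )
        results["comparisons"]["beta_j_anova"] = anova
        results["comparisons"]["beta_j_t_tests"] = t_tests
        comp_rows = [
            {
                "test": "perm_anova_beta_j",
                "statistic": anova.statistic,
                "p_value": anova.p_value,
            }
        ] + [
            {"test": f"perm_t_{k}", "statistic": v.statistic, "p_value": v.p_value}
            for k, v in t_tests.items()
        ]
        pd.DataFrame(comp_rows).to_csv(outdir / "between_system_tests.csv", index=False)

    # group-labelled splits within one (usually combined) matrix
    if config.groups:
        name = config.grouped_input or next(iter(matrices))
        mat = matrices[name]
        ov = group_overlap(mat, config.groups)
        between = subset_pairs(per_system_pairs[name], config.groups, "between")
        within = subset_pairs(per_system_pairs[name], config.groups, "within")
        split = {
            "overlap": ov,
            "n_between_pairs": len(between),
            "n_within_pairs": len(within),
            "mean_between_beta_j": float(np.mean([p.beta_j for p in between]))
            if between
            else float("nan"),
        }
        results["comparisons"]["group_split"] = split
        (outdir / "group_split.json").write_text(
            json.dumps(
                {k: v for k, v in split.items() if k != "overlap"}
                | {
                    "groups": ov["groups"],
                    "gamma": ov["gamma"],
                    "n_shared": ov["n_shared"],
                    "combined_gamma": ov["combined_gamma"],
                    "shared_fraction": ov["shared_fraction"],
                },
                indent=2,
            )
            + "\n"
        )

    log = {
        "ventbeta_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "platform": platform.platform(),
        "seed": config.seed,
        "n_sim": config.n_sim,
        "n_perm": config.n_perm,
        "ci_level": config.ci_level,
        "alpha_threshold": config.alpha_threshold,
        "inputs": {k: str(v) for k, v in config.inputs.items()},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return results
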