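"""Pinned benchmark scenarios for validating the screening pipeline.

These fix the study conditions used by the verification suite: a
50-bird recaptured cohort from the default cross-foster design, null-site
simulations for calibration checks, the planted-category recovery
benchmark, and small high-coverage toy datasets for checking the Laplace
engine against quadrature.  Keeping them here (rather than scattered in
test code) makes every reported number reproducible from the package
alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .methio import FilterConfig, MethylationMatrix
from .simulate import SimulationConfig, make_category_plan, simulate_design

__all__ = [
    "BENCH_BASELINE_MIX",
    "TOY_GFF3",
    "study_cohort",
    "null_site_config",
    "recovery_config",
    "toy_glmm_dataset",
    "toy_design4",
    "filter_toy",
    "annotation_fixture_sites",
]

#: baseline-methylation mixture emulating sites that survive the
#: mean-methylation filter (fractions mostly within 0.05-0.95)
BENCH_BASELINE_MIX = ((0.5, -1.2, 0.6), (0.5, 1.2, 0.6))


def study_cohort(seed: int, n_per_treatment: int = 25) -> pd.DataFrame:
    """A balanced recaptured cohort from the default study design.

    The default design (16 cross-foster pairs, treatment-specific
    recapture) yields ~30 recaptured birds per treatment; the first
    ``n_per_treatment`` per group give a cohort of fixed size while
    keeping the nested brood structure.  Seeds whose realised recapture
    falls short of the requested size are skipped deterministically
    (the next seed is tried), so a cohort exists for every input seed.
    """
    for attempt in range(50):
        design = simulate_design(SimulationConfig(seed=seed + attempt))
        rec = design[design["recaptured"]]
        keep: list[str] = []
        for g in ("reduced", "enlarged"):
            ids = rec.loc[rec["treatment"] == g, "bird_id"].tolist()
            if len(ids) < n_per_treatment:
                keep = []
                break
            keep += ids[:n_per_treatment]
        if keep:
            return design[design["bird_id"].isin(keep)].reset_index(drop=True)
    raise RuntimeError(
        f"no seed in [{seed}, {seed + 50}) yields {n_per_treatment} recaptured "
        "birds per treatment"
    )


def null_site_config(seed: int, n_sites: int) -> SimulationConfig:
    """Null CpGs at study conditions: coverage ~30x, brood random
    intercepts (sd 0.3 logit), binomial observation noise."""
    return SimulationConfig(
        seed=seed,
        n_sites=n_sites,
        obs_overdispersion_sd=0.0,
        baseline_logit_mix=BENCH_BASELINE_MIX,
    )


def recovery_config(seed: int = 1, per_category: int = 100,
                    n_sites: int = 2000, slope: float = 0.025) -> SimulationConfig:
    """The planted-category recovery benchmark: 100 sites per category at
    +/-0.025 logit/day among nulls, coverage ~30x."""
    return SimulationConfig(
        seed=seed,
        n_sites=n_sites,
        category_plan=make_category_plan(per_category, slope),
        obs_overdispersion_sd=0.0,
        baseline_logit_mix=BENCH_BASELINE_MIX,
    )


def toy_glmm_dataset(seed: int, n_obs: int = 10, n_groups: int = 3,
                     coverage: int = 600, sigma: float = 0.4):
    """A single-random-factor toy for engine checks.

    Ten observations in three near-balanced groups with deep coverage:
    enough information per group that the Laplace approximation is
    accurate to well under 1e-3 (the intrinsic gap scales as one over
    the per-group information), so any implementation error is visible
    against an adaptive-quadrature evaluation.
    Returns (frame, group codes).
    """
    rng = np.random.default_rng(seed)
    sizes = [n_obs // n_groups + (1 if i < n_obs % n_groups else 0)
             for i in range(n_groups)]
    codes = np.repeat(np.arange(n_groups), sizes)
    days = rng.uniform(-40, 40, n_obs)
    treat = np.array(["reduced", "enlarged"] * (n_obs // 2 + 1))[:n_obs]
    u = rng.normal(0, sigma, n_groups)
    eta = -0.5 + 0.3 * (treat == "enlarged") + 0.01 * days + u[codes]
    tot = rng.poisson(coverage, n_obs) + 1
    meth = rng.binomial(tot, special.expit(eta))
    frame = pd.DataFrame(
        {
            "meth": meth,
            "total": tot,
            "days": days,
            "treatment": treat,
            "grp": [f"g{c}" for c in codes],
        }
    )
    return frame, codes


# ---------------------------------------------------------------------------
# hand-audited deterministic fixtures
# ---------------------------------------------------------------------------


def toy_design4() -> pd.DataFrame:
    """Minimal design: two individuals per treatment in one CF pair."""
    return pd.DataFrame(
        {
            "bird_id": ["r1", "r2", "e1", "e2"],
            "treatment": ["reduced", "reduced", "enlarged", "enlarged"],
            "cf_pair": ["CF00"] * 4,
            "brood_origin": ["a", "b", "a", "b"],
            "brood_rearing": ["a", "a", "b", "b"],
            "origin_in_pair": ["CF00:a", "CF00:b", "CF00:a", "CF00:b"],
            "rearing_in_pair": ["CF00:a", "CF00:a", "CF00:b", "CF00:b"],
            "days_since_fledging": [30, 50, 70, 90],
        }
    )


def filter_toy() -> tuple[MethylationMatrix, pd.DataFrame, FilterConfig]:
    """Hand-audited 10-site filter toy with telescoping report 10->8->5->4.

    With min_coverage=10 and min_individuals_per_group=2: sites 0-1 lose
    every cell to the coverage cut; sites 2-4 then miss group presence;
    site 5 has mean methylation > 0.95; sites 6-9 survive.
    """
    design = toy_design4()
    S, N = 10, 4
    total = np.full((S, N), 20, dtype=int)
    meth = np.full((S, N), 10, dtype=int)
    missing = np.zeros((S, N), dtype=bool)
    total[0] = [5, 9, 3, 8]
    total[1] = [2, 2, 2, 2]
    meth[0] = [1, 2, 1, 2]
    meth[1] = [1, 1, 1, 1]
    missing[2, 1] = True          # one reduced bird left
    total[3, 2:] = [4, 6]         # enlarged cells under-covered
    meth[3, 2:] = [1, 2]
    missing[4, 3] = True          # one enlarged bird left
    meth[5] = [20, 20, 19, 20]    # mean methylation > 0.95
    matrix = MethylationMatrix(
        sites=pd.DataFrame({"chrom": "chr1", "pos": 100 + 50 * np.arange(S)}),
        individuals=list(design["bird_id"]),
        methylated=meth,
        total=total,
        missing=missing,
    )
    return matrix, design, FilterConfig(min_coverage=10, min_individuals_per_group=2)


TOY_GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t10000\t20000\t.\t+\t.\tID=gene1;Name=ABCD1
chr1\ttest\tmRNA\t10000\t20000\t.\t+\t.\tID=rna1;Parent=gene1
chr1\ttest\tfive_prime_UTR\t10000\t10400\t.\t+\t.\tID=utr5a;Parent=rna1
chr1\ttest\tthree_prime_UTR\t19500\t20000\t.\t+\t.\tID=utr3a;Parent=rna1
chr1\ttest\tgene\t60000\t70000\t.\t-\t.\tID=gene2;Name=LOC999
chr2\ttest\tgene\t5000\t9000\t.\t+\t.\tID=gene3;Name=EFG2
"""


def annotation_fixture_sites() -> pd.DataFrame:
    """Six sites crafted to hit each region class of :data:`TOY_GFF3`
    exactly once (UTRs ranked above the gene body)."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 5 + ["chr2"],
            "pos": [9800, 8500, 10300, 19600, 75000, 7000],
        }
    )
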