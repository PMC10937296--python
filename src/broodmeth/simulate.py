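"""Synthetic cross-foster / brood-size-manipulation data with known truth.

The generator emulates the study design the analysis assumes: paired
broods matched on hatch date, one enlarged and one reduced by a fixed
number of nestlings, partial cross-fostering (about half of each brood
reared away from its natal brood), treatment-dependent recapture after
nutritional independence, and a spread of days since fledging at
recapture.  Methylation counts are binomial on top of a logistic model
with nested brood random intercepts and, optionally, per-observation
Gaussian overdispersion on the logit scale; a truth table records each
site's planted interaction category and slopes for recovery tests.

One global seed drives independent sub-streams (design, phenotypes,
methylation) via ``numpy.random.SeedSequence`` spawning, so each stage
is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .methio import MethylationMatrix

__all__ = [
    "CATEGORIES",
    "SimulationConfig",
    "TraitParams",
    "PhenotypeParams",
    "category_slopes",
    "make_category_plan",
    "simulate_design",
    "simulate_phenotypes",
    "simulate_methylation",
    "write_simulation",
]

#: the six interaction categories: direction named after the enlarged group
CATEGORIES = [
    "opposing_enlarged_up",
    "opposing_enlarged_down",
    "enlarged_only_up",
    "enlarged_only_down",
    "reduced_only_up",
    "reduced_only_down",
]


def category_slopes(label: str, magnitude: float) -> tuple[float, float]:
    """(slope_enlarged, slope_reduced) in logit/day for a category label."""
    table = {
        "opposing_enlarged_up": (magnitude, -magnitude),
        "opposing_enlarged_down": (-magnitude, magnitude),
        "enlarged_only_up": (magnitude, 0.0),
        "enlarged_only_down": (-magnitude, 0.0),
        "reduced_only_up": (0.0, magnitude),
        "reduced_only_down": (0.0, -magnitude),
    }
    return table[label]


def make_category_plan(
    per_category: int, magnitude: float = 0.025
) -> dict[str, tuple[int, float, float]]:
    """Equal-sized plan over the six categories at a common |slope|."""
    return {
        lab: (per_category, *category_slopes(lab, magnitude)) for lab in CATEGORIES
    }


@dataclass
class SimulationConfig:
    """Free parameters of the generator.

    Defaults follow the study conditions: 16 cross-foster pairs
    (32 broods), +/-3-nestling manipulation, recapture probabilities
    30.51% (reduced) vs 16.43% (enlarged), recapture from 4 weeks
    post-fledging through the end of the season, and moderately
    overdispersed sequencing coverage around 30x.
    """

    n_cf_pairs: int = 16
    base_brood_size: int = 9
    manipulation: int = 3
    recapture_prob_reduced: float = 0.3051
    recapture_prob_enlarged: float = 0.1643
    days_range: tuple[int, int] = (28, 110)
    n_sites: int = 2000
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    re_sd_origin: float = 0.3
    re_sd_rearing: float = 0.3
    #: (weight, logit-mean, logit-sd) per mixture component of the
    #: baseline methylation distribution (hypo / hyper modes)
    baseline_logit_mix: tuple = ((0.55, -2.0, 1.0), (0.45, 1.6, 0.9))
    #: label -> (count, slope_enlarged, slope_reduced), logit/day
    category_plan: dict = field(default_factory=dict)
    obs_overdispersion_sd: float = 0.2
    #: anchor planted slopes at the mean recapture day (intercept
    #: reparametrisation only; keeps baselines mid-trajectory)
    center_days: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.recapture_prob_reduced, self.recapture_prob_enlarged):
            if not 0.0 <= p <= 1.0:
                raise ValueError("recapture probabilities must be in [0, 1]")
        if self.manipulation < 0:
            raise ValueError("manipulation must be >= 0")
        if self.n_cf_pairs < 1 or self.base_brood_size < 1 or self.n_sites < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.days_range
        if not lo < hi:
            raise ValueError("days_range.min must be < days_range.max")
        planned = sum(v[0] for v in self.category_plan.values())
        if planned > self.n_sites:
            raise ValueError("category_plan counts exceed n_sites")
        for lab in self.category_plan:
            if lab not in CATEGORIES:
                raise ValueError(f"unknown category {lab!r}")
        w = sum(c[0] for c in self.baseline_logit_mix)
        if abs(w - 1.0) > 1e-8:
            raise ValueError("baseline mixture weights must sum to 1")

    def to_file(self, path) -> None:
        path = Path(path)
        doc = asdict(self)
        doc["days_range"] = list(self.days_range)
        doc["baseline_logit_mix"] = [list(c) for c in self.baseline_logit_mix]
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc))

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        doc["days_range"] = tuple(doc["days_range"])
        doc["baseline_logit_mix"] = tuple(
            tuple(c) for c in doc["baseline_logit_mix"]
        )
        doc["category_plan"] = {
            k: tuple(v) for k, v in doc.get("category_plan", {}).items()
        }
        return cls(**doc)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

FLEDGE_AGE = 19  # days from hatching to fledging


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """One reduced and one enlarged brood per cross-foster pair.

    Returns one row per nestling alive at fledging, with natal and
    rearing broods (about half cross-fostered), treatment, hatch and
    fledge dates (April days), a Bernoulli recapture flag with
    treatment-specific probability and, for recaptured birds, days since
    fledging uniform over ``days_range`` and the implied test date.
    """
    rng = _rng(config.seed, 0)
    rows = []
    lo, hi = config.days_range
    for ip in range(config.n_cf_pairs):
        pair = f"CF{ip:02d}"
        hatch = int(np.clip(round(rng.normal(25.0, 4.0)), 10, 40))
        broods = [f"{pair}a", f"{pair}b"]
        enlarged_brood = broods[int(rng.integers(2))]
        for brood in broods:
            partner = broods[1] if brood == broods[0] else broods[0]
            treatment = "enlarged" if brood == enlarged_brood else "reduced"
            size = config.base_brood_size + (
                config.manipulation if treatment == "enlarged" else -config.manipulation
            )
            if size < 1:
                raise ValueError("brood size non-positive after manipulation")
            p_rec = (
                config.recapture_prob_enlarged
                if treatment == "enlarged"
                else config.recapture_prob_reduced
            )
            for k in range(size):
                origin = brood if k % 2 == 0 else partner
                recaptured = bool(rng.random() < p_rec)
                days = int(rng.integers(lo, hi + 1)) if recaptured else np.nan
                rows.append(
                    {
                        "bird_id": f"{brood}_{k:02d}",
                        "cf_pair": pair,
                        "treatment": treatment,
                        "brood_origin": origin,
                        "brood_rearing": brood,
                        "hatch_date": hatch,
                        "fledge_date": hatch + FLEDGE_AGE,
                        "recaptured": recaptured,
                        "days_since_fledging": days,
                    }
                )
    design = pd.DataFrame(rows)
    design["test_date"] = design["fledge_date"] + design["days_since_fledging"]
    design["origin_in_pair"] = design["cf_pair"] + ":" + design["brood_origin"]
    design["rearing_in_pair"] = design["cf_pair"] + ":" + design["brood_rearing"]
    for g in ("reduced", "enlarged"):
        n_rec = int(design.loc[design["treatment"] == g, "recaptured"].sum())
        if n_rec == 0:
            raise ValueError(f"zero recaptured individuals in treatment {g!r}")
    return design


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class TraitParams:
    """Linear-model effects for one simulated trait."""

    intercept: float = 0.0
    effect_enlarged: float = 0.0
    slope_days_reduced: float = 0.0
    slope_days_enlarged: float = 0.0
    hatch: float = 0.0
    hatch_sq: float = 0.0
    hatch_enlarged: float = 0.0
    hatch_sq_enlarged: float = 0.0
    noise_sd: float = 1.0
    re_sd_origin: float = 0.0
    re_sd_rearing: float = 0.0

    def validate(self) -> None:
        vals = list(asdict(self).values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite trait parameter")
        if self.noise_sd < 0 or self.re_sd_origin < 0 or self.re_sd_rearing < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class PhenotypeParams:
    """Per-trait effect sizes, defaulting to the observed study patterns:

    enlarged-brood birds lighter at day 14, post-fledging weight rising
    with days since fledging in both groups, P3 length and exploration
    rising with days only in the enlarged group (0.04 mm/day and
    0.21 score/day respectively), and later-hatched enlarged-brood birds
    showing stronger catch-up weight gain (hatch-date-squared term).
    """

    weight_day14: TraitParams = field(
        default_factory=lambda: TraitParams(
            intercept=18.5, effect_enlarged=-1.2, noise_sd=0.9,
            re_sd_origin=0.4, re_sd_rearing=0.4,
        )
    )
    weight_post: TraitParams = field(
        default_factory=lambda: TraitParams(
            intercept=16.0, slope_days_reduced=0.03, slope_days_enlarged=0.03,
            hatch_sq_enlarged=0.0005, noise_sd=0.8,
            re_sd_origin=0.3, re_sd_rearing=0.3,
        )
    )
    p3_length: TraitParams = field(
        default_factory=lambda: TraitParams(
            intercept=44.0, slope_days_reduced=-0.01, slope_days_enlarged=0.04,
            noise_sd=1.6, re_sd_origin=0.5, re_sd_rearing=0.5,
        )
    )
    exploration: TraitParams = field(
        default_factory=lambda: TraitParams(
            intercept=8.0, slope_days_reduced=0.002, slope_days_enlarged=0.21,
            noise_sd=5.5, re_sd_origin=1.0, re_sd_rearing=1.0,
        )
    )
    #: linear drift of raw movement counts with test date (removed again
    #: by the date correction of the exploration score)
    movement_date_trend: float = 0.1

    def validate(self) -> None:
        for t in (self.weight_day14, self.weight_post, self.p3_length, self.exploration):
            t.validate()
        if not np.isfinite(self.movement_date_trend):
            raise ValueError("non-finite movement_date_trend")


def _trait_values(
    design: pd.DataFrame, tp: TraitParams, rng: np.random.Generator
) -> np.ndarray:
    enl = (design["treatment"] == "enlarged").to_numpy(float)
    days = design["days_since_fledging"].to_numpy(float)
    hatch = design["hatch_date"].to_numpy(float)
    slope = np.where(enl > 0, tp.slope_days_enlarged, tp.slope_days_reduced)
    lin = (
        tp.intercept
        + tp.effect_enlarged * enl
        + slope * days
        + tp.hatch * hatch
        + tp.hatch_sq * hatch**2
        + enl * (tp.hatch_enlarged * hatch + tp.hatch_sq_enlarged * hatch**2)
    )
    for col, sd in (
        ("brood_origin", tp.re_sd_origin),
        ("brood_rearing", tp.re_sd_rearing),
    ):
        levels = pd.unique(design[col])
        u = dict(zip(levels, rng.normal(0.0, sd, size=len(levels)) if sd > 0 else np.zeros(len(levels))))
        lin = lin + design[col].map(u).to_numpy(float)
    if tp.noise_sd > 0:
        lin = lin + rng.normal(0.0, tp.noise_sd, size=len(design))
    return lin


def simulate_phenotypes(
    design: pd.DataFrame,
    phenotype_params: PhenotypeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes of the recaptured birds under the planted linear model.

    Raw movement counts carry a linear test-date trend on top of the
    exploration linear predictor, so the date correction of the
    exploration score has something real to remove.
    """
    params = phenotype_params or PhenotypeParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    rec = design[design["recaptured"]].reset_index(drop=True)
    out = rec[
        [
            "bird_id", "cf_pair", "treatment", "brood_origin", "brood_rearing",
            "origin_in_pair", "rearing_in_pair", "hatch_date",
            "days_since_fledging", "test_date",
        ]
    ].copy()
    out["weight_day14"] = _trait_values(rec, params.weight_day14, rng)
    out["weight_post"] = _trait_values(rec, params.weight_post, rng)
    out["delta_weight"] = out["weight_post"] - out["weight_day14"]
    out["p3_length"] = _trait_values(rec, params.p3_length, rng)
    score = _trait_values(rec, params.exploration, rng)
    date_c = out["test_date"] - out["test_date"].mean()
    out["movement_count"] = np.maximum(
        0, np.round(score + params.movement_date_trend * date_c)
    ).astype(int)
    out["exploration_score"] = score
    return out


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def _draw_baselines(config: SimulationConfig, size: int, rng) -> np.ndarray:
    comps = config.baseline_logit_mix
    w = np.array([c[0] for c in comps])
    idx = rng.choice(len(comps), size=size, p=w / w.sum())
    means = np.array([c[1] for c in comps])[idx]
    sds = np.array([c[2] for c in comps])[idx]
    return rng.normal(means, sds)


def simulate_methylation(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Binomial CpG counts for recaptured birds plus the truth table.

    Per site and individual the coverage is negative-binomial
    (``coverage_mean``, ``coverage_dispersion``); the methylated count is
    binomial with logit(p) = baseline + slope_treatment * days + u_origin
    + u_rearing (+ optional N(0, obs_overdispersion_sd) per observation).
    Cells with zero drawn coverage are missing.
    """
    rec = design[design["recaptured"]].reset_index(drop=True)
    for g in ("reduced", "enlarged"):
        if not (rec["treatment"] == g).any():
            raise ValueError(f"no recaptured individuals in treatment {g!r}")
    S = config.n_sites
    if S == 0 and not config.category_plan:
        raise ValueError("n_sites is 0 and category_plan is empty")
    rng = _rng(config.seed, 1)
    N = len(rec)
    days = rec["days_since_fledging"].to_numpy(float)
    if config.center_days:
        days = days - days.mean()
    enl = (rec["treatment"] == "enlarged").to_numpy()

    labels = []
    slopes_e, slopes_r = [], []
    for lab, (count, se, sr) in config.category_plan.items():
        labels += [lab] * count
        slopes_e += [se] * count
        slopes_r += [sr] * count
    n_null = S - len(labels)
    labels += ["null"] * n_null
    slopes_e += [0.0] * n_null
    slopes_r += [0.0] * n_null
    order = rng.permutation(S)
    labels = np.array(labels, dtype=object)[order]
    slopes_e = np.array(slopes_e)[order]
    slopes_r = np.array(slopes_r)[order]

    baselines = _draw_baselines(config, S, rng)
    positions = np.cumsum(rng.integers(50, 2000, size=S)) + 1
    sites = pd.DataFrame({"chrom": "chr1", "pos": positions.astype(int)})

    origin_levels, origin_codes = np.unique(rec["brood_origin"], return_inverse=True)
    rearing_levels, rearing_codes = np.unique(rec["brood_rearing"], return_inverse=True)
    u_o = rng.normal(0.0, config.re_sd_origin, size=(S, len(origin_levels)))
    u_r = rng.normal(0.0, config.re_sd_rearing, size=(S, len(rearing_levels)))

    slope_mat = np.where(enl[None, :], slopes_e[:, None], slopes_r[:, None])
    logit_p = (
        baselines[:, None]
        + slope_mat * days[None, :]
        + u_o[:, origin_codes]
        + u_r[:, rearing_codes]
    )
    if config.obs_overdispersion_sd > 0:
        logit_p = logit_p + rng.normal(
            0.0, config.obs_overdispersion_sd, size=(S, N)
        )
    p = 1.0 / (1.0 + np.exp(-np.clip(logit_p, -35, 35)))

    k = config.coverage_dispersion
    mu = config.coverage_mean
    total = rng.negative_binomial(k, k / (k + mu), size=(S, N))
    meth = rng.binomial(total, p)
    missing = total == 0

    matrix = MethylationMatrix(
        sites=sites,
        individuals=list(rec["bird_id"]),
        methylated=meth,
        total=total,
        missing=missing,
    )
    truth = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "category": labels,
            "slope_enlarged": slopes_e,
            "slope_reduced": slopes_r,
            "baseline_logit": baselines,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_simulation(
    outdir,
    design: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    matrix: MethylationMatrix | None = None,
    truth: pd.DataFrame | None = None,
    config: SimulationConfig | None = None,
    coverage_files: bool = False,
) -> None:
    """Write the simulated tables (TSV), matrix and optional per-sample
    Bismark-coverage-style files to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    if phenotypes is not None:
        phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    if matrix is not None:
        matrix.to_tsv(outdir / "methylation_matrix.tsv")
        if coverage_files:
            covdir = outdir / "coverage"
            covdir.mkdir(exist_ok=True)
            for j, ind in enumerate(matrix.individuals):
                obs = ~matrix.missing[:, j]
                m = matrix.methylated[obs, j]
                t = matrix.total[obs, j]
                pct = np.where(t > 0, 100.0 * m / np.maximum(t, 1), 0.0)
                df = pd.DataFrame(
                    {
                        "chrom": matrix.sites.loc[obs, "chrom"],
                        "start": matrix.sites.loc[obs, "pos"],
                        "end": matrix.sites.loc[obs, "pos"],
                        "pct": np.round(pct, 6),
                        "meth": m,
                        "unmeth": t - m,
                    }
                )
                df.to_csv(covdir / f"{ind}.cov", sep="\t", index=False, header=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if config is not None:
        config.to_file(outdir / "config.yaml")
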