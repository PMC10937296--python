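"""Biometric and behavioural stage: exploration scoring and phenotype LMMs.

Four post-fledging traits are analysed — weight, Δ weight (post-fledging
minus day-14 weight), third-primary (P3) length and exploration score —
each with a Gaussian ML mixed model containing brood-of-origin and
brood-of-rearing random intercepts (nested in cross-foster pair via
composite labels).  Fixed terms start from treatment, days since
fledging and their interaction (for Δ weight also hatch date, its square
and their treatment interactions) and are reduced by backward
elimination at p < 0.05 — interactions and higher-order terms first,
treatment never removed.  p-values come from type-III F tests with
Satterthwaite df; per-treatment slopes of days since fledging are
Bonferroni-corrected.  Exploration is the movement count in a 2-minute
novel-environment test, residualised on test date (recentred to the
cohort mean so the original scale is kept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodels import (
    FitResult,
    ModelSpec,
    fit_lmm_ml,
    slope_contrasts,
    type3_anova_satterthwaite,
)

__all__ = [
    "EliminationTrace",
    "compute_exploration_score",
    "backward_eliminate",
    "analyze_phenotypes",
    "spearman_check",
]

RANDOM_FACTORS = ["origin_in_pair", "rearing_in_pair"]

REQUIRED_COLUMNS = [
    "bird_id", "treatment", "cf_pair", "origin_in_pair", "rearing_in_pair",
    "hatch_date", "days_since_fledging", "test_date",
    "weight_day14", "weight_post", "p3_length", "movement_count",
]


@dataclass
class EliminationTrace:
    """Removal order of the backward elimination, with p at removal."""

    removed: list[tuple[str, float]] = field(default_factory=list)
    final_terms: list[str] = field(default_factory=list)


def compute_exploration_score(
    movement_count, test_date, cohort: pd.DataFrame | None = None
) -> np.ndarray:
    """Date-corrected exploration score.

    The score is the residual of the movement count regressed linearly on
    test date across the cohort, shifted back by the cohort grand mean so
    the original count scale is kept.  With a single distinct test date
    the correction is skipped with a warning and raw counts returned.
    """
    counts = np.asarray(movement_count, dtype=float)
    dates = np.asarray(test_date, dtype=float)
    if np.any(counts < 0):
        raise ValueError("movement counts must be >= 0")
    if len(np.unique(dates)) < 2:
        warnings.warn(
            "single distinct test date; date correction skipped", stacklevel=2
        )
        return counts.copy()
    slope, intercept = np.polyfit(dates, counts, 1)
    resid = counts - (intercept + slope * dates)
    return resid + counts.mean()


def _expanded_parts(term: str) -> set[str]:
    """Constituents of a term, including bases of squared factors."""
    parts = set(term.split(":"))
    for p in list(parts):
        if p.endswith("^2"):
            parts.add(p[:-2])
    return parts


def _removable(term: str, terms: list[str], always_keep: set[str]) -> bool:
    """A term is removable when it is not protected and no *other*
    retained term contains it (as interaction factor or squared base)."""
    if term in always_keep:
        return False
    for other in terms:
        if other == term:
            continue
        if term in _expanded_parts(other):
            return False
    return True


def backward_eliminate(
    initial_spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    always_keep: set[str] | frozenset[str] = frozenset({"treatment"}),
) -> tuple[FitResult, EliminationTrace]:
    """Backward elimination of non-significant fixed terms.

    At each step the model is refitted by ML, type-III Satterthwaite
    p-values computed, and the least significant removable term with
    p >= alpha deleted (interactions and squared terms before their main
    effects; ties in p broken by reverse model order).  Terms in
    ``always_keep`` are never removed.
    """
    always_keep = set(always_keep)
    terms = list(initial_spec.fixed_terms)
    trace = EliminationTrace()
    while True:
        spec = ModelSpec(
            response=initial_spec.response,
            fixed_terms=terms,
            random_intercepts=initial_spec.random_intercepts,
            family=initial_spec.family,
            coding=initial_spec.coding,
            ref_levels=initial_spec.ref_levels,
        )
        fit = fit_lmm_ml(spec, data)
        if not fit.converged:
            raise RuntimeError(
                f"non-convergence during elimination with terms {terms}; "
                f"trace so far: {trace.removed}"
            )
        anova = type3_anova_satterthwaite(fit).set_index("term")
        candidates = [
            (t, float(anova.loc[t, "p_value"]))
            for t in terms
            if _removable(t, terms, always_keep)
            and anova.loc[t, "p_value"] >= alpha
        ]
        if not candidates:
            trace.final_terms = list(terms)
            return fit, trace
        # worst p first; ties broken by reverse model order
        worst_p = max(p for _, p in candidates)
        victim = [t for t, p in candidates if p == worst_p][-1]
        trace.removed.append((victim, worst_p))
        terms.remove(victim)


TRAIT_MODELS = {
    "weight_post": ["treatment", "days_since_fledging",
                    "treatment:days_since_fledging"],
    "delta_weight": ["treatment", "hatch_date", "hatch_date^2",
                     "treatment:hatch_date", "treatment:hatch_date^2",
                     "days_since_fledging", "treatment:days_since_fledging"],
    "p3_length": ["treatment", "days_since_fledging",
                  "treatment:days_since_fledging"],
    "exploration_score": ["treatment", "days_since_fledging",
                          "treatment:days_since_fledging"],
}


def analyze_phenotypes(
    table: pd.DataFrame,
    alpha: float = 0.05,
    center_hatch: bool = False,
) -> dict:
    """Run the four phenotype analyses and return a results bundle.

    Each trait gets backward elimination (treatment always kept), the
    type-III Satterthwaite table of the final model and — when days
    since fledging is retained — Bonferroni-corrected per-treatment
    slopes.  ``center_hatch`` recentres hatch date before squaring
    (type-III tests with uncentred polynomials are sensitive to this).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    data = table.copy().reset_index(drop=True)
    if "exploration_score" not in data.columns:
        data["exploration_score"] = compute_exploration_score(
            data["movement_count"], data["test_date"]
        )
    if "delta_weight" not in data.columns:
        data["delta_weight"] = data["weight_post"] - data["weight_day14"]
    else:
        both = data[["weight_post", "weight_day14"]].notna().all(axis=1)
        if not np.allclose(
            data.loc[both, "delta_weight"],
            data.loc[both, "weight_post"] - data.loc[both, "weight_day14"],
        ):
            raise ValueError("delta_weight does not equal weight_post - weight_day14")
    if center_hatch:
        data["hatch_date"] = data["hatch_date"] - data["hatch_date"].mean()

    results: dict = {"traits": {}}
    for trait, terms in TRAIT_MODELS.items():
        spec = ModelSpec(
            response=trait,
            fixed_terms=terms,
            random_intercepts=RANDOM_FACTORS,
            family="gaussian_ml",
            coding="sum",
            ref_levels={"treatment": "reduced"},
        )
        fit, trace = backward_eliminate(spec, data, alpha=alpha)
        anova = type3_anova_satterthwaite(fit)
        slopes = None
        if any("days_since_fledging" in _expanded_parts(t) for t in trace.final_terms):
            slopes = slope_contrasts(
                fit, "days_since_fledging", "treatment", adjust="bonferroni"
            )
        results["traits"][trait] = {
            "fit": fit,
            "trace": trace,
            "anova": anova,
            "slopes": slopes,
        }
    results["spearman"] = {
        "days_vs_hatch": spearman_check(
            data["days_since_fledging"], data["hatch_date"]
        ),
        "days_vs_test_date": spearman_check(
            data["days_since_fledging"], data["test_date"]
        ),
    }
    return results


def spearman_check(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; p by t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman correlation undefined", stacklevel=2)
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def results_to_tables(results: dict) -> dict[str, pd.DataFrame]:
    """Flatten an :func:`analyze_phenotypes` bundle into per-model tables."""
    out = {}
    for trait, res in results["traits"].items():
        anova = res["anova"].copy()
        anova.insert(0, "trait", trait)
        out[f"{trait}_anova"] = anova
        rows = []
        if res["slopes"]:
            for s in res["slopes"]:
                rows.append(
                    {
                        "trait": trait, "treatment": s.group, "slope": s.slope,
                        "se": s.se, "t": s.statistic, "df": s.df,
                        "p_raw": s.p_raw, "p_bonferroni": s.p_adjusted,
                    }
                )
        out[f"{trait}_slopes"] = pd.DataFrame(rows)
    return out
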