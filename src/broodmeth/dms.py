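"""Per-CpG screening for days-dependent differential methylation.

For every CpG two binomial logit GLMMs are fitted — a null model with
treatment only and a full model adding days since fledging and the
treatment x days interaction, both with brood-of-origin and
brood-of-rearing random intercepts (nested in cross-foster pair via
composite labels) — and compared by a 2-df likelihood-ratio test.
Sites whose fits error are omitted (singular fits are kept); sites whose
Pearson dispersion falls outside the 95% highest-density interval of the
dispersion distribution are removed as overdispersed; the remaining LRT
p-values are Benjamini-Hochberg corrected; significant sites get
post-hoc per-treatment slopes (BH across all slope tests jointly by
default) and a six-way interaction-category label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methio import MethylationMatrix
from .mixedmodels import (
    ConvergenceError,
    ModelSpec,
    SlopeContrast,
    fit_binomial_glmm_laplace,
    likelihood_ratio_test,
    pearson_dispersion,
    slope_contrasts,
)

__all__ = [
    "HDIConfig",
    "bh_adjust",
    "hdi_filter",
    "run_per_site_models",
    "posthoc_slopes",
    "classify_interaction",
    "run_dms_pipeline",
    "evaluate_recovery",
]

RANDOM_FACTORS = ["origin_in_pair", "rearing_in_pair"]


@dataclass
class HDIConfig:
    """Mass of the highest-density interval used to screen dispersions."""

    mass: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.mass < 1.0:
            raise ValueError("HDI mass must be in (0, 1)")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    NaN p-values propagate as NaN and are excluded from the number of
    tests m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must be in [0, 1]")
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1.0)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def hdi_filter(dispersions, hdi_config: HDIConfig | None = None):
    """Keep values inside the shortest interval holding the given mass.

    The interval is the shortest contiguous window of the sorted values
    containing ceil(mass * N) of them; ties go to the lowest-start
    window.  Returns (keep mask, (low, high)).  Requires at least 20
    finite values for a stable interval.
    """
    cfg = hdi_config or HDIConfig()
    d = np.asarray(dispersions, dtype=float)
    finite = d[np.isfinite(d)]
    if finite.size < 20:
        raise ValueError(
            f"HDI filter needs >= 20 finite values, got {finite.size}"
        )
    s = np.sort(finite)
    k = math.ceil(cfg.mass * s.size)
    widths = s[k - 1 :] - s[: s.size - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    low, high = float(s[i]), float(s[i + k - 1])
    keep = np.isfinite(d) & (d >= low) & (d <= high)
    return keep, (low, high)


# ---------------------------------------------------------------------------
# per-site fitting
# ---------------------------------------------------------------------------

_NULL_SPEC = dict(fixed_terms=["treatment"])
_FULL_SPEC = dict(fixed_terms=["treatment", "days_since_fledging",
                               "treatment:days_since_fledging"])


def _site_frame(matrix: MethylationMatrix, design: pd.DataFrame, i: int):
    obs = ~matrix.missing[i] & (matrix.total[i] >= 1)
    ids = [ind for ind, o in zip(matrix.individuals, obs) if o]
    d = design.set_index("bird_id").loc[ids].reset_index()
    d["meth"] = matrix.methylated[i, obs]
    d["total"] = matrix.total[i, obs]
    return d


def _fit_one_site(frame: pd.DataFrame, min_obs_per_treatment: int = 2):
    """Fit null and full model for one site; returns a result dict."""
    res = {
        "fit_status": "ok", "reason": "",
        "loglik_null": np.nan, "loglik_full": np.nan,
        "lrt_stat": np.nan, "lrt_df": 2, "lrt_p": np.nan, "dispersion": np.nan,
        "slope_reduced": np.nan, "se_reduced": np.nan, "p_reduced_raw": np.nan,
        "slope_enlarged": np.nan, "se_enlarged": np.nan, "p_enlarged_raw": np.nan,
    }
    counts = frame["treatment"].value_counts()
    for g in ("reduced", "enlarged"):
        if counts.get(g, 0) < min_obs_per_treatment:
            res["fit_status"] = "omitted_error"
            res["reason"] = f"fewer than {min_obs_per_treatment} observations in {g}"
            return res
    if (frame["meth"] == 0).all() or (frame["meth"] == frame["total"]).all():
        res["fit_status"] = "omitted_error"
        res["reason"] = "complete separation"
        return res
    common = dict(
        response=("meth", "total"),
        random_intercepts=RANDOM_FACTORS,
        family="binomial_logit",
        coding="treatment",
        ref_levels={"treatment": "reduced"},
    )
    try:
        fit_null = fit_binomial_glmm_laplace(
            ModelSpec(**common, **_NULL_SPEC), frame
        )
        warm = np.log(
            np.sqrt(np.maximum(list(fit_null.var_components.values()), 1e-12))
        )
        fit_full = fit_binomial_glmm_laplace(
            ModelSpec(**common, **_FULL_SPEC), frame, start_log_sigmas=warm
        )
        if not (fit_null.converged and fit_full.converged):
            raise ConvergenceError("non-convergence")
        lrt = likelihood_ratio_test(fit_null, fit_full)
        dispersion = pearson_dispersion(fit_full)
        contrasts = slope_contrasts(fit_full, "days_since_fledging", "treatment")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        res["fit_status"] = "omitted_error"
        res["reason"] = str(exc)
        return res
    res["fit_status"] = (
        "singular_ok" if (fit_null.singular or fit_full.singular) else "ok"
    )
    res["loglik_null"] = fit_null.loglik
    res["loglik_full"] = fit_full.loglik
    res["lrt_stat"] = lrt.statistic
    res["lrt_df"] = lrt.df
    res["lrt_p"] = lrt.p_value
    res["dispersion"] = dispersion
    for sc in contrasts:
        suffix = "enlarged" if sc.group == "enlarged" else "reduced"
        res[f"slope_{suffix}"] = sc.slope
        res[f"se_{suffix}"] = sc.se
        res[f"p_{suffix}_raw"] = sc.p_raw
    return res


def run_per_site_models(
    matrix: MethylationMatrix,
    design: pd.DataFrame,
    min_obs_per_treatment: int = 2,
    progress: bool = False,
) -> pd.DataFrame:
    """Null/full binomial GLMMs, LRT, dispersion and raw slopes per site."""
    rows = []
    it = range(matrix.n_sites)
    if progress:
        from tqdm import tqdm  # pragma: no cover

        it = tqdm(it, desc="per-site GLMMs")  # pragma: no cover
    for i in it:
        frame = _site_frame(matrix, design, i)
        res = _fit_one_site(frame, min_obs_per_treatment)
        res["chrom"] = matrix.sites["chrom"].iloc[i]
        res["pos"] = int(matrix.sites["pos"].iloc[i])
        rows.append(res)
    cols = ["chrom", "pos"] + [c for c in rows[0] if c not in ("chrom", "pos")]
    return pd.DataFrame(rows)[cols]


def posthoc_slopes(
    site_table: pd.DataFrame,
    significant_mask: np.ndarray,
    adjust: str = "BH",
    pool: str = "joint",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """FDR-adjust the per-treatment slope tests of the significant sites.

    ``pool="joint"`` corrects across all 2 x n_significant tests at once;
    ``pool="per_site"`` corrects the two tests within each site.
    Returns the table with ``p_*_adj`` and ``sig_*`` columns added.
    """
    if adjust != "BH":
        raise ValueError("post-hoc slopes use BH adjustment")
    out = site_table.copy()
    for side in ("reduced", "enlarged"):
        out[f"p_{side}_adj"] = np.nan
        out[f"sig_{side}"] = False
    sig = np.asarray(significant_mask, dtype=bool)
    if not sig.any():
        return out
    pr = out.loc[sig, "p_reduced_raw"].to_numpy()
    pe = out.loc[sig, "p_enlarged_raw"].to_numpy()
    if pool == "joint":
        q = bh_adjust(np.concatenate([pr, pe]))
        qr, qe = q[: len(pr)], q[len(pr) :]
    elif pool == "per_site":
        qr = np.empty(len(pr))
        qe = np.empty(len(pe))
        for i, (a, b) in enumerate(zip(pr, pe)):
            qr[i], qe[i] = bh_adjust([a, b])
    else:
        raise ValueError(f"unknown pool {pool!r}")
    out.loc[sig, "p_reduced_adj"] = qr
    out.loc[sig, "p_enlarged_adj"] = qe
    out.loc[sig, "sig_reduced"] = qr <= alpha
    out.loc[sig, "sig_enlarged"] = qe <= alpha
    return out


def classify_interaction(slope_reduced, slope_enlarged) -> str:
    """Six-way interaction category from two post-FDR slope contrasts.

    Accepts :class:`SlopeContrast` objects or ``(slope, significant)``
    pairs.  Both slopes significant with opposite signs give the
    "opposing" categories (named after the enlarged-group direction);
    exactly one significant slope gives the corresponding "only"
    categories; anything else — both flat, or both significant with the
    same sign — is unclassified.
    """

    def unpack(s):
        if isinstance(s, SlopeContrast):
            return s.slope, s.significant
        return float(s[0]), bool(s[1])

    br, sr = unpack(slope_reduced)
    be, se = unpack(slope_enlarged)
    if sr and se:
        if be > 0 > br:
            return "opposing_enlarged_up"
        if be < 0 < br:
            return "opposing_enlarged_down"
        return "unclassified"
    if se and not sr:
        return "enlarged_only_up" if be > 0 else "enlarged_only_down"
    if sr and not se:
        return "reduced_only_up" if br > 0 else "reduced_only_down"
    return "unclassified"


def run_dms_pipeline(
    matrix: MethylationMatrix,
    design: pd.DataFrame,
    q_threshold: float = 0.05,
    hdi_config: HDIConfig | None = None,
    fdr_universe: str = "tested",
    posthoc_pool: str = "joint",
    min_obs_per_treatment: int = 2,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full screening pipeline: fits, HDI, FDR, post-hoc slopes, categories.

    ``fdr_universe="tested"`` applies BH among the sites surviving the
    HDI dispersion screen (the default); ``"all_filtered"`` computes the
    correction over all successfully fitted sites and then restricts the
    rejections to the HDI-kept set.
    """
    if fdr_universe not in ("tested", "all_filtered"):
        raise ValueError(f"unknown fdr_universe {fdr_universe!r}")
    table = run_per_site_models(matrix, design, min_obs_per_treatment, progress)
    ok = table["fit_status"].isin(["ok", "singular_ok"]).to_numpy()
    table["kept_by_hdi"] = False
    keep, (lo, hi) = hdi_filter(
        np.where(ok, table["dispersion"].to_numpy(), np.nan), hdi_config
    )
    table.loc[keep, "kept_by_hdi"] = True
    tested = ok & keep
    table["q_value"] = np.nan
    if fdr_universe == "tested":
        table.loc[tested, "q_value"] = bh_adjust(table.loc[tested, "lrt_p"])
    else:
        table.loc[ok, "q_value"] = bh_adjust(table.loc[ok, "lrt_p"])
    significant = tested & (table["q_value"].to_numpy() <= q_threshold)
    table = posthoc_slopes(table, significant, pool=posthoc_pool)
    table["significant"] = significant
    table["category"] = None
    for i in np.flatnonzero(significant):
        table.loc[i, "category"] = classify_interaction(
            (table.loc[i, "slope_reduced"], table.loc[i, "sig_reduced"]),
            (table.loc[i, "slope_enlarged"], table.loc[i, "sig_enlarged"]),
        )
    cat_counts = (
        table.loc[significant, "category"].value_counts().to_dict()
    )
    summary = {
        "n_sites_input": int(matrix.n_sites),
        "n_fit_ok": int(ok.sum()),
        "n_omitted": int((~ok).sum()),
        "n_hdi_removed": int((ok & ~keep).sum()),
        "n_tested": int(tested.sum()),
        "n_significant": int(significant.sum()),
        "hdi_interval": [lo, hi],
        "q_threshold": q_threshold,
        "fdr_universe": fdr_universe,
        "posthoc_pool": posthoc_pool,
        "category_counts": cat_counts,
    }
    return table, summary


def evaluate_recovery(dms_table: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare pipeline output with the generator's truth table.

    Sensitivity is the fraction of planted (non-null) sites called
    significant; category accuracy is the fraction of detected planted
    sites whose assigned category matches the planted one; FDP is the
    fraction of significant calls that are truly null.
    """
    merged = dms_table.merge(
        truth[["chrom", "pos", "category"]].rename(columns={"category": "true_category"}),
        on=["chrom", "pos"],
        how="left",
    )
    planted = merged["true_category"] != "null"
    sig = merged["significant"].fillna(False).to_numpy(bool)
    n_planted = int(planted.sum())
    detected = sig & planted.to_numpy()
    sensitivity = float(detected.sum() / n_planted) if n_planted else np.nan
    correct = (
        merged.loc[detected, "category"] == merged.loc[detected, "true_category"]
    )
    accuracy = float(correct.mean()) if detected.any() else np.nan
    n_sig = int(sig.sum())
    fdp = float((sig & ~planted.to_numpy()).sum() / n_sig) if n_sig else 0.0
    return {
        "n_planted": n_planted,
        "n_significant": n_sig,
        "sensitivity": sensitivity,
        "category_accuracy": accuracy,
        "fdp": fdp,
    }
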