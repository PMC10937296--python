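"""Reading, destranding, assembling and filtering CpG methylation counts.

Input dialects are Bismark-style per-sample text files (coverage files or
cytosine reports, plain or gzipped) or a single wide TSV matrix.  Sites
are CpG dinucleotides anchored at the plus-strand cytosine, 1-based.
Counts from the complementary minus-strand cytosine (position + 1) are
merged into the anchored site.

Filtering applies four rules in fixed order, with a telescoping report:

1. coverage — cells with total < 10x or above the sample's 99.9th
   coverage percentile become missing; sites left with no data drop out;
2. group presence — a site must be covered in at least 15 individuals in
   *both* treatment groups;
3. mean methylation — sites with mean methylated fraction across
   individuals < 0.05 or > 0.95 drop out.

All inequalities are strict, matching the stated rules.  Filtering never
alters retained counts; cells only ever become missing.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "MethylationMatrix",
    "FilterConfig",
    "read_sample_counts",
    "merge_complementary_strands",
    "assemble_matrix",
    "filter_by_coverage",
    "filter_by_group_presence",
    "filter_by_mean_methylation",
    "run_filter_pipeline",
]

RECORD_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth"]


class CpGSite(NamedTuple):
    """A merged CpG dinucleotide, anchored at the plus-strand cytosine."""

    chrom: str
    pos: int  # 1-based
    context: str = "CpG"


@dataclass
class MethylationMatrix:
    """Site x individual methylated/total counts with explicit missingness.

    ``sites`` is a DataFrame with columns ``chrom`` and ``pos`` (1-based
    plus-strand anchor), one row per site, aligned with the first axis of
    the count arrays.  Missing cells are flagged, never zero-filled, so
    an observed total of zero methylated reads stays distinguishable
    from "not covered".
    """

    sites: pd.DataFrame
    individuals: list[str]
    methylated: np.ndarray
    total: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        S, N = len(self.sites), len(self.individuals)
        for name, arr in (
            ("methylated", self.methylated),
            ("total", self.total),
            ("missing", self.missing),
        ):
            if arr.shape != (S, N):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(S, N)}")
        obs = ~self.missing
        if np.any(self.total[obs] < 0) or np.any(self.methylated[obs] < 0):
            raise ValueError("negative counts")
        if np.any(self.methylated[obs] > self.total[obs]):
            raise ValueError("methylated exceeds total")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate sites")
        if len(set(self.individuals)) != N:
            raise ValueError("duplicate individuals")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_tuples(self) -> list[CpGSite]:
        return [CpGSite(c, int(p)) for c, p in zip(self.sites["chrom"], self.sites["pos"])]

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            sites=self.sites.reset_index(drop=True).copy(),
            individuals=list(self.individuals),
            methylated=self.methylated.copy(),
            total=self.total.copy(),
            missing=self.missing.copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylationMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            individuals=list(self.individuals),
            methylated=self.methylated[mask],
            total=self.total[mask],
            missing=self.missing[mask],
        )

    def mean_methylation(self) -> np.ndarray:
        """Per-site mean of per-individual methylated fractions (NaN if empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(
                self.missing | (self.total == 0), np.nan, self.methylated / np.maximum(self.total, 1)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(frac, axis=1)

    # ---- serialisation -------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write as a wide TSV (chrom, pos, then <id>.meth / <id>.total)."""
        out = self.sites[["chrom", "pos"]].copy()
        for j, ind in enumerate(self.individuals):
            meth = self.methylated[:, j].astype(float)
            tot = self.total[:, j].astype(float)
            meth[self.missing[:, j]] = np.nan
            tot[self.missing[:, j]] = np.nan
            out[f"{ind}.meth"] = meth
            out[f"{ind}.total"] = tot
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t")
        inds = [c[:-5] for c in df.columns if c.endswith(".meth")]
        meth = df[[f"{i}.meth" for i in inds]].to_numpy(float)
        tot = df[[f"{i}.total" for i in inds]].to_numpy(float)
        missing = ~np.isfinite(tot)
        meth = np.nan_to_num(meth).astype(int)
        tot = np.nan_to_num(tot).astype(int)
        return cls(
            sites=df[["chrom", "pos"]].copy(),
            individuals=inds,
            methylated=meth,
            total=tot,
            missing=missing,
        )

    def to_bed(self, path) -> None:
        """Retained sites as BED (0-based half-open CpG dinucleotides)."""
        bed = pd.DataFrame(
            {
                "chrom": self.sites["chrom"],
                "start": self.sites["pos"] - 1,
                "end": self.sites["pos"] + 1,
                "name": [f"CpG_{c}_{p}" for c, p in zip(self.sites["chrom"], self.sites["pos"])],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class FilterConfig:
    """Thresholds for the four-stage site/cell filter."""

    min_coverage: int = 10
    coverage_percentile_cut: float = 99.9
    min_individuals_per_group: int = 15
    mean_meth_low: float = 0.05
    mean_meth_high: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.mean_meth_low < self.mean_meth_high < 1):
            raise ValueError("require 0 < mean_meth_low < mean_meth_high < 1")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.coverage_percentile_cut <= 100):
            raise ValueError("coverage percentile must be in (0, 100]")
        if self.min_individuals_per_group < 0:
            raise ValueError("min_individuals_per_group must be >= 0")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sample_counts(path, format: str = "coverage") -> pd.DataFrame:
    """Read one sample's CpG records.

    ``format`` is ``"coverage"`` (Bismark coverage: chrom, start, end,
    %methylation, count_methylated, count_unmethylated; no strand) or
    ``"cytosine_report"`` (chrom, pos, strand, count_methylated,
    count_unmethylated, context[, trinucleotide]; non-CpG contexts are
    skipped since methylation calling is CpG-only).
    """
    if format not in ("coverage", "cytosine_report"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if format == "coverage":
                    chrom, start = fields[0], int(fields[1])
                    meth, unmeth = int(fields[4]), int(fields[5])
                    strand = None
                    pos = start
                else:
                    chrom, pos = fields[0], int(fields[1])
                    strand = fields[2]
                    meth, unmeth = int(fields[3]), int(fields[4])
                    context = fields[5] if len(fields) > 5 else "CpG"
                    if context != "CpG":
                        continue
                    if strand not in ("+", "-"):
                        raise ValueError(f"bad strand {strand!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}: negative counts at line {lineno}")
            rows.append((chrom, pos, strand, meth, unmeth))
    if not rows:
        warnings.warn(f"{path}: no records read", stacklevel=2)
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def merge_complementary_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Merge plus/minus-strand cytosines of each CpG into one record.

    A plus-strand C at position p and the complementary minus-strand C at
    p+1 are summed into a single site anchored at p.  A lone minus-strand
    record at p+1 is re-anchored to p.  Records without strand annotation
    are assumed destranded and pass through unchanged.
    """
    if records.empty or records["strand"].isna().all():
        return records.copy()
    rec = records.copy()
    minus = rec["strand"] == "-"
    rec.loc[minus, "pos"] = rec.loc[minus, "pos"] - 1
    plus = rec[~minus]
    if plus.duplicated(["chrom", "pos"]).any():
        dup = plus[plus.duplicated(["chrom", "pos"], keep=False)].iloc[0]
        raise ValueError(
            f"duplicate plus-strand record at {dup['chrom']}:{dup['pos']}"
        )
    merged = (
        rec.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    merged["strand"] = None
    return merged[["chrom", "pos", "strand", "meth", "unmeth"]]


def assemble_matrix(samples: list[tuple[str, pd.DataFrame]]) -> MethylationMatrix:
    """Union of destranded per-sample records into a site x individual matrix.

    Cells absent in a sample are flagged missing, never zero-filled.
    """
    if not samples:
        raise ValueError("at least one sample required")
    ids = [s for s, _ in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample id")
    keys = pd.concat(
        [df[["chrom", "pos"]] for _, df in samples if not df.empty],
        ignore_index=True,
    ).drop_duplicates()
    keys = keys.sort_values(["chrom", "pos"]).reset_index(drop=True)
    S, N = len(keys), len(ids)
    meth = np.zeros((S, N), dtype=int)
    tot = np.zeros((S, N), dtype=int)
    missing = np.ones((S, N), dtype=bool)
    index = pd.MultiIndex.from_frame(keys)
    for j, (_, df) in enumerate(samples):
        if df.empty:
            continue
        loc = index.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos"]]))
        meth[loc, j] = df["meth"].to_numpy()
        tot[loc, j] = df["meth"].to_numpy() + df["unmeth"].to_numpy()
        missing[loc, j] = False
    return MethylationMatrix(
        sites=keys, individuals=ids, methylated=meth, total=tot, missing=missing
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_by_coverage(matrix: MethylationMatrix, config: FilterConfig) -> MethylationMatrix:
    """Mask low/high-coverage cells; drop sites left without data.

    The high-coverage cut is each sample's own ``coverage_percentile_cut``
    percentile (linear interpolation over that sample's non-missing
    totals); both cuts are strict inequalities.
    """
    out = matrix.copy()
    for j in range(len(out.individuals)):
        obs = ~out.missing[:, j]
        if not obs.any():
            continue
        totals = out.total[obs, j]
        cut = np.percentile(totals, config.coverage_percentile_cut)
        bad = obs & (
            (out.total[:, j] < config.min_coverage) | (out.total[:, j] > cut)
        )
        out.missing[bad, j] = True
    keep = ~out.missing.all(axis=1)
    return out.subset_sites(keep)


def filter_by_group_presence(
    matrix: MethylationMatrix, design: pd.DataFrame, config: FilterConfig
) -> MethylationMatrix:
    """Keep sites covered in >= min individuals in both treatment groups."""
    tr = design.set_index("bird_id")["treatment"]
    missing_ids = [i for i in matrix.individuals if i not in tr.index]
    if missing_ids:
        raise ValueError(f"individuals absent from design: {missing_ids}")
    groups = tr.loc[matrix.individuals].to_numpy()
    keep = np.ones(matrix.n_sites, dtype=bool)
    for g in ("reduced", "enlarged"):
        cols = groups == g
        n_obs = (~matrix.missing[:, cols]).sum(axis=1)
        keep &= n_obs >= config.min_individuals_per_group
    return matrix.subset_sites(keep)


def filter_by_mean_methylation(
    matrix: MethylationMatrix, config: FilterConfig
) -> MethylationMatrix:
    """Drop sites with extreme mean methylation (strict bounds).

    Sites with all cells missing are also dropped (their mean is
    undefined); the pipeline report counts them separately.
    """
    mean = matrix.mean_methylation()
    keep = (
        np.isfinite(mean)
        & (mean >= config.mean_meth_low)
        & (mean <= config.mean_meth_high)
    )
    return matrix.subset_sites(keep)


def run_filter_pipeline(
    matrix: MethylationMatrix, design: pd.DataFrame, config: FilterConfig
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Apply coverage, group-presence and mean-methylation filters in order.

    Returns the filtered matrix and a telescoping report with one row per
    stage (sites in, removed, out).
    """
    stages = []
    current = matrix
    n0 = current.n_sites
    after_cov = filter_by_coverage(current, config)
    stages.append(("coverage", n0, n0 - after_cov.n_sites, after_cov.n_sites, 0))
    after_grp = filter_by_group_presence(after_cov, design, config)
    stages.append(
        (
            "group_presence",
            after_cov.n_sites,
            after_cov.n_sites - after_grp.n_sites,
            after_grp.n_sites,
            0,
        )
    )
    n_all_missing = int(after_grp.missing.all(axis=1).sum())
    after_mean = filter_by_mean_methylation(after_grp, config)
    stages.append(
        (
            "mean_methylation",
            after_grp.n_sites,
            after_grp.n_sites - after_mean.n_sites,
            after_mean.n_sites,
            n_all_missing,
        )
    )
    report = pd.DataFrame(
        stages,
        columns=["stage", "sites_in", "sites_removed", "sites_out", "removed_all_missing"],
    )
    return after_mean, report
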