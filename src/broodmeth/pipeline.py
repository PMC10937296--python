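"""End-to-end pipeline: filter -> DMS screen -> annotate -> phenotypes.

A :class:`PipelineConfig` collects paths and stage options; the run
writes every stage's table, a machine-readable ``summary.json`` with all
telescoping counts, and a log recording the seed and a hash of the
configuration.  The summary content is a pure function of inputs and
configuration (no timestamps), so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationConfig, annotate_table, load_gene_models
from .dms import HDIConfig, run_dms_pipeline
from .methio import FilterConfig, MethylationMatrix, run_filter_pipeline
from .phenotypes import analyze_phenotypes, results_to_tables

logger = logging.getLogger("broodmeth")

__all__ = ["PipelineConfig", "run_full_pipeline", "plot_manhattan"]


@dataclass
class PipelineConfig:
    """Paths and options for a full run; paths may be None to skip stages."""

    matrix: str | None = None
    design: str | None = None
    phenotypes: str | None = None
    gff3: str | None = None
    outdir: str = "broodmeth_run"
    filter: FilterConfig = field(default_factory=FilterConfig)
    hdi: HDIConfig = field(default_factory=HDIConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    q_threshold: float = 0.05
    fdr_universe: str = "tested"
    posthoc_pool: str = "joint"
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("filter", FilterConfig),
            ("hdi", HDIConfig),
            ("annotation", AnnotationConfig),
        ):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = sub(**doc[key])
        return cls(**doc)

    def digest(self) -> str:
        doc = asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"{what} path not configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def plot_manhattan(dms_table: pd.DataFrame, path) -> None:
    """Diagnostic Manhattan-style plot of -log10 LRT p by genome position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = dms_table.dropna(subset=["lrt_p"])
    fig, ax = plt.subplots(figsize=(8, 3))
    colors = tab["significant"].map({True: "tab:blue", False: "0.6"})
    ax.scatter(tab["pos"], -np.log10(np.maximum(tab["lrt_p"], 1e-300)),
               s=6, c=colors)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p (treatment x days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Execute filter -> dms -> annotate (-> phenotypes) and write outputs.

    Any stage failure aborts with the stage name; outputs written so far
    are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {
        "broodmeth_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    logger.info("run start: config hash %s seed %d", config.digest(), config.seed)
    stage = "load"
    try:
        matrix = MethylationMatrix.from_tsv(_require(config.matrix, "matrix"))
        design = pd.read_csv(_require(config.design, "design"), sep="\t")

        stage = "filter"
        filtered, report = run_filter_pipeline(matrix, design, config.filter)
        report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        filtered.to_tsv(outdir / "filtered_matrix.tsv")
        filtered.to_bed(outdir / "retained_sites.bed")
        summary["stages"]["filter"] = {
            "report": report.to_dict(orient="records"),
            "n_rows_filtered_matrix": int(filtered.n_sites),
        }
        logger.info("filter: %d -> %d sites", matrix.n_sites, filtered.n_sites)

        stage = "dms"
        dms_table, dms_summary = run_dms_pipeline(
            filtered,
            design,
            q_threshold=config.q_threshold,
            hdi_config=config.hdi,
            fdr_universe=config.fdr_universe,
            posthoc_pool=config.posthoc_pool,
        )
        sig = dms_table[dms_table["significant"]]
        summary["stages"]["dms"] = dict(
            dms_summary, n_rows_dms_table=int(len(dms_table))
        )
        logger.info("dms: %d tested, %d significant",
                    dms_summary["n_tested"], dms_summary["n_significant"])

        stage = "annotate"
        if config.gff3 is not None:
            index = load_gene_models(_require(config.gff3, "GFF3"), config.annotation)
            dms_table, counts = annotate_table(dms_table, index, config.annotation)
            summary["stages"]["annotate"] = dict(
                counts, n_rows_annotated_table=int(len(dms_table))
            )
        dms_table.to_csv(outdir / "dms_table.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "chrom": sig["chrom"],
                "start": sig["pos"] - 1,
                "end": sig["pos"] + 1,
                "name": sig.get("category", pd.Series(dtype=object)),
            }
        ).to_csv(outdir / "significant_sites.bed", sep="\t", index=False, header=False)
        if config.make_plots:
            plot_manhattan(dms_table, outdir / "manhattan.png")

        stage = "phenotypes"
        if config.phenotypes is not None:
            pheno = pd.read_csv(_require(config.phenotypes, "phenotypes"), sep="\t")
            results = analyze_phenotypes(pheno)
            tables = results_to_tables(results)
            pheno_summary: dict = {"n_rows_phenotypes": int(len(pheno)), "traits": {}}
            for name, tab in tables.items():
                tab.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            for trait, res in results["traits"].items():
                pheno_summary["traits"][trait] = {
                    "final_terms": res["trace"].final_terms,
                    "removed": res["trace"].removed,
                    "anova": res["anova"].to_dict(orient="records"),
                }
            pheno_summary["spearman"] = {
                k: list(v) for k, v in results["spearman"].items()
            }
            summary["stages"]["phenotypes"] = pheno_summary

        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
        )
        logger.info("run complete")
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
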