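"""Priority-ordered, strand-aware gene-region annotation of CpG sites.

Each CpG is assigned to one of: TSS region (300 bp upstream to 50 bp
downstream of the transcription start), promoter (2000 bp upstream to
200 bp downstream), gene body, 5'/3' UTR, or the 10 kb flanks adjacent
to the gene body; otherwise it is intergenic.  When a site overlaps
several regions the highest-priority class wins (TSS > promoter >
gene body > 5'UTR > 3'UTR > flank by default — note the UTR classes are
then unreachable since UTRs lie inside gene bodies; set
``utr_above_gene_body`` to rank them above).  Within the winning class,
ties between genes are broken by preferring characterised (non-LOC)
genes and then the shortest distance to the gene body.  Flank hits are
reported as upstream or downstream relative to the winning gene's
strand.

Coordinates are 1-based inclusive internally; upstream of a minus-strand
gene lies at higher coordinates.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methio import CpGSite

__all__ = [
    "AnnotationConfig",
    "GeneFeature",
    "GeneFeatureIndex",
    "AnnotationResult",
    "load_gene_models",
    "annotate_site",
    "annotate_table",
]

DEFAULT_PRIORITY = [
    "TSS",
    "promoter",
    "gene_body",
    "five_prime_UTR",
    "three_prime_UTR",
    "flank",
]


@dataclass
class AnnotationConfig:
    """Window sizes (bp) and class priority for region assignment."""

    tss_upstream: int = 300
    tss_downstream: int = 50
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    flank: int = 10000
    utr_above_gene_body: bool = False

    def __post_init__(self) -> None:
        for name in ("tss_upstream", "tss_downstream", "promoter_upstream",
                     "promoter_downstream", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def priority(self) -> list[str]:
        if self.utr_above_gene_body:
            return ["TSS", "promoter", "five_prime_UTR", "three_prime_UTR",
                    "gene_body", "flank"]
        return list(DEFAULT_PRIORITY)


@dataclass
class GeneFeature:
    """One gene with its body, UTRs and strand-aware derived windows."""

    gene_id: str
    name: str
    chrom: str
    start: int  # 1-based inclusive gene body
    end: int
    strand: str
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def characterized(self) -> bool:
        return not self.name.upper().startswith("LOC")

    @property
    def tss(self) -> int:
        """Strand-aware 5' end of the gene body."""
        return self.start if self.strand == "+" else self.end

    def windows(self, config: AnnotationConfig) -> list[tuple[str, int, int, str]]:
        """(class, start, end, side) intervals, 1-based inclusive, clipped at 1."""
        out = []
        t = self.tss
        if self.strand == "+":
            out.append(("TSS", t - config.tss_upstream, t + config.tss_downstream, ""))
            out.append(("promoter", t - config.promoter_upstream,
                        t + config.promoter_downstream, ""))
            out.append(("flank", self.start - config.flank, self.start - 1, "upstream"))
            out.append(("flank", self.end + 1, self.end + config.flank, "downstream"))
        else:
            out.append(("TSS", t - config.tss_downstream, t + config.tss_upstream, ""))
            out.append(("promoter", t - config.promoter_downstream,
                        t + config.promoter_upstream, ""))
            out.append(("flank", self.end + 1, self.end + config.flank, "upstream"))
            out.append(("flank", self.start - config.flank, self.start - 1, "downstream"))
        out.append(("gene_body", self.start, self.end, ""))
        for s, e in self.utr5:
            out.append(("five_prime_UTR", s, e, ""))
        for s, e in self.utr3:
            out.append(("three_prime_UTR", s, e, ""))
        return [
            (cls, max(1, s), e, side) for cls, s, e, side in out if e >= max(1, s)
        ]

    def distance_to_body(self, pos: int) -> int:
        if self.start <= pos <= self.end:
            return 0
        return self.start - pos if pos < self.start else pos - self.end


class GeneFeatureIndex:
    """Interval lookup over the derived windows of all genes."""

    def __init__(self, genes: dict[str, GeneFeature], config: AnnotationConfig):
        self.genes = genes
        self.config = config
        self._trees: dict[str, IntervalTree] = {}
        for g in genes.values():
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for cls, s, e, side in g.windows(config):
                # intervaltree is half-open; store [s, e+1)
                tree.addi(s, e + 1, (cls, g.gene_id, side))

    def query(self, chrom: str, pos: int) -> list[tuple[str, str, str]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def _read_text(path) -> str:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def _validate_gff3(text: str, path) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"{path}: malformed GFF3 line {lineno}: {line!r}")


def load_gene_models(
    gff3_path, config: AnnotationConfig | None = None
) -> GeneFeatureIndex:
    """Build the gene-feature index from a GFF3 file (plain or gzip).

    One entry per ``gene`` record; the TSS is the strand-aware 5' end of
    the gene span (genes, not transcripts, are annotated).  UTR child
    records are attached when present.  Genes without strand are skipped
    with a warning.
    """
    config = config or AnnotationConfig()
    text = _read_text(gff3_path)
    _validate_gff3(text, gff3_path)
    genes: dict[str, GeneFeature] = {}
    if not text.strip() or not any(
        line and not line.startswith("#") for line in text.splitlines()
    ):
        return GeneFeatureIndex(genes, config)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            warnings.warn(
                f"gene {g.id} has no strand; record skipped", stacklevel=2
            )
            continue
        name = g.attributes.get("Name", [g.id])[0]
        feat = GeneFeature(
            gene_id=g.id,
            name=name,
            chrom=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand,
        )
        for ft, target in (("five_prime_UTR", feat.utr5), ("three_prime_UTR", feat.utr3)):
            for child in db.children(g, featuretype=ft):
                target.append((child.start, child.end))
        genes[g.id] = feat
    return GeneFeatureIndex(genes, config)


@dataclass
class AnnotationResult:
    """Winning region assignment for one CpG site."""

    site: CpGSite
    region_class: str  # TSS/promoter/gene_body/five_prime_UTR/three_prime_UTR/upstream/downstream/intergenic
    gene_id: str = ""
    gene_name: str = ""
    gene_characterized: bool | None = None
    distance_to_gene_body: int | None = None


def annotate_site(
    site: CpGSite, index: GeneFeatureIndex, config: AnnotationConfig | None = None
) -> AnnotationResult:
    """Assign one site to its highest-priority overlapping region.

    Class priority wins before any gene-level tie-break; within the
    winning class, characterised genes beat LOC genes and then the
    smallest distance to the gene body decides.
    """
    config = config or index.config
    hits = index.query(site.chrom, site.pos)
    if not hits:
        return AnnotationResult(site=site, region_class="intergenic")
    rank = {cls: i for i, cls in enumerate(config.priority)}
    best_rank = min(rank[cls] for cls, _, _ in hits)
    winning_class = config.priority[best_rank]
    candidates = [
        (gid, side) for cls, gid, side in hits if cls == winning_class
    ]

    def sort_key(cand):
        gid, _ = cand
        g = index.genes[gid]
        return (not g.characterized, g.distance_to_body(site.pos), gid)

    gid, side = min(candidates, key=sort_key)
    gene = index.genes[gid]
    region = side if winning_class == "flank" else winning_class
    return AnnotationResult(
        site=site,
        region_class=region,
        gene_id=gid,
        gene_name=gene.name,
        gene_characterized=gene.characterized,
        distance_to_gene_body=gene.distance_to_body(site.pos),
    )


def annotate_table(
    dms_table: pd.DataFrame,
    index: GeneFeatureIndex,
    config: AnnotationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Annotate every site of a DMS table; returns the joined table and
    counts by region class and by characterised/LOC status."""
    config = config or index.config
    out = dms_table.copy()
    cols = {
        "region_class": [],
        "gene_id": [],
        "gene_name": [],
        "gene_characterized": [],
        "distance_to_gene_body": [],
    }
    for chrom, pos in zip(out["chrom"], out["pos"]):
        res = annotate_site(CpGSite(chrom, int(pos)), index, config)
        cols["region_class"].append(res.region_class)
        cols["gene_id"].append(res.gene_id)
        cols["gene_name"].append(res.gene_name)
        cols["gene_characterized"].append(res.gene_characterized)
        cols["distance_to_gene_body"].append(res.distance_to_gene_body)
    for k, v in cols.items():
        out[k] = v
    annotated = out["region_class"] != "intergenic"
    counts = {
        "by_class": out["region_class"].value_counts().to_dict(),
        "n_annotated": int(annotated.sum()),
        "n_intergenic": int((~annotated).sum()),
        "n_genes": int(out.loc[annotated, "gene_id"].nunique()),
        "n_genes_characterized": int(
            out.loc[annotated & out["gene_characterized"].fillna(False).astype(bool), "gene_id"].nunique()
        ),
        "n_genes_loc": int(
            out.loc[
                annotated & ~out["gene_characterized"].fillna(True).astype(bool), "gene_id"
            ].nunique()
        ),
    }
    return out, counts
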