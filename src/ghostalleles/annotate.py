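"""Site annotation against gene models.

Each SNP site is classified as ``exonic``, ``intronic``, ``promoter`` or
``intergenic`` with precedence exonic > intronic > promoter > intergenic.
A promoter is any position within ``promoter_window`` bp upstream of a
transcription start site on that gene's strand. Gene models come from GFF3
(1-based closed intervals, via gffutils) or BED6 (0-based half-open, each
record treated as a single-exon gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genotypes import SiteInfo

logger = logging.getLogger(__name__)

CLASSES = ("exonic", "intronic", "promoter", "intergenic")


@dataclass
class GeneModel:
    """One gene: 1-based closed body interval, strand, and exon intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")

    @property
    def tss(self) -> int:
        """Transcription start: ``start`` on '+', ``end`` on '-'."""
        return self.start if self.strand == "+" else self.end


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from a GFF3 (``.gff``/``.gff3``) or BED file."""
    p = str(path)
    if p.endswith((".bed", ".bed.txt")):
        return _read_bed(p)
    return _read_gff3(p)


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        try:
            exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    chrom=g.seqid,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    exons=exons,
                )
            )
        except ValueError as exc:
            logger.warning("skipping malformed gene record %s: %s", g.id, exc)
    return genes


def _read_bed(path: str) -> list[GeneModel]:
    """BED6: 0-based half-open converted to 1-based closed; one exon per record."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                logger.warning("skipping malformed BED line %d (need 6 columns)", ln)
                continue
            try:
                chrom, start0, end0, name, _score, strand = parts[:6]
                start, end = int(start0) + 1, int(end0)
                genes.append(
                    GeneModel(
                        gene_id=name,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        exons=[(start, end)],
                    )
                )
            except ValueError as exc:
                logger.warning("skipping malformed BED line %d: %s", ln, exc)
    return genes


def annotate_sites(
    sites: list[SiteInfo],
    gene_models: list[GeneModel],
    promoter_window: int = 2000,
) -> list[str]:
    """Classify every site; returns one class per site, in order.

    Interval trees are half-open; 1-based closed intervals [a, b] are stored
    as [a, b + 1).
    """
    exon_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    prom_trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1)
        for a, b in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(a, b + 1)
        if g.strand == "+":
            lo, hi = g.tss - promoter_window, g.tss - 1
        else:
            lo, hi = g.tss + 1, g.tss + promoter_window
        lo = max(lo, 1)
        if hi >= lo:
            prom_trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1)

    classes: list[str] = []
    for s in sites:
        if s.chrom in exon_trees and exon_trees[s.chrom].overlaps_point(s.pos):
            classes.append("exonic")
        elif s.chrom in body_trees and body_trees[s.chrom].overlaps_point(s.pos):
            classes.append("intronic")
        elif s.chrom in prom_trees and prom_trees[s.chrom].overlaps_point(s.pos):
            classes.append("promoter")
        else:
            classes.append("intergenic")
    return classes


def write_gff3(gene_models: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ttoy\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
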