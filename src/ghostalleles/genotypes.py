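"""Genotype data model and I/O.

The universal substrate is a dense individuals x sites matrix of diploid
ALT-allele dosages in {0, 1, 2}, with :data:`MISSING` (-1) for no-calls.
Samples are partitioned by a :class:`PopulationMap` into named reference
groups plus *focal* individuals that are analysed one at a time and never
pooled into a reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing (uncalled or half-called) genotype.
MISSING: int = -1

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SiteInfo:
    """A biallelic SNP site.

    ``locus_id`` tags SNPs from the same RAD locus (used by the
    one-SNP-per-locus filter); ``annotation_class`` is one of
    ``exonic``/``intronic``/``promoter``/``intergenic`` once
    :func:`ghostalleles.annotate.annotate_sites` has run, else
    ``unannotated``.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    locus_id: str | None = None
    annotation_class: str = "unannotated"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix: ``calls[i, j]`` is sample i's ALT count at site j."""

    samples: list[str]
    sites: list[SiteInfo]
    calls: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        valid = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not valid.all():
            raise ValueError("calls must be in {0,1,2} or MISSING")
        keys = {(s.chrom, s.pos) for s in self.sites}
        if len(keys) != len(self.sites):
            raise ValueError("duplicate (chromosome, position) site records")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in matrix") from None

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[j] for j in index],
            calls=self.calls[:, index].copy(),
        )

    def subset_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=list(self.sites),
            calls=self.calls[idx, :].copy(),
        )

    def with_annotations(self, classes: Sequence[str]) -> "GenotypeMatrix":
        if len(classes) != self.n_sites:
            raise ValueError("one annotation class per site required")
        sites = [replace(s, annotation_class=c) for s, c in zip(self.sites, classes)]
        return GenotypeMatrix(samples=list(self.samples), sites=sites, calls=self.calls.copy())


@dataclass
class PopulationMap:
    """Sample -> reference-group assignment plus the flagged focal samples."""

    assignments: dict[str, str]  # reference samples only
    focal_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & set(self.focal_samples)
        if overlap:
            raise ValueError(f"samples both focal and reference: {sorted(overlap)}")
        if len(set(self.focal_samples)) != len(self.focal_samples):
            raise ValueError("duplicate focal sample")

    @property
    def groups(self) -> list[str]:
        """Reference group labels in first-seen order."""
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def require_reference_groups(self, n: int = 2) -> None:
        if len(self.groups) < n:
            raise ValueError(
                f"at least {n} reference groups required, found {len(self.groups)}"
            )


@dataclass
class AlleleFrequencyTable:
    """Per (group, site) ALT-allele counts over non-missing gene copies.

    Focal individuals appear as their own single-sample rows after the
    reference groups; ``ref_groups`` lists which rows are reference groups.
    Frequencies are NaN where a group has zero called copies.
    """

    groups: list[str]
    ref_groups: list[str]
    sites: list[SiteInfo]
    alt_count: np.ndarray  # int, (n_groups, n_sites)
    copies: np.ndarray  # int, (n_groups, n_sites)

    def __post_init__(self) -> None:
        if not set(self.ref_groups) <= set(self.groups):
            raise ValueError("ref_groups must be a subset of groups")
        if self.alt_count.shape != self.copies.shape:
            raise ValueError("alt_count / copies shape mismatch")
        if (self.alt_count < 0).any() or (self.alt_count > self.copies).any():
            raise ValueError("need 0 <= alt_count <= copies")

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.copies > 0, self.alt_count / self.copies, np.nan)

    def row(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in table") from None

    def allele_count(self, group: str, site_idx: int, allele: int) -> int:
        """Observed copies of ``allele`` (0 = REF, 1 = ALT) in ``group`` at a site."""
        r = self.row(group)
        alt = int(self.alt_count[r, site_idx])
        return alt if allele == 1 else int(self.copies[r, site_idx]) - alt


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged); ``./.``
    and half-calls become :data:`MISSING`. The dosage counts ALT alleles.
    A ``locus_id`` is taken from the ID column's text before the first
    ``:`` when present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error surface varies
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    sites: list[SiteInfo] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = np.array(var.genotypes, dtype=int)  # (n, 3): a1, a2, phased
        alleles = gts[:, :2]
        dosage = alleles.sum(axis=1).astype(np.int8)
        dosage[(alleles < 0).any(axis=1)] = MISSING  # ./., half-calls
        locus = None
        if var.ID not in (None, "", "."):
            locus = str(var.ID).split(":", 1)[0]
        sites.append(
            SiteInfo(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                locus_id=locus,
            )
        )
        rows.append(dosage)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    if not sites:
        raise ValueError(f"no biallelic SNP records retained from {path}")
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms: dict[str, None] = {}
        for s in G.sites:
            chroms.setdefault(s.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, site in enumerate(G.sites):
            vid = f"{site.locus_id}:{site.pos}" if site.locus_id else "."
            gts = "\t".join(gt_map[int(d)] for d in G.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{vid}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_popmap(path: str, samples: Sequence[str] | None = None) -> PopulationMap:
    """Read a population map TSV with columns ``sample``, ``group``, ``role``.

    ``role`` is ``reference`` or ``focal``; focal samples keep an empty or
    ignored group label. If ``samples`` (e.g. the VCF sample list) is given,
    map entries absent from it are an error, while samples absent from the
    map are excluded with a warning by the caller.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample", "group", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"popmap must have columns {sorted(required)}, got {list(df.columns)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample(s) in popmap: {dups}")
    if samples is not None:
        unknown = set(df["sample"]) - set(samples)
        if unknown:
            raise ValueError(f"popmap samples not in genotype data: {sorted(unknown)}")
        unmapped = set(samples) - set(df["sample"])
        if unmapped:
            logger.warning("samples without popmap entry excluded: %s", sorted(unmapped))
    assignments: dict[str, str] = {}
    focal: list[str] = []
    for rec in df.itertuples(index=False):
        role = str(rec.role).strip().lower()
        if role == "focal":
            focal.append(rec.sample)
        elif role == "reference":
            if pd.isna(rec.group) or str(rec.group).strip() == "":
                raise ValueError(f"reference sample {rec.sample} lacks a group label")
            assignments[rec.sample] = str(rec.group).strip()
        else:
            raise ValueError(f"unknown role {rec.role!r} for sample {rec.sample}")
    return PopulationMap(assignments=assignments, focal_samples=focal)


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\trole\n")
        for s, g in popmap.assignments.items():
            fh.write(f"{s}\t{g}\treference\n")
        for s in popmap.focal_samples:
            fh.write(f"{s}\t-\tfocal\n")


def allele_frequencies(G: GenotypeMatrix, popmap: PopulationMap) -> AlleleFrequencyTable:
    """ALT-allele counts and frequencies per reference group and per focal.

    Frequencies use non-missing gene copies only; a group with zero called
    copies at a site has an undefined (NaN) frequency there.
    """
    groups = popmap.groups
    focal = [f for f in popmap.focal_samples if f in G.samples]
    labels = groups + focal
    n_sites = G.n_sites
    alt = np.zeros((len(labels), n_sites), dtype=np.int64)
    cop = np.zeros((len(labels), n_sites), dtype=np.int64)
    for r, g in enumerate(groups):
        idx = [G.sample_index(s) for s in popmap.group_samples(g) if s in G.samples]
        sub = G.calls[idx, :]
        called = sub != MISSING
        alt[r] = np.where(called, sub, 0).sum(axis=0)
        cop[r] = 2 * called.sum(axis=0)
    for k, f in enumerate(focal):
        row = len(groups) + k
        d = G.calls[G.sample_index(f), :]
        called = d != MISSING
        alt[row] = np.where(called, d, 0)
        cop[row] = 2 * called
    return AlleleFrequencyTable(
        groups=labels, ref_groups=groups, sites=list(G.sites), alt_count=alt, copies=cop
    )
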