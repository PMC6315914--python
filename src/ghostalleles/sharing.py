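"""Private-allele sharing between reference groups and focal individuals.

An allele (REF or ALT at a site) is *private* to a reference group when it
is observed at least once in that group's non-missing gene copies and
never in any other reference group. Focal individuals never veto
privateness. Sharing analyses survey, per focal individual, only the loci
at which that focal is fully genotyped, recompute the private-allele sets
over the surveyed loci, and count how many private alleles the focal
carries (S_PA), with the percentage S_PA% = 100 * S_PA / N_PA, the
zygosity of each carried allele, a rarefied shared private allelic
richness (S_PAr), frequency-binned sharing proportions, and an
annotation-class tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import RarefactionSpec, _absence_prob
from .genotypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    PopulationMap,
    allele_frequencies,
)

#: An allele is identified as (site_index, allele) with allele 0=REF, 1=ALT.
Allele = tuple[int, int]


@dataclass
class PrivateAlleleSet:
    """Per reference group: the set of (site, allele) pairs private to it."""

    sets: dict[str, set[Allele]]

    def __post_init__(self) -> None:
        seen: set[Allele] = set()
        for group, alleles in self.sets.items():
            dup = seen & alleles
            if dup:
                raise ValueError(f"allele(s) {sorted(dup)} private to multiple groups")
            seen |= alleles

    def n_pa(self, group: str) -> int:
        return len(self.sets[group])


@dataclass
class SharingReport:
    focal: str
    loci_surveyed: int
    per_group: dict[str, dict] = field(default_factory=dict)

    def table_row(self, group: str) -> dict:
        rec = self.per_group[group]
        return {
            "focal": self.focal,
            "group": group,
            "loci_surveyed": self.loci_surveyed,
            "N_PA": rec["N_PA"],
            "S_PA": rec["S_PA"],
            "S_PA_pct": rec["S_PA_pct"],
        }


def percent_shared(n_pa: int, s_pa: int) -> float:
    """The sharing percentage 100 * S_PA / N_PA, rounded to two decimals."""
    if s_pa > n_pa:
        raise ValueError("S_PA cannot exceed N_PA")
    if n_pa == 0:
        return float("nan")
    return round(100.0 * s_pa / n_pa, 2)


def private_alleles(
    freq_table: AlleleFrequencyTable, reference_groups: list[str] | None = None
) -> PrivateAlleleSet:
    """Identify alleles private to each reference group.

    Allele a at site s is private to group k iff count(k, s, a) >= 1 and
    count(k', s, a) = 0 for every other reference group k' (non-missing
    copies only; singletons count). Focal rows in the table are ignored.
    """
    groups = reference_groups if reference_groups is not None else freq_table.ref_groups
    if len(groups) < 2:
        raise ValueError("private alleles need >= 2 reference groups")
    rows = [freq_table.row(g) for g in groups]
    alt = freq_table.alt_count[rows, :]
    ref = freq_table.copies[rows, :] - alt
    sets: dict[str, set[Allele]] = {g: set() for g in groups}
    for counts, allele in ((ref, 0), (alt, 1)):
        present = counts > 0
        owners = present.sum(axis=0)
        for k, g in enumerate(groups):
            priv = present[k] & (owners == 1)
            sets[g].update((int(j), allele) for j in np.flatnonzero(priv))
    return PrivateAlleleSet(sets=sets)


def _carries(dosage: int, allele: int) -> bool:
    """Does a non-missing diploid dosage include at least one copy of allele?"""
    return dosage >= 1 if allele == 1 else dosage <= 1


def _zygosity(dosage: int, allele: int) -> str:
    if allele == 1:
        return "hom" if dosage == 2 else "het"
    return "hom" if dosage == 0 else "het"


def shared_private_report(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    focal: str,
    bin_width: float = 0.10,
    global_denominator: bool = False,
) -> SharingReport:
    """Survey one focal individual for carried private alleles.

    Only loci with a non-missing focal call are surveyed; private-allele
    sets are recomputed over the surveyed loci so missing focal data can
    never masquerade as absence of sharing.
    """
    if focal not in G.samples:
        raise ValueError(f"focal sample {focal!r} not in genotype matrix")
    popmap.require_reference_groups(2)
    fi = G.sample_index(focal)
    surveyed = G.calls[fi, :] != MISSING
    if not surveyed.any():
        raise ValueError(f"focal {focal!r} has no genotyped locus to survey")
    Gs = G.subset_sites(surveyed)
    dosages = Gs.calls[Gs.sample_index(focal), :]
    freq = allele_frequencies(Gs, popmap)
    privates = private_alleles(freq)

    report = SharingReport(focal=focal, loci_surveyed=int(surveyed.sum()))
    for group in popmap.groups:
        shared: list[dict] = []
        for site_idx, allele in sorted(privates.sets[group]):
            d = int(dosages[site_idx])
            if _carries(d, allele):
                site = Gs.sites[site_idx]
                r = freq.row(group)
                cop = int(freq.copies[r, site_idx])
                cnt = freq.allele_count(group, site_idx, allele)
                shared.append(
                    {
                        "chrom": site.chrom,
                        "pos": site.pos,
                        "allele": allele,
                        "zygosity": _zygosity(d, allele),
                        "owner_freq": cnt / cop if cop else float("nan"),
                        "annotation_class": site.annotation_class,
                    }
                )
        n_pa = privates.n_pa(group)
        s_pa = len(shared)
        ann_tally: dict[str, int] = {}
        for rec in shared:
            ann_tally[rec["annotation_class"]] = ann_tally.get(rec["annotation_class"], 0) + 1
        het = sum(1 for rec in shared if rec["zygosity"] == "het")
        report.per_group[group] = {
            "N_PA": n_pa,
            "S_PA": s_pa,
            "S_PA_pct": percent_shared(n_pa, s_pa),
            "shared_detail": shared,
            "het_fraction": het / s_pa if s_pa else float("nan"),
            "annotation_tally": ann_tally,
            "propS_bins": freq_bin_props(
                privates,
                shared_set={(rec["chrom"], rec["pos"], rec["allele"]) for rec in shared},
                freq_table=freq,
                group=group,
                bin_width=bin_width,
                global_denominator=global_denominator,
            ),
        }
    return report


def freq_bin_props(
    privates: PrivateAlleleSet,
    shared_set: set,
    freq_table: AlleleFrequencyTable,
    group: str,
    bin_width: float = 0.10,
    global_denominator: bool = False,
) -> list[dict]:
    """Sharing proportion per owner-group frequency bin.

    Bins are left-open/right-closed: (0, w], (w, 2w], ..., (1-w, 1], on the
    allele's frequency in its owning reference group (full sample,
    non-missing copies). propS for a bin is the number of shared private
    alleles in the bin divided by the number of private alleles in the
    same bin (or by the total private-allele count with
    ``global_denominator``). Bins with no private alleles are undefined
    (NaN), not zero.
    """
    n_bins = int(round(1.0 / bin_width))
    priv_counts = np.zeros(n_bins, dtype=int)
    shared_counts = np.zeros(n_bins, dtype=int)
    r = freq_table.row(group)
    total_priv = len(privates.sets[group])
    for site_idx, allele in privates.sets[group]:
        cop = int(freq_table.copies[r, site_idx])
        if cop == 0:
            continue
        f = freq_table.allele_count(group, site_idx, allele) / cop
        b = min(int(np.ceil(f / bin_width)) - 1, n_bins - 1)
        b = max(b, 0)
        priv_counts[b] += 1
        site = freq_table.sites[site_idx]
        if (site.chrom, site.pos, allele) in shared_set:
            shared_counts[b] += 1
    rows = []
    for b in range(n_bins):
        denom = total_priv if global_denominator else priv_counts[b]
        rows.append(
            {
                "bin_low": round(b * bin_width, 10),
                "bin_high": round((b + 1) * bin_width, 10),
                "n_private": int(priv_counts[b]),
                "n_shared": int(shared_counts[b]),
                "propS": (shared_counts[b] / denom) if denom > 0 else float("nan"),
            }
        )
    return rows


def shared_private_richness(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    focal: str,
    spec: RarefactionSpec,
) -> dict[str, float]:
    """Rarefied shared private allelic richness S_PAr per reference group.

    Per retained locus (focal fully genotyped and every reference group
    with >= g called copies), the group-k contribution is

        sum_a P(a in g-subsample of k)
              * prod_{k' != k} P(a absent from g-subsample of k')
              * 1[a carried by the focal]

    averaged over retained loci. The focal is a fixed, unsubsampled unit
    of two gene copies.
    """
    if focal not in G.samples:
        raise ValueError(f"focal sample {focal!r} not in genotype matrix")
    groups = popmap.groups
    for group in groups:
        n_k = len(popmap.group_samples(group))
        g_max = int(np.floor((1.0 - spec.tolerance) * 2 * n_k))
        if spec.g > g_max:
            raise ValueError(
                f"g={spec.g} infeasible for group {group!r} at tolerance {spec.tolerance}"
            )
    fi = G.sample_index(focal)
    freq = allele_frequencies(G, popmap)
    rows = [freq.row(g) for g in groups]
    alt = freq.alt_count[rows, :].astype(float)
    cop = freq.copies[rows, :].astype(float)
    ref = cop - alt
    focal_called = G.calls[fi, :] != MISSING
    retained = focal_called & (cop >= spec.g).all(axis=0)
    if not retained.any():
        raise ValueError("no locus retained for shared rarefaction")
    alt, cop, ref = alt[:, retained], cop[:, retained], ref[:, retained]
    dos = G.calls[fi, retained].astype(int)

    q_alt = _absence_prob(cop - alt, cop, spec.g)
    q_ref = _absence_prob(cop - ref, cop, spec.g)
    carry_alt = (dos >= 1).astype(float)
    carry_ref = (dos <= 1).astype(float)

    out: dict[str, float] = {}
    for k, group in enumerate(groups):
        others = [i for i in range(len(groups)) if i != k]
        contrib = (1.0 - q_alt[k]) * np.prod(q_alt[others], axis=0) * carry_alt + (
            1.0 - q_ref[k]
        ) * np.prod(q_ref[others], axis=0) * carry_ref
        out[group] = float(contrib.mean())
    return out


def focal_unique_alleles(
    G: GenotypeMatrix, popmap: PopulationMap, focals: list[str] | None = None
) -> dict:
    """Alleles carried by focal individuals but absent from every reference group.

    Returns the overall allele set, per-focal carriage with zygosity and
    homozygous fraction, and the intersection across focals.
    """
    focals = focals if focals is not None else popmap.focal_samples
    if not focals:
        raise ValueError("at least one focal sample required")
    freq = allele_frequencies(G, popmap)
    rows = [freq.row(g) for g in popmap.groups]
    alt = freq.alt_count[rows, :]
    ref = freq.copies[rows, :] - alt
    absent_alt = (alt == 0).all(axis=0)
    absent_ref = (ref == 0).all(axis=0)

    per_focal: dict[str, dict[Allele, str]] = {}
    for f in focals:
        d = G.calls[G.sample_index(f), :]
        carried: dict[Allele, str] = {}
        for allele, absent in ((1, absent_alt), (0, absent_ref)):
            for j in np.flatnonzero(absent):
                dj = int(d[j])
                if dj != MISSING and _carries(dj, allele):
                    carried[(int(j), allele)] = _zygosity(dj, allele)
        per_focal[f] = carried
    union: set[Allele] = set()
    for carried in per_focal.values():
        union |= set(carried)
    inter: set[Allele] = set.intersection(*(set(c) for c in per_focal.values()))
    return {
        "alleles": union,
        "per_focal": per_focal,
        "hom_fraction": {
            f: (
                sum(1 for z in c.values() if z == "hom") / len(c)
                if c
                else float("nan")
            )
            for f, c in per_focal.items()
        },
        "intersection": inter,
    }


def ibs_matrix(G: GenotypeMatrix, samples: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Pairwise mean identity-by-state over jointly genotyped loci.

    Per locus the IBS score of dosages d1, d2 is 1 - |d1 - d2| / 2; the
    pair value averages over loci non-missing in both samples. Pairs with
    no jointly genotyped locus get NaN.
    """
    names = samples if samples is not None else list(G.samples)
    if len(names) < 2:
        raise ValueError("ibs_matrix needs >= 2 samples")
    idx = [G.sample_index(s) for s in names]
    X = G.calls[idx, :].astype(float)
    V = X != MISSING
    n = len(names)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = V[i] & V[j]
            if not both.any():
                M[i, j] = M[j, i] = float("nan")
                continue
            score = 1.0 - np.abs(X[i, both] - X[j, both]) / 2.0
            M[i, j] = M[j, i] = float(score.mean())
    return M, names
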