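"""Site-retention filters on a genotype matrix.

Three composable rules, applied in a fixed order when chained:

1. per-site missingness: drop sites where the missing-call fraction
   exceeds ``max_missing`` (a site at exactly the threshold is kept);
2. minor-allele frequency: drop sites with MAF below ``min_maf``,
   computed over all non-missing gene copies of all analysed samples;
3. LD pruning: plink-style ``--indep-pairwise``-like pruning on squared
   dosage correlation; while any pair of retained sites separated by fewer
   than ``window`` retained sites has r^2 above ``r2_max``, one member of
   the worst pair is removed (the site with more missing calls; tie broken
   by removing the later coordinate). Correlations use pairwise-complete
   observations; zero-variance pairs count as r^2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class FilterStage:
    rule: str
    parameters: dict
    sites_in: int
    sites_out: int

    def __post_init__(self) -> None:
        if self.sites_out > self.sites_in:
            raise ValueError("sites_out cannot exceed sites_in")


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)

    def add(self, rule: str, parameters: dict, sites_in: int, sites_out: int) -> None:
        if self.stages and sites_in != self.stages[-1].sites_out:
            raise ValueError("stage input count does not chain from previous stage")
        self.stages.append(FilterStage(rule, parameters, sites_in, sites_out))

    def to_rows(self) -> list[dict]:
        return [
            {
                "rule": s.rule,
                "parameters": ";".join(f"{k}={v}" for k, v in s.parameters.items()),
                "sites_in": s.sites_in,
                "sites_out": s.sites_out,
            }
            for s in self.stages
        ]


def filter_sites(
    G: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Missingness filter then MAF filter, in that order."""
    if not 0.0 <= max_missing <= 1.0 or not 0.0 <= min_maf <= 1.0:
        raise ValueError("thresholds must be in [0, 1]")
    report = report if report is not None else FilterReport()
    n0 = G.n_sites
    miss_frac = (G.calls == MISSING).mean(axis=0)
    keep = miss_frac <= max_missing + 1e-12
    G1 = G.subset_sites(keep)
    report.add("max_missing", {"max_missing": max_missing}, n0, G1.n_sites)

    called = G1.calls != MISSING
    copies = 2 * called.sum(axis=0)
    alt = np.where(called, G1.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / copies, 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep2 = maf >= min_maf - 1e-12
    G2 = G1.subset_sites(keep2)
    report.add("min_maf", {"min_maf": min_maf}, G1.n_sites, G2.n_sites)
    if G2.n_sites == 0:
        raise ValueError(
            "all sites removed by filters; stages: "
            + "; ".join(f"{s.rule}: {s.sites_in}->{s.sites_out}" for s in report.stages)
        )
    return G2, report


def one_snp_per_locus(G: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the positionally first SNP per ``locus_id``; untagged sites kept."""
    best: dict[str, int] = {}
    keep: list[int] = []
    for j, s in enumerate(G.sites):
        if s.locus_id is None:
            keep.append(j)
            continue
        prev = best.get(s.locus_id)
        if prev is None or (s.chrom, s.pos) < (G.sites[prev].chrom, G.sites[prev].pos):
            best[s.locus_id] = j
    keep.extend(best.values())
    keep.sort()
    return G.subset_sites(keep)


def _band_r2(X: np.ndarray, max_offset: int) -> list[tuple[float, int, int]]:
    """r^2 for every column pair (i, i + d), d = 1..max_offset.

    Vectorised per offset with pairwise-complete sums; returns
    (r2, i, j) triples for pairs exceeding nothing in particular —
    callers filter. Zero-variance or <2 complete observations -> 0.
    """
    V = (X != MISSING).astype(float)
    Xv = np.where(X == MISSING, 0, X).astype(float)
    X2 = Xv**2
    out: list[tuple[float, int, int]] = []
    w = X.shape[1]
    for d in range(1, min(max_offset, w - 1) + 1):
        Va, Vb = V[:, :-d], V[:, d:]
        Xa, Xb = Xv[:, :-d], Xv[:, d:]
        both = Va * Vb
        n = both.sum(axis=0)
        sx = (Xa * Vb).sum(axis=0)
        sy = (Xb * Va).sum(axis=0)
        sxy = (Xa * Xb).sum(axis=0)
        sxx = (X2[:, :-d] * Vb).sum(axis=0)
        syy = (X2[:, d:] * Va).sum(axis=0)
        cov = n * sxy - sx * sy
        denom = (n * sxx - sx**2) * (n * syy - sy**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where((denom > 0) & (n >= 2), cov**2 / np.where(denom > 0, denom, 1.0), 0.0)
        out.extend((float(r2[i]), i, i + d) for i in np.flatnonzero(r2 > 0))
    return out


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """LD pruning on composite (dosage) correlation.

    A pair of retained sites is "within a window" when fewer than
    ``window`` retained sites separate them on the same chromosome.
    While any such pair has r^2 > ``r2_max``, one member of the currently
    worst pair is removed (the site with more missing calls; tie broken by
    removing the later coordinate); passes repeat until no within-window
    pair violates the bound, so the post-condition is guaranteed on the
    output regardless of removal order. ``step`` is accepted for interface
    compatibility with plink-style (window, step, r^2) triples; the
    fixed-point formulation does not use it.
    """
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    report = report if report is not None else FilterReport()
    n0 = G.n_sites
    n_miss = (G.calls == MISSING).sum(axis=0)

    order = sorted(range(n0), key=lambda j: (G.sites[j].chrom, G.sites[j].pos))
    by_chrom: dict[str, list[int]] = {}
    for j in order:
        by_chrom.setdefault(G.sites[j].chrom, []).append(j)

    removed: set[int] = set()
    for idxs in by_chrom.values():
        alive = list(idxs)
        while len(alive) >= 2:
            pairs = _band_r2(G.calls[:, alive], window - 1)
            offending = sorted(
                ((r2, a, b) for r2, a, b in pairs if r2 > r2_max + 1e-12),
                key=lambda t: -t[0],
            )
            if not offending:
                break
            dropped_local: set[int] = set()
            for _r2, a, b in offending:
                if a in dropped_local or b in dropped_local:
                    continue  # stale pair; re-evaluated next pass
                ja, jb = alive[a], alive[b]
                if n_miss[ja] > n_miss[jb]:
                    drop_local = a
                elif n_miss[jb] > n_miss[ja]:
                    drop_local = b
                else:
                    drop_local = (
                        a
                        if (G.sites[ja].chrom, G.sites[ja].pos)
                        > (G.sites[jb].chrom, G.sites[jb].pos)
                        else b
                    )
                dropped_local.add(drop_local)
            removed.update(alive[k] for k in dropped_local)
            alive = [j for k, j in enumerate(alive) if k not in dropped_local]
    keep = [j for j in range(n0) if j not in removed]
    Gp = G.subset_sites(keep)
    report.add(
        "ld_prune", {"window": window, "step": step, "r2_max": r2_max}, n0, Gp.n_sites
    )
    return Gp, report


def verify_ld(G: GenotypeMatrix, window: int = 50, r2_max: float = 0.5) -> bool:
    """Check that all pairs within ``window`` retained sites satisfy the bound."""
    order = sorted(range(G.n_sites), key=lambda j: (G.sites[j].chrom, G.sites[j].pos))
    by_chrom: dict[str, list[int]] = {}
    for j in order:
        by_chrom.setdefault(G.sites[j].chrom, []).append(j)
    for idxs in by_chrom.values():
        if len(idxs) < 2:
            continue
        pairs = _band_r2(G.calls[:, idxs], window - 1)
        if any(r2 > r2_max + 1e-9 for r2, _a, _b in pairs):
            return False
    return True
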