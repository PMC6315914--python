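"""Per-group diversity, differentiation and rarefaction-based richness.

Heterozygosity
    H_O per locus is the heterozygote fraction among non-missing genotypes;
    H_E is 2*p*(1-p) with p the group's ALT frequency (no small-sample
    correction). Group values are means over loci where the group has at
    least one called genotype.

F_ST
    The Weir & Cockerham (1984) estimator with variance components a
    (among populations), b (among individuals within populations) and c
    (within individuals), combined across loci as a ratio of sums
    (ratio-of-averages). Loci monomorphic across a pair contribute zero
    components.

Rarefaction
    ADZE-style estimators of allelic richness A_R and private allelic
    richness PA_R in standardized subsamples of g gene copies. With N_kj
    copies of allele j among N_k called copies in group k, the probability
    that allele j appears in a g-subsample is
    Q_kj = 1 - C(N_k - N_kj, g) / C(N_k, g), and

        A_R contribution  = sum_j Q_kj
        PA_R contribution = sum_j Q_kj * prod_{k' != k} (1 - Q_k'j)

    averaged over loci at which every analysed group has at least g called
    copies. The missing-data tolerance enters through the feasibility
    bound g <= floor((1 - tolerance) * 2 n_k) for every group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix, PopulationMap, allele_frequencies


@dataclass(frozen=True)
class RarefactionSpec:
    """Subsample size g (gene copies) and per-group missing-copy tolerance."""

    g: int
    tolerance: float = 0.10

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if not 0.0 <= self.tolerance < 1.0:
            raise ValueError("tolerance must be in [0, 1)")


def max_feasible_g(
    popmap: PopulationMap, tolerance: float, groups: list[str] | None = None
) -> int:
    """Largest subsample size g feasible for every analysed group:
    min over groups of floor((1 - tolerance) * 2 n_k)."""
    groups = groups if groups is not None else popmap.groups
    if not groups:
        raise ValueError("no groups to rarefy")
    return min(
        int(np.floor((1.0 - tolerance) * 2 * len(popmap.group_samples(g)))) for g in groups
    )


def _group_calls(G: GenotypeMatrix, popmap: PopulationMap, group: str) -> np.ndarray:
    idx = [G.sample_index(s) for s in popmap.group_samples(group) if s in G.samples]
    if not idx:
        raise ValueError(f"group {group!r} has no samples in the genotype matrix")
    return G.calls[idx, :]


def het_stats(G: GenotypeMatrix, popmap: PopulationMap) -> dict[str, dict[str, float]]:
    """Per-group mean observed and expected heterozygosity over loci."""
    out: dict[str, dict[str, float]] = {}
    for group in popmap.groups:
        calls = _group_calls(G, popmap, group)
        called = calls != MISSING
        n_called = called.sum(axis=0)
        has_data = n_called > 0
        het = ((calls == 1) & called).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(has_data, het / np.maximum(n_called, 1), np.nan)
            p = np.where(
                has_data,
                np.where(called, calls, 0).sum(axis=0) / np.maximum(2 * n_called, 1),
                np.nan,
            )
        he = 2.0 * p * (1.0 - p)
        out[group] = {
            "n": calls.shape[0],
            "H_O": float(np.nanmean(ho[has_data])),
            "H_E": float(np.nanmean(he[has_data])),
        }
    return out


def _wc84_components(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for two populations."""
    comps = []
    for calls in (calls_a, calls_b):
        called = calls != MISSING
        n_i = called.sum(axis=0).astype(float)  # genotyped individuals
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2.0 * n_i), np.nan)
            h_i = np.where(n_i > 0, ((calls == 1) & called).sum(axis=0) / n_i, np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    # loci unusable (a group fully missing or <2 individuals) or monomorphic
    usable = (n1 >= 2) & (n2 >= 2)
    poly = (p_bar > 0) & (p_bar < 1)
    ok = usable & poly & np.isfinite(a)
    zero = np.zeros_like(n_bar)
    return (
        np.where(ok, a, zero),
        np.where(ok, b, zero),
        np.where(ok, c, zero),
    )


def pairwise_fst(
    G: GenotypeMatrix, popmap: PopulationMap
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], np.ndarray]]:
    """Multi-locus WC84 F_ST for every reference-group pair.

    Returns the symmetric estimate dict plus per-locus (a, b, c) component
    arrays per pair (kept for testing and per-locus analyses).
    """
    groups = popmap.groups
    est: dict[tuple[str, str], float] = {}
    components: dict[tuple[str, str], np.ndarray] = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            calls_a = _group_calls(G, popmap, ga)
            calls_b = _group_calls(G, popmap, gb)
            if calls_a.shape[0] < 2 or calls_b.shape[0] < 2:
                raise ValueError(f"pairwise_fst needs >=2 samples per group ({ga}, {gb})")
            a, b, c = _wc84_components(calls_a, calls_b)
            denom = (a + b + c).sum()
            theta = float(a.sum() / denom) if denom > 0 else float("nan")
            est[(ga, gb)] = theta
            est[(gb, ga)] = theta
            components[(ga, gb)] = np.stack([a, b, c])
    for g in groups:
        est[(g, g)] = 0.0
    return est, components


def compare_groups(
    vectors: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> list[dict]:
    """Two-sided Wilcoxon rank-sum tests on per-locus statistic vectors.

    Normal approximation with tie correction; Benjamini-Hochberg adjustment
    across the tested pairs; ``significant`` flags FDR < ``alpha``.
    Degenerate comparisons (all values tied across both groups) get p = 1.
    """
    if pairs is None:
        names = list(vectors)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw: list[float] = []
    for a, b in pairs:
        x = np.asarray(vectors[a], dtype=float)
        y = np.asarray(vectors[b], dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"need >=2 loci per group for pair ({a}, {b})")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            raw.append(1.0)  # all-tied: no evidence either way
            continue
        p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        raw.append(float(min(p, 1.0)))
    rejected, adjusted, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    return [
        {
            "group_a": a,
            "group_b": b,
            "p_raw": praw,
            "p_adj": float(padj),
            "significant": bool(rej),
        }
        for (a, b), praw, padj, rej in zip(pairs, raw, adjusted, rejected)
    ]


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    """log C(n, k) with C(n, k) = 0 for n < k handled by the caller."""
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1.0) - gammaln(n - k + 1.0) - gammaln(k + 1.0)


def _absence_prob(n_without: np.ndarray, n_total: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a g-subsample) = C(N - N_j, g) / C(N, g)."""
    n_without = np.asarray(n_without, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    out = np.zeros(np.broadcast(n_without, n_total).shape, dtype=float)
    feasible = n_without >= g
    if np.any(feasible):
        lw = _log_comb(np.where(feasible, n_without, g), g)
        lt = _log_comb(n_total, g)
        out = np.where(feasible, np.exp(lw - np.broadcast_to(lt, out.shape)), 0.0)
    return out


def rarefied_richness(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    spec: RarefactionSpec,
    groups: list[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Rarefied allelic richness A_R and private allelic richness PA_R at g.

    A locus enters only if every analysed group has >= g called copies
    there; reported values are means over retained loci. Also reports
    N_PA, the plain count of private alleles (full-sample, no
    rarefaction) over the same retained loci.
    """
    groups = groups if groups is not None else popmap.groups
    for group in groups:
        n_k = len(popmap.group_samples(group))
        g_max = int(np.floor((1.0 - spec.tolerance) * 2 * n_k))
        if spec.g > g_max:
            raise ValueError(
                f"g={spec.g} infeasible for group {group!r}: "
                f"floor((1-{spec.tolerance}) * {2 * n_k}) = {g_max}"
            )
    freq = allele_frequencies(G, popmap)
    rows = [freq.row(g) for g in groups]
    alt = freq.alt_count[rows, :].astype(float)  # (K, L)
    cop = freq.copies[rows, :].astype(float)
    ref = cop - alt
    retained = (cop >= spec.g).all(axis=0)
    if not retained.any():
        raise ValueError(f"no locus has >= {spec.g} called copies in every group")
    alt, cop, ref = alt[:, retained], cop[:, retained], ref[:, retained]

    # absence probabilities per allele (axis 0: allele REF/ALT), group, locus
    q_alt = _absence_prob(cop - alt, cop, spec.g)  # P(ALT absent)
    q_ref = _absence_prob(cop - ref, cop, spec.g)  # P(REF absent)
    pres_alt = 1.0 - q_alt
    pres_ref = 1.0 - q_ref

    out: dict[str, dict[str, float]] = {}
    for k, group in enumerate(groups):
        others = [i for i in range(len(groups)) if i != k]
        ar = pres_ref[k] + pres_alt[k]
        pa = pres_ref[k] * np.prod(q_ref[others], axis=0) + pres_alt[k] * np.prod(
            q_alt[others], axis=0
        )
        # plain private-allele count at full sample over the same loci
        npa = int(
            ((alt[k] > 0) & (alt[others] == 0).all(axis=0)).sum()
            + ((ref[k] > 0) & (ref[others] == 0).all(axis=0)).sum()
        )
        out[group] = {
            "A_R": float(ar.mean()),
            "PA_R": float(pa.mean()),
            "N_PA": npa,
            "loci": int(retained.sum()),
        }
    return out
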