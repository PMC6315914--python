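"""Synthetic genotype panels with the structure the analysis assumes.

Reference groups drift independently from a shared ancestral allele
frequency under the Balding-Nichols model: at each locus with ancestral
frequency p, group k's frequency is Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k),
so the drift parameter F_k maps directly onto expected F_ST (two groups
with drift F each show pairwise F_ST close to F). Focal individuals are
two-way admixtures: each of their two gene copies per locus comes from
source group A with probability q, else B. Missing genotypes are injected
uniformly at random.

Defaults emulate a 62-canid reference panel: four groups (29 + 10 + 10 +
11 samples) over ~7,000 biallelic SNPs with pairwise F_ST in the
0.04-0.14 band, two focal individuals admixed between two of the groups,
and 10% missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .annotate import GeneModel
from .genotypes import MISSING, GenotypeMatrix, PopulationMap, SiteInfo

_N_CHROMS = 20
_SITE_SPACING = 5000


@dataclass(frozen=True)
class GroupSpec:
    """A drifted reference group: name, diploid sample size, drift F in (0, 1)."""

    name: str
    n: int
    F: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name}: n must be >= 1")
        if not 0.0 < self.F < 1.0:
            raise ValueError(f"group {self.name}: F must be in (0, 1), got {self.F}")


@dataclass(frozen=True)
class FocalSpec:
    """A two-way admixed focal individual with ancestry fraction q from source_a."""

    name: str
    source_a: str
    source_b: str
    q: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"focal {self.name}: q must be in [0, 1], got {self.q}")


@dataclass
class SimConfig:
    n_loci: int
    group_specs: list[GroupSpec]
    focal_specs: list[FocalSpec] = field(default_factory=list)
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        names = [g.name for g in self.group_specs]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for f in self.focal_specs:
            for src in (f.source_a, f.source_b):
                if src not in names:
                    raise ValueError(f"focal {f.name}: unknown source group {src!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        law = self.ancestral_freq_law
        if law[0] == "uniform":
            _, lo, hi = law
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError("uniform ancestral_freq_law needs 0 <= lo < hi <= 1")
        elif law[0] == "beta":
            _, a, b = law
            if a <= 0 or b <= 0:
                raise ValueError("beta ancestral_freq_law needs a, b > 0")
        else:
            raise ValueError(f"unknown ancestral_freq_law {law[0]!r}")


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions: a 4-group canid-like panel + 2 admixed focals.

    Drift values are chosen so pairwise F_ST spans roughly 0.04-0.14, with
    the most diverse group ('coyote') least drifted. The two focal
    individuals carry 60% ancestry from the small, strongly drifted
    'red_wolf' group, the rest from 'coyote'. The ancestral frequency law
    is the U-shaped Beta(0.5, 0.5): a rare-allele-rich spectrum is what
    gives every group a meaningful stock of private alleles, the quantity
    the sharing analyses run on.
    """
    return SimConfig(
        n_loci=7000,
        ancestral_freq_law=("beta", 0.5, 0.5),
        group_specs=[
            GroupSpec("coyote", 29, 0.010),
            GroupSpec("gray_wolf", 10, 0.115),
            GroupSpec("eastern_wolf", 10, 0.075),
            GroupSpec("red_wolf", 11, 0.070),
        ],
        focal_specs=[
            FocalSpec("GI-1", "red_wolf", "coyote", 0.60),
            FocalSpec("GI-2", "red_wolf", "coyote", 0.60),
        ],
        missing_rate=0.10,
        seed=seed,
    )


def _ancestral_freqs(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], size=n)
    return rng.beta(law[1], law[2], size=n)


def _make_sites(n_loci: int) -> list[SiteInfo]:
    sites = []
    per_chrom = int(np.ceil(n_loci / _N_CHROMS))
    for j in range(n_loci):
        chrom = f"chr{j // per_chrom + 1}"
        pos = (j % per_chrom) * _SITE_SPACING + 1000
        sites.append(
            SiteInfo(chrom=chrom, pos=pos, ref="A", alt="G", locus_id=f"L{j}")
        )
    return sites


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Simulate a reference panel plus admixed focal individuals.

    Returns the genotype matrix (missingness already injected if
    ``config.missing_rate > 0``), the population map, and a truth record
    with the ancestral and per-group allele frequencies, each focal's true
    q, and each group's drift F.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    p_anc = _ancestral_freqs(config.ancestral_freq_law, L, rng)

    group_freqs: dict[str, np.ndarray] = {}
    blocks: list[np.ndarray] = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for spec in config.group_specs:
        shape = (1.0 - spec.F) / spec.F
        f = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        group_freqs[spec.name] = f
        g = rng.binomial(2, f, size=(spec.n, L)).astype(np.int8)
        blocks.append(g)
        for i in range(spec.n):
            name = f"{spec.name}_{i + 1}"
            samples.append(name)
            assignments[name] = spec.name

    focal_rows: list[np.ndarray] = []
    for spec in config.focal_specs:
        row = simulate_admixed(
            group_freqs[spec.source_a],
            group_freqs[spec.source_b],
            spec.q,
            rng=rng,
        )
        focal_rows.append(row)
        samples.append(spec.name)
    if focal_rows:
        blocks.append(np.stack(focal_rows))

    calls = np.concatenate(blocks, axis=0)
    G = GenotypeMatrix(samples=samples, sites=_make_sites(L), calls=calls)
    popmap = PopulationMap(
        assignments=assignments,
        focal_samples=[f.name for f in config.focal_specs],
    )
    if config.missing_rate > 0:
        G = inject_missingness(G, config.missing_rate, seed=rng.integers(2**31))
    truth = {
        "ancestral_freq": p_anc,
        "group_freqs": group_freqs,
        "q": {f.name: f.q for f in config.focal_specs},
        "F": {g.name: g.F for g in config.group_specs},
        "seed": config.seed,
    }
    return G, popmap, truth


def simulate_admixed(
    freqs_A: np.ndarray,
    freqs_B: np.ndarray,
    q: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Genotype vector of a two-way admixed diploid.

    Each of the two gene copies at each locus descends from population A
    with probability ``q`` (else B) independently, then carries the ALT
    allele with that population's frequency. No linkage or ancestry-tract
    structure is imposed.
    """
    freqs_A = np.asarray(freqs_A, dtype=float)
    freqs_B = np.asarray(freqs_B, dtype=float)
    if freqs_A.shape != freqs_B.shape:
        raise ValueError("frequency vectors must have equal length")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = freqs_A.shape[0]
    from_A = rng.random(size=(2, L)) < q
    p_copy = np.where(from_A, freqs_A[None, :], freqs_B[None, :])
    copies = rng.random(size=(2, L)) < p_copy
    return copies.sum(axis=0).astype(np.int8)


def inject_missingness(G: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call to MISSING independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return GenotypeMatrix(
            samples=list(G.samples), sites=list(G.sites), calls=G.calls.copy()
        )
    rng = np.random.default_rng(seed)
    mask = rng.random(size=G.calls.shape) < rate
    calls = G.calls.copy()
    calls[mask] = MISSING
    return GenotypeMatrix(samples=list(G.samples), sites=list(G.sites), calls=calls)


def simulate_annotation(
    sites: list[SiteInfo],
    seed: int = 0,
    n_genes: int = 3,
    covered_fraction: float = 0.5,
    promoter_window: int = 2000,
) -> tuple[list[GeneModel], list[str]]:
    """Toy gene models over the sites' span, plus the true class per site.

    Genes are laid down over ~``covered_fraction`` of each chromosome's
    span with alternating exon/intron structure; the truth record is
    computed from the constructed intervals so tests of the annotation
    engine have an independent answer key.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    genes: list[GeneModel] = []
    gid = 0
    for chrom, positions in by_chrom.items():
        lo, hi = min(positions), max(positions)
        span = max(hi - lo + 1, 1)
        gene_len = max(int(span * covered_fraction / max(n_genes, 1)), 200)
        for k in range(n_genes):
            start = lo + int(k * span / max(n_genes, 1)) + int(rng.integers(0, 100))
            end = min(start + gene_len - 1, hi + 500)
            if end <= start + 10:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            # alternate exon/intron thirds inside the body
            third = max((end - start + 1) // 3, 1)
            exons = [(start, start + third - 1), (end - third + 1, end)]
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                )
            )
    truth = [_classify_plain(s, genes, promoter_window) for s in sites]
    return genes, truth


def _classify_plain(site: SiteInfo, genes: list[GeneModel], window: int) -> str:
    """Direct per-site scan over gene intervals; the generator's answer key
    is deliberately computed without the interval-tree annotation engine."""
    in_exon = in_body = in_prom = False
    for g in genes:
        if g.chrom != site.chrom:
            continue
        if any(a <= site.pos <= b for a, b in g.exons):
            in_exon = True
        if g.start <= site.pos <= g.end:
            in_body = True
        if g.strand == "+":
            if g.tss - window <= site.pos <= g.tss - 1:
                in_prom = True
        else:
            if g.tss + 1 <= site.pos <= g.tss + window:
                in_prom = True
    if in_exon:
        return "exonic"
    if in_body:
        return "intronic"
    if in_prom:
        return "promoter"
    return "intergenic"
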