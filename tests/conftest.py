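import numpy as np
import pytest

from ghostalleles import GenotypeMatrix, PopulationMap, SiteInfo
from ghostalleles.simulate import FocalSpec, GroupSpec, SimConfig, simulate_panel


def make_matrix(calls, chrom="chr1", samples=None, locus_ids=None):
    """Build a GenotypeMatrix from a dense array of dosages (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    samples = samples or [f"s{i}" for i in range(n)]
    sites = [
        SiteInfo(
            chrom=chrom,
            pos=100 * (j + 1),
            ref="A",
            alt="G",
            locus_id=None if locus_ids is None else locus_ids[j],
        )
        for j in range(L)
    ]
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def make_popmap(groups, focals=()):
    """groups: dict label -> list of sample names."""
    assignments = {s: g for g, members in groups.items() for s in members}
    return PopulationMap(assignments=assignments, focal_samples=list(focals))


@pytest.fixture(scope="session")
def small_panel():
    """A 4-group panel with two admixed focals, 800 loci, 10% missing."""
    cfg = SimConfig(
        n_loci=800,
        group_specs=[
            GroupSpec("coyote", 12, 0.02),
            GroupSpec("gray_wolf", 8, 0.12),
            GroupSpec("eastern_wolf", 8, 0.08),
            GroupSpec("red_wolf", 9, 0.07),
        ],
        focal_specs=[
            FocalSpec("GI-1", "red_wolf", "coyote", 0.60),
            FocalSpec("GI-2", "red_wolf", "coyote", 0.60),
        ],
        missing_rate=0.10,
        seed=42,
    )
    G, popmap, truth = simulate_panel(cfg)
    return G, popmap, truth
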