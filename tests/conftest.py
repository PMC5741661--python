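"""Shared fixtures: small hand-built tables and seeded simulations."""

import numpy as np
import pytest

from domestiscan.containers import MISSING, GenotypeTable
from domestiscan.simulate import (
    SimConfig,
    simulate_founder_haplotypes,
    simulate_population,
)


def make_gt(genotypes, pos=None, chrom=None, groups=None, haplotypes=None):
    """Build a GenotypeTable from a samples x variants list of lists."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    pos = np.arange(1, m + 1) * 10 if pos is None else np.asarray(pos)
    chrom = np.full(m, "chr1", dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeTable(
        sample_ids=sample_ids,
        variant_ids=[f"v{j}" for j in range(m)],
        chrom=chrom,
        pos=pos,
        genotypes=g,
        haplotypes=haplotypes,
        groups=groups or {},
    )


@pytest.fixture(scope="session")
def small_population():
    """Structured two-chromosome population reused by read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_variants=1500,
        n_genes=30,
        chrom_lengths={"LG1": 5_000_000, "LG2": 5_000_000},
        group_sizes={"serriola": 12, "butterhead": 20, "stem": 20},
        drift={"serriola": 0.1, "butterhead": 0.35, "stem": 0.35},
        missing_rate_range=(0.0, 0.15),
    )
    gt, truth = simulate_population(simulate_founder_haplotypes(cfg), cfg)
    return cfg, gt, truth
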