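"""Core in-memory containers for the pipeline.

All genomic intervals are 0-based half-open internally; VCF and GFF3
coordinates are converted at the I/O boundary. Genotypes are coded as the
count of alternate alleles (0 hom-ref, 1 het, 2 hom-alt) with ``MISSING``
(-1) for no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Sentinel genotype code for a missing call.
MISSING: int = -1


@dataclass
class GenotypeTable:
    """Samples x biallelic variants with genotype codes {0, 1, 2, MISSING}.

    Parameters
    ----------
    sample_ids : list of str
    variant_ids : list of str
    chrom : array of str, per variant
    pos : array of int, 1-based coordinate per variant, strictly increasing
        within each chromosome
    genotypes : int8 array, shape (n_samples, n_variants)
    haplotypes : optional int8 array, shape (n_samples, n_variants, 2),
        phased alleles; where present, their sum equals the genotype at
        every non-missing entry
    groups : mapping sample_id -> group label (may cover only some samples)
    """

    sample_ids: list
    variant_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    haplotypes: Optional[np.ndarray] = None
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        for c in pd_unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            hsum = self.haplotypes.sum(axis=2)
            obs = self.genotypes != MISSING
            if np.any(hsum[obs] != self.genotypes[obs]):
                raise ValueError("haplotype sums disagree with genotypes")

    # -- basic derived quantities -------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        n = 2 * g.count(axis=0)
        with np.errstate(invalid="ignore"):
            p = g.sum(axis=0).filled(0) / np.where(n > 0, n, 1)
        return np.where(n > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency from non-missing alleles only."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per variant."""
        return (self.genotypes == MISSING).mean(axis=0)

    def het_rate(self) -> np.ndarray:
        """Heterozygote fraction among non-missing calls per variant."""
        obs = (self.genotypes != MISSING).sum(axis=0)
        het = (self.genotypes == 1).sum(axis=0)
        return np.where(obs > 0, het / np.maximum(obs, 1), np.nan)

    # -- selection helpers ---------------------------------------------

    def sample_indices(self, group: str) -> np.ndarray:
        """Indices of samples assigned to ``group``."""
        idx = [i for i, s in enumerate(self.sample_ids) if self.groups.get(s) == group]
        return np.asarray(idx, dtype=np.int64)

    def take_samples(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=np.int64)
        sids = [self.sample_ids[i] for i in idx]
        return replace(
            self,
            sample_ids=sids,
            genotypes=self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            groups={s: self.groups[s] for s in sids if s in self.groups},
        )

    def take_variants(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=np.int64)
        return replace(
            self,
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            genotypes=self.genotypes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )

    def variant_mask_region(self, region: "Region") -> np.ndarray:
        """Boolean mask of variants inside a 0-based half-open region."""
        p0 = self.pos - 1
        return (self.chrom == region.chrom) & (p0 >= region.start) & (p0 < region.end)


def pd_unique(arr) -> list:
    """Order-preserving unique over a small object array."""
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


@dataclass
class RawVariantCall:
    """One raw variant site with per-sample evidence, pre-filtering."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: list
    mq: float
    depth: float
    qual: float
    # per-sample tuples (genotype code, ref_support, alt_support, gq)
    sample_calls: list = field(default_factory=list)
    is_indel: bool = False

    def __post_init__(self):
        if min(self.mq, self.depth, self.qual) < 0:
            raise ValueError("depth and qualities must be nonnegative")
        if len(self.alt) < 1:
            raise ValueError("at least one alt allele required")


@dataclass
class GeneAnnotation:
    """Gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class Region:
    """Half-open genomic interval with an attached statistic."""

    chrom: str
    start: int
    end: int
    stat_name: str = ""
    stat_value: float = float("nan")
    support: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must be < end")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "Region") -> float:
        """Gap between intervals; 0 when overlapping; inf across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        if self.overlaps(other):
            return 0.0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class ExpressionTable:
    """Genes x samples of nonnegative abundances (FPKM-like)."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    gene_annotations: dict = field(default_factory=dict)  # gene_id -> GeneAnnotation

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_id in expression table")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def take_samples(self, idx: Sequence[int]) -> "ExpressionTable":
        idx = np.asarray(idx, dtype=np.int64)
        return ExpressionTable(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            gene_annotations=dict(self.gene_annotations),
        )


def merge_overlapping(regions: list, merge_gap: float = 0) -> list:
    """Merge touching/overlapping regions, plus gaps strictly below ``merge_gap``.

    Supports of merged members are summed; the stat value is the maximum.
    Idempotent: merging already-merged output is a no-op.
    """
    if not regions:
        return []
    out = []
    for r in sorted(regions, key=lambda r: (str(r.chrom), r.start, r.end)):
        gap = r.start - out[-1].end if out else None
        if out and r.chrom == out[-1].chrom and (gap <= 0 or gap < merge_gap):
            last = out[-1]
            stats = [s for s in (last.stat_value, r.stat_value) if not np.isnan(s)]
            out[-1] = Region(
                last.chrom,
                last.start,
                max(last.end, r.end),
                stat_name=last.stat_name,
                stat_value=max(stats) if stats else float("nan"),
                support=last.support + r.support,
            )
        else:
            out.append(replace(r))
    return out
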