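"""Synthetic genotype, expression and phenotype generator with truth tracks.

The generator emulates the statistical structure of a structured crop
population assayed by RNA-seq: one wild group plus several cultivated
subgroups, block-haplotype linkage disequilibrium, implanted low-diversity
sweep intervals, donor-copied introgression tracts, a log-scale expression
model with local (cis) and distant (master-regulator-driven) genetic
effects, and a liability-threshold binary trait.

Model
-----
Each chromosome is tiled by blocks of ``block_length`` bp. A founder panel
of ``n_founders`` haplotypes per block is drawn with U-shaped allele
frequencies (Beta(0.2, 0.2)); every sample draws its two haplotypes per
block from a group-specific distribution over founders. Group distributions
derive from the uniform base by a Balding-Nichols-style Dirichlet
perturbation with drift intensity F: weights ~ Dirichlet(base * (1-F)/F),
so F -> 0 gives no differentiation and larger F more. Sweep intervals
restrict the affected (cultivated) groups to a reduced founder subset;
introgression tracts replace the recipient's haplotypes with draws from the
donor group's distribution.

Expression follows a log2-scale linear model

    y_g = mu_g + beta_cis * x_g + sum_m beta_trans(m, g) * r_m + eps,

where ``x_g`` is the centered genotype at the gene's cis variant, ``r_m``
the (itself cis-driven) centered expression of master regulator ``m`` and
eps ~ N(0, sigma^2); reported abundance is 2**y - 1 truncated at zero. The
binary trait is a liability threshold model over a small set of causal
variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .containers import (
    MISSING,
    ExpressionTable,
    GeneAnnotation,
    GenotypeTable,
    Region,
)


@dataclass
class SweepSpec:
    """Low-diversity interval implanted into cultivated groups."""

    chrom: str
    start: int
    end: int
    reduction: float = 0.9  # 1.0 -> single founder haplotype (monomorphic)
    groups: Optional[List[str]] = None  # None = all cultivated groups


@dataclass
class IntrogressionSpec:
    """Tract copied from the donor group's haplotype pool into recipients."""

    recipients: List[str]
    donor_group: str
    chrom: str
    start: int
    end: int


@dataclass
class TraitSpec:
    n_causal: int = 6
    effect: float = 4.0  # liability-scale effect per alt allele
    maf_min: float = 0.3
    threshold: Optional[float] = None  # None -> set from target prevalence
    prevalence: float = 0.5


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults are the analysis scale.

    Group sizes default to one wild group and four cultivated horticultural
    subgroups totalling 180 samples; 20,000 variants and 2,000 genes match
    the scale the association stages assume.
    """

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"LG1": 20_000_000, "LG2": 20_000_000, "LG3": 20_000_000}
    )
    n_variants: int = 20_000
    n_founders: int = 6
    block_length: int = 200_000
    # probability that a variant repeats the previous variant's founder
    # allele pattern (within a block), emulating the tight clusters of
    # near-perfectly linked SNPs that transcript-derived variants form
    copy_prob: float = 0.5
    # fraction of block draws where both haplotypes copy one founder:
    # cultivated and wild lettuce are predominantly self-pollinating, so
    # accessions are close to fully homozygous inbred lines
    selfing_rate: float = 0.95
    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {
            "serriola": 30,
            "butterhead": 45,
            "crisphead": 45,
            "romaine": 45,
            "stem": 45,
        }
    )
    wild_group: str = "serriola"
    # shared drift of the cultivated ancestor (single domestication
    # bottleneck) applied before per-subgroup drift; lowers pooled
    # cultivated diversity below the wild group's as observed in crops
    domestication_drift: float = 0.25
    drift: Dict[str, float] = field(
        default_factory=lambda: {
            "serriola": 0.10,
            "butterhead": 0.35,
            "crisphead": 0.35,
            "romaine": 0.35,
            "stem": 0.35,
        }
    )
    sweeps: List[SweepSpec] = field(default_factory=list)
    introgressions: List[IntrogressionSpec] = field(default_factory=list)
    # per-group fraction of variants carrying a fixed (lineage-private)
    # allele flip relative to the shared panel. The default wild group is a
    # progenitor (no fixed flips); a distinct donor species (the kind whose
    # private-SNP fraction dominates real panels) should set ~0.5 here.
    species_divergence: Dict[str, float] = field(default_factory=dict)
    missing_rate_range: Tuple[float, float] = (0.0, 0.2)
    # per-allele genotype-call error probability; keeps swept/monomorphic
    # windows from being exactly zero-diversity, as real call sets are
    error_rate: float = 0.001
    # expression architecture
    n_genes: int = 2_000
    cis_fraction: float = 0.3
    beta_cis: float = 1.5
    noise_sd: float = 0.25
    n_masters: int = 2
    master_targets: int = 40
    # distant effects are modest relative to local ones; 0.3 puts the
    # trans-explained share of a target's variance near one third
    beta_trans: float = 0.3
    mu_mean: float = 3.0
    mu_sd: float = 1.5
    trait: TraitSpec = field(default_factory=TraitSpec)

    def __post_init__(self):
        for g, f in self.drift.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"drift F for {g} must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for spec in self.sweeps + self.introgressions:
            if spec.chrom not in self.chrom_lengths:
                raise ValueError(f"spec chromosome {spec.chrom} not simulated")
            if not 0 <= spec.start < spec.end <= self.chrom_lengths[spec.chrom]:
                raise ValueError("spec interval outside chromosome bounds")

    @property
    def cultivated_groups(self) -> List[str]:
        return [g for g in self.group_sizes if g != self.wild_group]

    def sample_ids(self) -> List[str]:
        return [
            f"{g}_{i:03d}" for g, n in self.group_sizes.items() for i in range(n)
        ]


@dataclass
class TruthSet:
    """Ground truth emitted alongside the simulated data."""

    sweep_regions: List[dict] = field(default_factory=list)
    introgression_tracts: List[dict] = field(default_factory=list)
    eqtls: List[dict] = field(default_factory=list)  # gene, variant, kind, beta
    masters: List[dict] = field(default_factory=list)  # gene, variant, targets
    trait_loci: List[str] = field(default_factory=list)
    trait_prevalence: float = float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


@dataclass
class FounderPanel:
    """Founder haplotypes per chromosome plus block bookkeeping."""

    chroms: List[str]
    positions: Dict[str, np.ndarray]  # 1-based, sorted
    haplotypes: Dict[str, np.ndarray]  # (n_founders, n_var_chrom) in {0,1}
    block_of: Dict[str, np.ndarray]  # block index per variant
    n_blocks: Dict[str, int]
    n_founders: int
    block_length: int


def simulate_founder_haplotypes(config: SimConfig, rng: Optional[np.random.Generator] = None) -> FounderPanel:
    """Draw the founder haplotype panel defining the LD structure."""
    if config.n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    total_len = sum(config.chrom_lengths.values())
    positions, haplos, block_of, n_blocks = {}, {}, {}, {}
    remaining = config.n_variants
    chroms = list(config.chrom_lengths)
    for ci, (chrom, length) in enumerate(config.chrom_lengths.items()):
        if ci == len(chroms) - 1:
            m = remaining
        else:
            m = int(round(config.n_variants * length / total_len))
            remaining -= m
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=m, replace=False))
        freqs = np.clip(rng.beta(0.2, 0.2, size=m), 0.05, 0.95)
        H = (rng.random((config.n_founders, m)) < freqs).astype(np.int8)
        blocks = ((pos - 1) // config.block_length).astype(np.int64)
        copy = rng.random(m) < config.copy_prob
        for j in range(1, m):
            if copy[j] and blocks[j] == blocks[j - 1]:
                H[:, j] = H[:, j - 1]
        positions[chrom] = pos
        haplos[chrom] = H
        block_of[chrom] = ((pos - 1) // config.block_length).astype(np.int64)
        n_blocks[chrom] = int(np.ceil(length / config.block_length))
    return FounderPanel(
        chroms=chroms,
        positions=positions,
        haplotypes=haplos,
        block_of=block_of,
        n_blocks=n_blocks,
        n_founders=config.n_founders,
        block_length=config.block_length,
    )


def _blocks_overlapping(panel: FounderPanel, chrom: str, start: int, end: int) -> np.ndarray:
    bl = panel.block_length
    first = start // bl
    last = (end - 1) // bl
    return np.arange(first, min(last + 1, panel.n_blocks[chrom]))


def simulate_population(
    panel: FounderPanel, config: SimConfig
) -> Tuple[GenotypeTable, TruthSet]:
    """Draw the sample haplotypes/genotypes and record ground truth."""
    if any(n <= 0 for n in config.group_sizes.values()):
        raise ValueError("all group sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    K = panel.n_founders
    truth = TruthSet()

    divergence = config.species_divergence
    # per-group panel view: lineage-private fixed allele flips
    flips = {
        g: {
            c: rng.random(len(panel.positions[c])) < divergence.get(g, 0.0)
            for c in panel.chroms
        }
        for g in config.group_sizes
    }

    def group_panel(g: str, c: str) -> np.ndarray:
        return panel.haplotypes[c] ^ flips[g][c][None, :]

    # group-specific founder weights per (chrom, block); cultivated groups
    # drift from a common domesticated ancestor rather than from the base
    def _perturb(base, F):
        if F <= 0:
            return base.copy()
        w = rng.dirichlet(np.clip(base, 1e-9, None) * (1.0 - F) / F)
        return np.clip(w, 1e-12, None) / np.clip(w, 1e-12, None).sum()

    base = np.full(K, 1.0 / K)
    weights = {g: {} for g in config.group_sizes}
    for c in panel.chroms:
        ancestors = [
            _perturb(base, config.domestication_drift)
            for _ in range(panel.n_blocks[c])
        ]
        for g in config.group_sizes:
            F_g = config.drift.get(g, 0.3)
            if g == config.wild_group:
                weights[g][c] = np.stack(
                    [_perturb(base, F_g) for _ in range(panel.n_blocks[c])]
                )
            else:
                weights[g][c] = np.stack(
                    [_perturb(anc, F_g) for anc in ancestors]
                )

    # sweeps: affected cultivated groups share a reduced founder subset
    for sw in config.sweeps:
        affected = sw.groups if sw.groups is not None else config.cultivated_groups
        n_keep = max(1, int(np.ceil((1.0 - sw.reduction) * K - 1e-12)))
        for b in _blocks_overlapping(panel, sw.chrom, sw.start, sw.end):
            keep = rng.choice(K, size=n_keep, replace=False)
            for g in affected:
                w = np.zeros(K)
                w[keep] = weights[g][sw.chrom][b][keep] + 1e-9
                weights[g][sw.chrom][b] = w / w.sum()
        truth.sweep_regions.append(
            {"chrom": sw.chrom, "start": sw.start, "end": sw.end,
             "groups": list(affected), "reduction": sw.reduction}
        )

    sample_ids = config.sample_ids()
    groups = {}
    for g, n in config.group_sizes.items():
        for i in range(n):
            groups[f"{g}_{i:03d}"] = g
    n_samples = len(sample_ids)

    hap_chrom = {}
    for c in panel.chroms:
        m = len(panel.positions[c])
        hap = np.zeros((n_samples, m, 2), dtype=np.int8)
        row0 = 0
        for g, n in config.group_sizes.items():
            H = group_panel(g, c)
            rows = slice(row0, row0 + n)
            sub = hap[rows]  # view into hap
            for b in range(panel.n_blocks[c]):
                cols = (panel.block_of[c] == b).nonzero()[0]
                if cols.size == 0:
                    continue
                idx = rng.choice(K, size=(n, 2), p=weights[g][c][b])
                selfed = rng.random(n) < config.selfing_rate
                idx[selfed, 1] = idx[selfed, 0]
                sub[:, cols, 0] = H[idx[:, 0]][:, cols]
                sub[:, cols, 1] = H[idx[:, 1]][:, cols]
            row0 += n
        hap_chrom[c] = hap

    # introgression tracts: recipients redraw from the donor pool
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    for intro in config.introgressions:
        if intro.donor_group not in config.group_sizes:
            raise ValueError(f"unknown donor group {intro.donor_group}")
        c = intro.chrom
        for b in _blocks_overlapping(panel, c, intro.start, intro.end):
            vmask = panel.block_of[c] == b
            if not vmask.any():
                continue
            Hd = group_panel(intro.donor_group, c)
            for s in intro.recipients:
                si = sample_index[s]
                idx = rng.choice(K, size=2, p=weights[intro.donor_group][c][b])
                if rng.random() < config.selfing_rate:
                    idx[1] = idx[0]
                hap_chrom[c][si, vmask, 0] = Hd[idx[0]][vmask]
                hap_chrom[c][si, vmask, 1] = Hd[idx[1]][vmask]
        for s in intro.recipients:
            truth.introgression_tracts.append(
                {"sample": s, "donor": intro.donor_group, "chrom": c,
                 "start": intro.start, "end": intro.end}
            )

    haplotypes = np.concatenate([hap_chrom[c] for c in panel.chroms], axis=1)
    if config.error_rate > 0:
        err = rng.random(haplotypes.shape) < config.error_rate
        haplotypes = haplotypes ^ err
    chrom_arr = np.concatenate(
        [np.full(len(panel.positions[c]), c, dtype=object) for c in panel.chroms]
    )
    pos_arr = np.concatenate([panel.positions[c] for c in panel.chroms])
    genotypes = haplotypes.sum(axis=2).astype(np.int8)

    lo, hi = config.missing_rate_range
    if hi > 0:
        site_rate = rng.uniform(lo, hi, size=genotypes.shape[1])
        mask = rng.random(genotypes.shape) < site_rate
        genotypes[mask] = MISSING
        haplotypes[mask] = 0  # haplotype info is lost at missing calls

    vids = [f"{c}_{p}" for c, p in zip(chrom_arr, pos_arr)]
    gt = GenotypeTable(sample_ids, vids, chrom_arr, pos_arr, genotypes,
                       haplotypes=haplotypes, groups=groups)
    return gt, truth


def simulate_expression(
    gt: GenotypeTable, config: SimConfig, truth: Optional[TruthSet] = None
) -> Tuple[ExpressionTable, TruthSet]:
    """Simulate the cis/trans expression architecture on log2 scale."""
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    truth = TruthSet() if truth is None else truth
    # anchors must segregate in the cultivated mapping panel (expression
    # mapping excludes the wild group), else cis effects are untestable
    cult_idx = np.asarray(
        [i for i, s in enumerate(gt.sample_ids)
         if gt.groups.get(s) != config.wild_group],
        dtype=np.int64,
    )
    panel_view = gt.take_samples(cult_idx) if cult_idx.size >= 2 else gt
    testable = np.nonzero(panel_view.maf() >= 0.05)[0]
    if testable.size == 0:
        raise ValueError("no polymorphic variants to anchor genes on")
    n_genes = min(config.n_genes, testable.size)
    anchors = testable[
        np.linspace(0, testable.size - 1, n_genes).round().astype(int)
    ]
    anchors = np.unique(anchors)
    n_genes = len(anchors)
    gene_ids = [f"G{j:05d}" for j in range(n_genes)]
    annotations = {}
    chrom_len = dict(config.chrom_lengths)
    for j, v in enumerate(anchors):
        c = gt.chrom[v]
        p0 = int(gt.pos[v]) - 1
        start = max(0, p0 - 500)
        end = min(chrom_len.get(c, p0 + 1501), p0 + 1501)
        annotations[gene_ids[j]] = GeneAnnotation(gene_ids[j], c, start, end)

    n_cis = int(round(config.cis_fraction * n_genes))
    cis_genes = rng.choice(n_genes, size=n_cis, replace=False)
    beta = np.zeros(n_genes)
    beta[cis_genes] = config.beta_cis * rng.choice([-1.0, 1.0], size=n_cis)
    masters = rng.choice(cis_genes, size=min(config.n_masters, n_cis), replace=False)

    # mean-imputed, centered genotype dosages at anchors
    G = gt.genotypes[:, anchors].astype(float)
    miss = G == MISSING
    G[miss] = np.nan
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    G = np.where(np.isnan(G), col_mean[None, :], G)
    Gc = G - G.mean(axis=0)

    mu = rng.normal(config.mu_mean, config.mu_sd, size=n_genes)
    eps = rng.normal(0.0, config.noise_sd, size=(n_genes, gt.n_samples))
    y = mu[:, None] + beta[:, None] * Gc.T[np.arange(n_genes)] + eps

    # master-regulator trans effects driven by the master's own expression;
    # targets sit far from the master so their eQTLs are genuinely distant
    target_map = {}
    for m in masters:
        pool = np.setdiff1d(np.arange(n_genes), np.concatenate([[m], masters]))
        far = np.array(
            [
                j for j in pool
                if gt.chrom[anchors[j]] != gt.chrom[anchors[m]]
                or abs(int(gt.pos[anchors[j]]) - int(gt.pos[anchors[m]])) > 2_000_000
            ],
            dtype=np.int64,
        )
        pool = far if far.size else pool
        targets = rng.choice(pool, size=min(config.master_targets, len(pool)),
                             replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(targets))
        r_m = y[m] - y[m].mean()
        for t, s in zip(targets, signs):
            y[t] = y[t] + s * config.beta_trans * r_m
        target_map[m] = list(zip(targets, signs))

    values = np.clip(2.0 ** y - 1.0, 0.0, None)
    expr = ExpressionTable(gene_ids, list(gt.sample_ids), values,
                           gene_annotations=annotations)

    for j in cis_genes:
        truth.eqtls.append(
            {"gene": gene_ids[j], "variant": gt.variant_ids[anchors[j]],
             "kind": "local", "beta": float(beta[j])}
        )
    for m, targets in target_map.items():
        for t, s in targets:
            truth.eqtls.append(
                {"gene": gene_ids[t], "variant": gt.variant_ids[anchors[m]],
                 "kind": "distant", "beta": float(s * config.beta_trans)}
            )
        truth.masters.append(
            {"gene": gene_ids[m], "variant": gt.variant_ids[anchors[m]],
             "targets": [gene_ids[t] for t, _ in targets]}
        )
    return expr, truth


def simulate_trait(
    expression: ExpressionTable,
    gt: GenotypeTable,
    config: SimConfig,
    truth: Optional[TruthSet] = None,
) -> Tuple[np.ndarray, TruthSet]:
    """Liability-threshold binary trait from a handful of causal variants."""
    spec = config.trait
    if spec.n_causal < 1:
        raise ValueError("at least one causal locus required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    truth = TruthSet() if truth is None else truth

    # causal loci must segregate in the cultivated panel the trait is mapped on
    cult_idx = np.asarray(
        [i for i, s in enumerate(gt.sample_ids)
         if gt.groups.get(s) != config.wild_group],
        dtype=np.int64,
    )
    panel_view = gt.take_samples(cult_idx) if cult_idx.size >= 2 else gt
    maf = panel_view.maf()
    eligible = np.nonzero(maf >= spec.maf_min)[0]
    if len(eligible) < spec.n_causal:
        raise ValueError("not enough variants above trait maf_min")
    # favor causal variants that segregate across (not between) subgroups:
    # traits like leaf color vary within every horticultural type, so their
    # loci are weakly confounded with structure
    groups_of = [panel_view.groups.get(s) for s in panel_view.sample_ids]
    labels = sorted({g for g in groups_of if g is not None})
    if len(labels) >= 2:
        freqs = []
        for g in labels:
            gi = np.asarray([k for k, gg in enumerate(groups_of) if gg == g])
            sub = panel_view.genotypes[gi][:, eligible].astype(float)
            sub[sub == MISSING] = np.nan
            freqs.append(np.nanmean(sub, axis=0) / 2.0)
        spread = np.nanstd(np.stack(freqs), axis=0)
        order = np.argsort(spread, kind="stable")
        eligible = np.sort(eligible[order[: max(spec.n_causal, len(eligible) // 2)]])
    # spread causal loci out to keep them quasi-independent
    picks = eligible[np.linspace(0, len(eligible) - 1, spec.n_causal).round().astype(int)]

    X = gt.genotypes[:, picks].astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu[None, :], X) - mu[None, :]
    liability = X @ np.full(spec.n_causal, spec.effect) + rng.normal(size=gt.n_samples)
    thr = (
        spec.threshold
        if spec.threshold is not None
        else float(np.quantile(liability, 1.0 - spec.prevalence))
    )
    phenotype = (liability > thr).astype(int)
    truth.trait_loci = [gt.variant_ids[v] for v in picks]
    truth.trait_prevalence = float(phenotype.mean())
    return phenotype, truth


def simulate_all(config: SimConfig):
    """Run the full generator: genotypes, expression, trait, truth."""
    panel = simulate_founder_haplotypes(config)
    gt, truth = simulate_population(panel, config)
    expr, truth = simulate_expression(gt, config, truth)
    pheno, truth = simulate_trait(expr, gt, config, truth)
    return gt, expr, pheno, truth
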