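"""Seeded end-to-end benchmark flows with known ground truth.

Each function runs one stage of the pipeline on data from the synthetic
generator and scores it against the generator's truth tracks. The problem
sizes are reduced relative to the generator's study-scale defaults (they
keep the per-window SNP density, LD scale, group structure and sample
sizes, but shrink the genome) so a full benchmark pass stays in the
minutes range; docs/methods.md lists the exact geometries.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .assoc import (
    bn_kinship,
    emma_reml,
    group_significant_snps,
    lmm_scan,
    quantile_transform,
    significance_thresholds,
)
from .containers import Region
from .eqtlnet import EqtlBlock, hotspot_scan, make_blocks, master_regulators
from .introgression import scan_sample
from .popstats import WindowSpec, pi_ratio, window_fst, window_pi
from .selscan import domestication_scan
from .simulate import (
    IntrogressionSpec,
    SimConfig,
    SweepSpec,
    simulate_expression,
    simulate_founder_haplotypes,
    simulate_population,
    simulate_trait,
)


def _cultivated_panel(gt, expr=None, maf_min=0.05):
    """Subset to the cultivated mapping panel and testable variants."""
    cult = np.asarray(
        [i for i, s in enumerate(gt.sample_ids) if gt.groups[s] != "serriola"],
        dtype=np.int64,
    )
    sub = gt.take_samples(cult)
    keep = np.nonzero(sub.maf() >= maf_min)[0]
    sub = sub.take_variants(keep)
    if expr is None:
        return sub, None
    return sub, expr.take_samples(cult)


def _pool_cultivated(gt, wild="serriola"):
    gt.groups = {s: ("cult" if g != wild else g) for s, g in gt.groups.items()}
    return gt


def cis_eqtl_recall(seed: int, n_genes_tested: int = 40) -> dict:
    """Fraction of expressed genes with a strong cis effect whose called
    locus overlaps the causal variant."""
    cfg = SimConfig(
        seed=seed, n_variants=6600, n_genes=200,
        chrom_lengths={"LG1": 10_000_000, "LG2": 10_000_000},
        missing_rate_range=(0.0, 0.1),
    )
    gt, truth = simulate_population(simulate_founder_haplotypes(cfg), cfg)
    expr, truth = simulate_expression(gt, cfg, truth)
    gtc, exprc = _cultivated_panel(gt, expr)
    expressed = np.median(exprc.values, axis=1) > 0
    K = bn_kinship(gtc)
    thr_p, _ = significance_thresholds(gtc.n_variants, 0.05)
    vindex = {v: i for i, v in enumerate(gtc.variant_ids)}
    cis = [
        e for e in truth.eqtls
        if e["kind"] == "local" and e["variant"] in vindex
        and expressed[exprc.gene_ids.index(e["gene"])]
    ][:n_genes_tested]
    hits = 0
    for e in cis:
        j = vindex[e["variant"]]
        y = quantile_transform(np.log2(exprc.row(e["gene"]) + 1.0))
        loci = group_significant_snps(lmm_scan(y, None, K, gtc), gtc, thr_p)
        hits += any(
            l.region.chrom == gtc.chrom[j]
            and l.region.start <= gtc.pos[j] - 1 < l.region.end
            for l in loci
        )
    return {"recall": hits / len(cis), "n": len(cis)}


def sweep_recovery(seeds) -> dict:
    """Fraction of implanted sweeps overlapped by a domestication-scan call."""
    hits = 0
    true_reg = Region("LG1", 4_000_000, 4_400_000)
    spec = WindowSpec(20_000, 10_000)
    for seed in seeds:
        cfg = SimConfig(
            seed=seed, n_variants=5_000, n_genes=10,
            chrom_lengths={"LG1": 10_000_000, "LG2": 10_000_000},
            sweeps=[SweepSpec("LG1", 4_000_000, 4_400_000, reduction=0.9)],
            missing_rate_range=(0.0, 0.1),
        )
        gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        gt = _pool_cultivated(gt)
        ratio = pi_ratio(
            window_pi(gt, "serriola", spec, cfg.chrom_lengths),
            window_pi(gt, "cult", spec, cfg.chrom_lengths),
        )
        _, win = window_fst(gt, "serriola", "cult", spec, cfg.chrom_lengths)
        call = domestication_scan(win.rename(columns={"fst": "score"}), ratio)
        hits += any(r.overlaps(true_reg) for r in call.regions)
    return {"rate": hits / len(seeds), "n": len(seeds)}


def _introgression_cfg(seed):
    return SimConfig(
        seed=seed, n_variants=6_600, n_genes=10,
        chrom_lengths={"LG1": 10_000_000, "LG2": 10_000_000},
        group_sizes={"serriola": 20, "saligna": 14, "butterhead": 45, "stem": 45},
        drift={"serriola": 0.1, "saligna": 0.5, "butterhead": 0.35, "stem": 0.35},
        species_divergence={"saligna": 0.65},
        introgressions=[
            IntrogressionSpec(["stem_000"], "saligna", "LG2", 3_000_000, 3_600_000)
        ],
        missing_rate_range=(0.0, 0.1),
    )


def introgression_recovery(seeds) -> dict:
    """Tract recovery rate for the carrier and confirmed-call genome fraction
    for a non-carrier (false-positive) sample."""
    true_reg = Region("LG2", 3_000_000, 3_600_000)
    genome = 20_000_000
    hits, fp_bp = 0, 0
    for seed in seeds:
        cfg = _introgression_cfg(seed)
        gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        gt.groups = {
            s: ("cult" if g in ("butterhead", "stem") else g)
            for s, g in gt.groups.items()
        }
        res = scan_sample(gt, "stem_000", "cult", "saligna",
                          chrom_lengths=cfg.chrom_lengths)
        hits += any(c.region.overlaps(true_reg) for c in res)
        null = scan_sample(gt, "stem_010", "cult", "saligna",
                           chrom_lengths=cfg.chrom_lengths)
        fp_bp += sum(c.region.length for c in null)
    return {
        "rate": hits / len(seeds),
        "false_positive_fraction": fp_bp / (len(seeds) * genome),
        "n": len(seeds),
    }


def master_regulator_pr(seeds) -> dict:
    """Precision/recall of master-regulator candidates vs simulated truth."""
    tps, n_called, n_true = 0, 0, 0
    for seed in seeds:
        cfg = SimConfig(
            seed=seed, n_variants=10_000, n_genes=150,
            n_masters=2, master_targets=40,
            chrom_lengths={"LG1": 25_000_000, "LG2": 25_000_000},
            missing_rate_range=(0.0, 0.1),
        )
        gt, truth = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        expr, truth = simulate_expression(gt, cfg, truth)
        gtc, exprc = _cultivated_panel(gt, expr)
        expressed = np.median(exprc.values, axis=1) > 0
        K = bn_kinship(gtc)
        thr_p, _ = significance_thresholds(gtc.n_variants, 0.05)
        vindex = {v: i for i, v in enumerate(gtc.variant_ids)}
        snp_positions = {v: (gtc.chrom[j], int(gtc.pos[j]))
                         for v, j in vindex.items()}
        blocks = []
        for gi, gid in enumerate(exprc.gene_ids):
            if not expressed[gi]:
                continue
            y = quantile_transform(np.log2(exprc.values[gi] + 1.0))
            loci = group_significant_snps(lmm_scan(y, None, K, gtc), gtc, thr_p)
            blocks += make_blocks(gid, loci, exprc.gene_annotations[gid])
        hs = hotspot_scan([b for b in blocks if b.classification == "distant"],
                          cfg.chrom_lengths, snp_positions)
        cands = master_regulators(hs, blocks, exprc, snp_positions=snp_positions)
        called = {c.gene_id for c in cands}
        true_m = {m["gene"] for m in truth.masters}
        tps += len(called & true_m)
        n_called += len(called)
        n_true += len(true_m)
    return {
        "precision": tps / n_called if n_called else float("nan"),
        "recall": tps / n_true,
        "n": len(seeds),
    }


def h2_recovery(seed: int, n_reps: int = 200, h2_true: float = 0.5) -> dict:
    """Mean REML pseudo-heritability over replicate responses drawn with
    equal genetic and residual variance components."""
    cfg = SimConfig(
        seed=seed, n_variants=3_000, n_genes=10,
        chrom_lengths={"LG1": 10_000_000, "LG2": 10_000_000},
        missing_rate_range=(0.0, 0.1),
    )
    gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
    K = bn_kinship(gt)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0, None)
    lam = h2_true / (1.0 - h2_true)
    rng = np.random.default_rng(seed + 1)
    h2s = []
    for _ in range(n_reps):
        y = (np.sqrt(lam) * (U @ (np.sqrt(w) * rng.normal(size=len(K))))
             + rng.normal(size=len(K)))
        h2s.append(emma_reml(y, None, K).h2)
    return {"mean_h2": float(np.mean(h2s)), "n": n_reps}


def lmm_null_calibration(seed: int, n_perm: int = 250, snps_per_perm: int = 40) -> dict:
    """KS uniformity of mixed-model p-values over the permutation null.

    Each permutation of the phenotype contributes a disjoint set of widely
    spaced SNPs, so the pooled p-values estimate the marginal null
    distribution rather than one permutation's (strongly cross-dependent)
    scan.
    """
    cfg = SimConfig(
        seed=seed, n_variants=14_000, n_genes=10,
        chrom_lengths={"LG1": 20_000_000, "LG2": 20_000_000},
        missing_rate_range=(0.0, 0.1),
    )
    gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
    g, _ = _cultivated_panel(gt)
    K = bn_kinship(g)
    labels = sorted(set(g.groups.values()))
    C = np.column_stack(
        [[1.0 if g.groups[s] == lab else 0.0 for s in g.sample_ids]
         for lab in labels[:-1]]
    )
    rng = np.random.default_rng(seed + 1)
    base = np.log2(1.0 + rng.gamma(2, 2, size=g.n_samples))
    stride = g.n_variants // snps_per_perm
    pooled = []
    for _ in range(n_perm):
        y = quantile_transform(rng.permutation(base))
        offset = int(rng.integers(0, stride))
        idx = np.sort((offset + np.arange(snps_per_perm) * stride) % g.n_variants)
        res = lmm_scan(y, C, K, g.take_variants(idx))
        pooled.append(res.p.dropna().to_numpy())
    p = np.concatenate(pooled)
    ks = sps.kstest(p, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "ks_D": float(ks.statistic),
            "frac_below_05": float((p < 0.05).mean()), "n": len(p)}


def hotspot_null_fp(seed: int, n_reps: int = 20, n_eqtls: int = 200) -> dict:
    """Hotspots called on uniformly placed distant eQTLs (false positives)."""
    from .assoc import SignificantLocus

    chrom_lengths = {"LG1": 20_000_000, "LG2": 20_000_000}
    total = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        blocks, pos_map = [], {}
        for i in range(n_eqtls):
            c = "LG1" if rng.random() < 0.5 else "LG2"
            p = int(rng.integers(1, chrom_lengths[c]))
            vid = f"v{i}"
            pos_map[vid] = (c, p)
            blocks.append(
                EqtlBlock(
                    f"g{i}",
                    SignificantLocus(Region(c, max(0, p - 1), p + 1),
                                     [vid, "a", "b"], vid, 8.0),
                    "distant",
                )
            )
        total += len(hotspot_scan(blocks, chrom_lengths, pos_map))
    return {"hotspots": total, "n": n_reps}


def trait_gwas_recovery(seeds, proximity_bp: int = 100_000) -> dict:
    """Causal loci with a suggestive-threshold signal nearby, per replicate."""
    recovered, totals = 0, 0
    for seed in seeds:
        cfg = SimConfig(
            seed=seed, n_variants=6_000, n_genes=60,
            chrom_lengths={"LG1": 15_000_000, "LG2": 15_000_000},
            missing_rate_range=(0.0, 0.1),
        )
        gt, truth = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        expr, truth = simulate_expression(gt, cfg, truth)
        pheno, truth = simulate_trait(expr, gt, cfg, truth)
        cult = np.asarray(
            [i for i, s in enumerate(gt.sample_ids) if gt.groups[s] != "serriola"]
        )
        gtc = gt.take_samples(cult)
        gtc = gtc.take_variants(np.nonzero(gtc.maf() >= 0.05)[0])
        K = bn_kinship(gtc)
        res = lmm_scan(pheno[cult].astype(float), None, K, gtc)
        sugg_p, _ = significance_thresholds(gtc.n_variants, 1.0)
        vindex = {v: i for i, v in enumerate(gtc.variant_ids)}
        for v in truth.trait_loci:
            if v not in vindex:
                continue
            j = vindex[v]
            near = (
                (res.chrom == gtc.chrom[j])
                & (np.abs(res.pos - gtc.pos[j]) <= proximity_bp)
                & (res.p <= sugg_p)
            )
            totals += 1
            recovered += bool(near.any())
    return {"recovered": recovered, "total": totals, "n": len(seeds)}
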