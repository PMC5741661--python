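"""Per-sample introgression scan and neighbor-joining confirmation.

For each cultivated focal sample, the scan slides 200-kb windows (20-kb
step) and counts, over homozygous calls only, how often the focal genotype
matches the cultivated-group consensus versus the candidate donor group's
consensus. A window ratio (cultivated matches / donor matches) at or below
0.5 with at least 20 informative SNPs marks a candidate; overlapping
candidate windows merge into regions. Each region is then checked on a
neighbor-joining tree built from identity-by-state distances: the call is
confirmed when the focal sample nests inside the donor clade. Confirmed
regions closer than 200 kb are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeTable, Region, merge_overlapping
from .popstats import WindowSpec, chrom_lengths_from, window_grid


@dataclass
class IntrogressionCandidate:
    """One candidate (or confirmed) introgressed region for one sample."""

    sample_id: str
    donor_group: str
    region: Region
    confirmed: Optional[bool] = None  # None = untested
    newick: Optional[str] = None


def _consensus_hom(g: np.ndarray) -> np.ndarray:
    """Most frequent homozygous genotype (0 or 2) per site; MISSING if none."""
    n0 = (g == 0).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    out = np.full(g.shape[1], MISSING, dtype=np.int8)
    out[n0 > n2] = 0
    out[n2 > n0] = 2
    # ties with at least one call: no unambiguous consensus -> MISSING
    return out


def shared_ratio_scan(
    gt: GenotypeTable,
    focal_sample: str,
    cultivated_group: str,
    donor_group: str,
    spec: WindowSpec = WindowSpec(200_000, 20_000),
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Window ratios of focal matches to cultivated vs donor consensus.

    Only homozygous calls are used; heterozygous and missing genotypes are
    excluded. A window's ratio is C_cult / C_wild over SNPs where the focal
    genotype and both consensuses are defined; NaN when C_wild is 0.
    """
    if gt.groups.get(focal_sample) == donor_group:
        raise ValueError("focal sample must not belong to the donor group")
    fi = gt.sample_ids.index(focal_sample)
    cult_idx = np.array(
        [i for i in gt.sample_indices(cultivated_group) if i != fi], dtype=np.int64
    )
    donor_idx = gt.sample_indices(donor_group)

    focal = gt.genotypes[fi]
    cult_cons = _consensus_hom(gt.genotypes[cult_idx])
    donor_cons = _consensus_hom(gt.genotypes[donor_idx])
    informative = (
        np.isin(focal, (0, 2)) & (cult_cons != MISSING) & (donor_cons != MISSING)
    )
    match_cult = informative & (focal == cult_cons)
    match_donor = informative & (focal == donor_cons)

    grid = window_grid(chrom_lengths or chrom_lengths_from(gt), spec)
    ratios = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for c, sub in grid.groupby("chrom", sort=False):
        cidx = np.nonzero(gt.chrom == c)[0]
        pos0 = gt.pos[cidx] - 1
        inf_c = np.cumsum(np.concatenate([[0], informative[cidx]]))
        mc = np.cumsum(np.concatenate([[0], match_cult[cidx]]))
        md = np.cumsum(np.concatenate([[0], match_donor[cidx]]))
        lo = np.searchsorted(pos0, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, sub["end"].to_numpy(), side="left")
        n_inf = inf_c[hi] - inf_c[lo]
        c_cult = mc[hi] - mc[lo]
        c_wild = md[hi] - md[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(c_wild > 0, c_cult / np.maximum(c_wild, 1), np.nan)
        ratios[sub.index] = r
        counts[sub.index] = n_inf
    out = grid.copy()
    out["ratio"] = ratios
    out["snp_count"] = counts
    out.attrs["focal_sample"] = focal_sample
    out.attrs["donor_group"] = donor_group
    return out


def candidate_regions(
    ratios: pd.DataFrame,
    ratio_max: float = 0.5,
    min_snps: int = 20,
) -> List[IntrogressionCandidate]:
    """Merge qualifying windows (ratio <= ratio_max, snp_count >= min_snps)."""
    qual = (
        (ratios["ratio"].to_numpy() <= ratio_max)
        & (ratios["snp_count"].to_numpy() >= min_snps)
    )
    qual &= np.isfinite(ratios["ratio"].to_numpy())
    marked = [
        Region(row.chrom, int(row.start), int(row.end), stat_name="shared_ratio",
               stat_value=float(row.ratio), support=1)
        for row, m in zip(ratios.itertuples(index=False), qual)
        if m
    ]
    merged = merge_overlapping(marked)
    return [
        IntrogressionCandidate(
            sample_id=ratios.attrs.get("focal_sample", ""),
            donor_group=ratios.attrs.get("donor_group", ""),
            region=r,
        )
        for r in merged
    ]


def ibs_distance_matrix(gt: GenotypeTable, sample_idx: np.ndarray,
                        variant_mask: np.ndarray) -> np.ndarray:
    """1 - mean fraction of shared alleles over co-called SNPs."""
    g = gt.genotypes[np.ix_(sample_idx, np.nonzero(variant_mask)[0])].astype(float)
    g[g == MISSING] = np.nan
    n = len(sample_idx)
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i][None, :] - g)  # 0, 1 or 2 allele differences
        ok = np.isfinite(diff)
        cnt = ok.sum(axis=1)
        if np.any(cnt == 0):
            bad = np.nonzero(cnt == 0)[0]
            for j in bad:
                if j != i:
                    raise ValueError(
                        f"samples {gt.sample_ids[sample_idx[i]]} and "
                        f"{gt.sample_ids[sample_idx[j]]} share no called SNPs"
                    )
        ibs = 1.0 - np.nansum(diff, axis=1) / (2.0 * np.maximum(cnt, 1))
        D[i] = 1.0 - ibs
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def nj_tree(gt: GenotypeTable, region: Region,
            sample_idx: Optional[np.ndarray] = None):
    """Neighbor-joining tree on IBS distances over a region's SNPs.

    Returns a ``skbio.TreeNode``; negative NJ branch lengths are clamped
    to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if sample_idx is None:
        sample_idx = np.arange(gt.n_samples)
    sample_idx = np.asarray(sample_idx, dtype=np.int64)
    if len(sample_idx) < 3:
        raise ValueError("NJ needs >= 3 samples")
    vmask = gt.variant_mask_region(region)
    if not vmask.any():
        raise ValueError("region contains no SNPs")
    D = ibs_distance_matrix(gt, sample_idx, vmask)
    ids = [gt.sample_ids[i] for i in sample_idx]
    tree = nj(DistanceMatrix(D, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def donor_placement(tree, focal: str, donor_group: str, other_groups: set,
                    groups: Dict[str, str]) -> bool:
    """True iff the smallest clade holding the focal leaf and >= 1 donor leaf
    contains no leaf from ``other_groups``.

    The unrooted NJ tree is rooted at the non-donor, non-focal leaf farthest
    from the focal sample before the clade walk.
    """
    names = {t.name for t in tree.tips()}
    if focal not in names:
        raise ValueError(f"focal sample {focal} absent from tree")
    donors = {n for n in names if groups.get(n) == donor_group}
    if len(donors) < 2:
        raise ValueError("need >= 2 donor leaves in the tree")
    outsiders = {
        n for n in names
        if groups.get(n) in other_groups and n != focal
    }
    # root away from the focal/donor side for a meaningful clade walk
    candidates = outsiders or (names - donors - {focal})
    if candidates:
        far = max(candidates, key=lambda n: tree.find(focal).distance(tree.find(n)))
        tree = tree.root_at(tree.find(far).parent)
    node = tree.find(focal)
    while node.parent is not None:
        node = node.parent
        leaves = {t.name for t in node.tips()}
        if leaves & donors:
            return not (leaves & outsiders)
    return False


def scan_sample(
    gt: GenotypeTable,
    focal_sample: str,
    cultivated_group: str,
    donor_group: str,
    spec: WindowSpec = WindowSpec(200_000, 20_000),
    chrom_lengths: Optional[Dict[str, int]] = None,
    ratio_max: float = 0.5,
    min_snps: int = 20,
    confirm: bool = True,
    final_merge_gap: int = 200_000,
    tree_samples: Optional[np.ndarray] = None,
) -> List[IntrogressionCandidate]:
    """Full per-sample pipeline: scan, call, confirm, merge.

    Confirmed regions closer than ``final_merge_gap`` bp are merged; with
    ``confirm=False`` all candidates are returned untested.
    """
    ratios = shared_ratio_scan(gt, focal_sample, cultivated_group, donor_group,
                               spec, chrom_lengths)
    cands = candidate_regions(ratios, ratio_max, min_snps)
    if not confirm:
        return cands
    other_groups = {
        g for g in set(gt.groups.values())
        if g not in (donor_group, cultivated_group)
    }
    confirmed = []
    for cand in cands:
        try:
            tree = nj_tree(gt, cand.region, tree_samples)
            ok = donor_placement(tree, focal_sample, donor_group, other_groups,
                                 gt.groups)
            cand.confirmed = ok
            cand.newick = str(tree)
        except ValueError:
            cand.confirmed = None
        if cand.confirmed:
            confirmed.append(cand)
    merged = merge_overlapping([c.region for c in confirmed], final_merge_gap)
    return [
        IntrogressionCandidate(focal_sample, donor_group, r, confirmed=True)
        for r in merged
    ]
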