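"""eQTL classification, hotspots, master regulators and iGA networks.

An eQTL block is local when its interval overlaps the target gene, distant
otherwise. Distant-eQTL hotspots are found by a sliding-window binomial
scan over lead-SNP positions with Benjamini-Yekutieli control (a
statistically equivalent stand-in for specialized hotspot-scan software:
the window size and the adjustment are the interface that matters here).
Master-regulator candidates must (1) lie inside a hotspot, (2) carry their
own local eQTL, and (3) correlate beyond permutation-derived thresholds
with at least one gene whose distant eQTL maps to that hotspot.

The regulatory network uses iterated group analysis (iGA): genes are ranked
by correlation with a candidate regulator and the probability-of-change
(PC) value is the minimum hypergeometric upper-tail probability over list
prefixes ending at a pathway member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assoc import SignificantLocus
from .containers import ExpressionTable, GeneAnnotation, Region, merge_overlapping


@dataclass
class EqtlBlock:
    """One gene's eQTL block with its local/distant classification."""

    gene_id: str
    locus: SignificantLocus
    classification: str  # "local" | "distant"
    effect_r2: float = float("nan")  # r^2 of lead SNP with transformed expression


@dataclass
class Hotspot:
    region: Region
    count: int
    p_adjusted: float


@dataclass
class RegulatorCandidate:
    gene_id: str
    hotspot: Region
    targets: List[Tuple[str, float]] = field(default_factory=list)  # (gene, pcc)


@dataclass
class RegulatoryNetwork:
    """Directed signed edges regulator -> target with PC values."""

    edges: List[dict] = field(default_factory=list)

    def add(self, regulator: str, target: str, sign: int, pc: float, pcc: float):
        if regulator == target:
            return
        self.edges.append(
            {"regulator": regulator, "target": target, "sign": sign,
             "pc": pc, "pcc": pcc}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges)


def classify_eqtl(locus: SignificantLocus, gene: GeneAnnotation) -> str:
    """'local' iff the locus interval overlaps the gene interval."""
    r = locus.region
    if r.chrom == gene.chrom and r.start < gene.end and gene.start < r.end:
        return "local"
    return "distant"


def make_blocks(
    gene_id: str,
    loci: Sequence[SignificantLocus],
    gene: GeneAnnotation,
    expr_transformed: Optional[np.ndarray] = None,
    lead_dosages: Optional[Dict[str, np.ndarray]] = None,
) -> List[EqtlBlock]:
    """Wrap one gene's loci as classified blocks with effect-size proxies."""
    blocks = []
    for locus in loci:
        r2 = float("nan")
        if expr_transformed is not None and lead_dosages is not None:
            g = lead_dosages.get(locus.lead_snp)
            if g is not None and np.std(g) > 0:
                r2 = float(np.corrcoef(g, expr_transformed)[0, 1] ** 2)
        blocks.append(EqtlBlock(gene_id, locus, classify_eqtl(locus, gene), r2))
    return blocks


def hotspot_scan(
    distant_blocks: Sequence[EqtlBlock],
    chrom_lengths: Dict[str, int],
    snp_positions: Dict[str, Tuple[str, int]],
    window: int = 400_000,
    alpha: float = 0.05,
    step: Optional[int] = None,
) -> List[Hotspot]:
    """Sliding-window binomial scan over distant-eQTL lead positions.

    Each window's count is tested against Binomial(N, window / genome
    length); windows significant after Benjamini-Yekutieli adjustment merge
    into hotspots (count = distinct contributing eQTLs, p = the best
    member-window adjusted p).
    """
    step = window // 10 if step is None else step
    leads = []
    for b in distant_blocks:
        if b.classification != "distant":
            continue
        c, p = snp_positions[b.locus.lead_snp]
        leads.append((c, p))
    if not leads:
        return []
    genome = float(sum(chrom_lengths.values()))
    n_total = len(leads)
    rate = window / genome
    rows = []
    for c, L in chrom_lengths.items():
        pos = np.sort([p for cc, p in leads if cc == c])
        starts = np.arange(0, L, step)
        lo = np.searchsorted(pos, starts + 1, side="left")
        hi = np.searchsorted(pos, np.minimum(starts + window, L), side="right")
        counts = hi - lo
        for s, n in zip(starts, counts):
            rows.append((c, int(s), int(min(s + window, L)), int(n)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    pvals = stats.binom.sf(df["count"] - 1, n_total, rate)
    df["p_adj"] = multipletests(pvals, method="fdr_by")[1]
    sig = df[(df["p_adj"] <= alpha) & (df["count"] > 0)]
    regions = merge_overlapping(
        [
            Region(r.chrom, r.start, r.end, stat_name="hotspot",
                   stat_value=float(-np.log10(max(r.p_adj, 1e-300))),
                   support=int(r.count))
            for r in sig.itertuples(index=False)
        ]
    )
    out = []
    for reg in regions:
        inside = [
            (c, p) for c, p in leads
            if c == reg.chrom and reg.start < p <= reg.end
        ]
        best = sig[
            (sig["chrom"] == reg.chrom)
            & (sig["start"] < reg.end) & (sig["end"] > reg.start)
        ]["p_adj"].min()
        out.append(Hotspot(reg, count=len(inside), p_adjusted=float(best)))
    return out


def log_expression(expr: ExpressionTable) -> np.ndarray:
    """log10(FPKM + 1) matrix used for all correlation work."""
    return np.log10(expr.values + 1.0)


def pcc_threshold(
    expr_log: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permutation null for Pearson correlation between expression profiles.

    Each permutation correlates one randomly chosen gene profile, with its
    sample labels shuffled, against another random gene; the thresholds are
    the upper and lower alpha quantiles of the null distribution (the two
    tails may be asymmetric for skewed expression data).
    """
    if expr_log.shape[1] < 10:
        raise ValueError("need >= 10 samples for permutation thresholds")
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations; thresholds are noisy")
    rng = np.random.default_rng(seed)
    n_genes = expr_log.shape[0]
    null = np.empty(n_perm)
    for t in range(n_perm):
        i, j = rng.integers(0, n_genes, size=2)
        x = rng.permutation(expr_log[i])
        y = expr_log[j]
        if x.std() == 0 or y.std() == 0:
            null[t] = 0.0
        else:
            null[t] = np.corrcoef(x, y)[0, 1]
    return float(np.quantile(null, 1 - alpha)), float(np.quantile(null, alpha))


def _genes_in_region(annotations: Dict[str, GeneAnnotation], region: Region) -> List[str]:
    return [
        g.gene_id
        for g in annotations.values()
        if g.chrom == region.chrom and g.start < region.end and region.start < g.end
    ]


def master_regulators(
    hotspots: Sequence[Hotspot],
    all_blocks: Sequence[EqtlBlock],
    expr: ExpressionTable,
    thresholds: Tuple[float, float] = (0.39, -0.28),
    snp_positions: Optional[Dict[str, Tuple[str, int]]] = None,
) -> List[RegulatorCandidate]:
    """Candidates inside a hotspot, with a local eQTL, correlated with >= 1
    gene whose distant eQTL maps to that hotspot.

    The default correlation thresholds are the operating point used for
    this filter in practice; ``pcc_threshold`` derives data-driven values
    by permutation when preferred (its null is typically narrower, since
    shuffling destroys all shared structure among genes).
    """
    pos_thr, neg_thr = thresholds
    X = log_expression(expr)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    local_genes = {b.gene_id for b in all_blocks if b.classification == "local"}
    out = []
    for hs in hotspots:
        # genes whose distant eQTL lead SNP falls in this hotspot
        targets = []
        for b in all_blocks:
            if b.classification != "distant":
                continue
            c, p = snp_positions[b.locus.lead_snp]
            if c == hs.region.chrom and hs.region.start < p <= hs.region.end:
                targets.append(b.gene_id)
        if not targets:
            continue
        for gid in _genes_in_region(expr.gene_annotations, hs.region):
            if gid not in local_genes or gid not in gene_index:
                continue
            xg = X[gene_index[gid]]
            found = []
            for t in targets:
                if t == gid or t not in gene_index:
                    continue
                xt = X[gene_index[t]]
                if xg.std() == 0 or xt.std() == 0:
                    continue
                r = float(np.corrcoef(xg, xt)[0, 1])
                if r >= pos_thr or r <= neg_thr:
                    found.append((t, r))
            if found:
                out.append(RegulatorCandidate(gid, hs.region, found))
    return out


def iga_pc(ranked_gene_list: Sequence[str], group_members: Iterable[str]):
    """Probability-of-change: minimum hypergeometric upper tail over
    prefixes ending at a group member.

    Returns ``(pc, prefix_length)`` where the prefix realizes the minimum.
    """
    members = set(group_members)
    if not members:
        raise ValueError("empty group")
    N = len(ranked_gene_list)
    G = len(members & set(ranked_gene_list))
    if G == 0:
        raise ValueError("no group member present in the ranked list")
    best_pc, best_d = 1.0, N
    g = 0
    for d, gene in enumerate(ranked_gene_list, start=1):
        if gene in members:
            g += 1
            pc = float(stats.hypergeom.sf(g - 1, N, G, d))
            if pc < best_pc:
                best_pc, best_d = pc, d
    return best_pc, best_d


def build_network(
    pathway_blocks: Sequence[EqtlBlock],
    pathway_genes: Sequence[str],
    expr: ExpressionTable,
    pc_alpha: float = 0.01,
) -> Tuple[RegulatoryNetwork, List[Region]]:
    """iGA regulatory network over merged distant-eQTL regions of a pathway.

    Distant-eQTL regions of pathway genes are merged; every expressed gene
    in a merged region is tested in both correlation directions against the
    region's pathway targets, and kept as a regulator when its PC value is
    below ``pc_alpha`` / (expressed genes in the region). Edges carry the
    correlation sign and go to the group members inside the optimal prefix.
    """
    pathway = set(pathway_genes)
    distant = [
        b for b in pathway_blocks
        if b.classification == "distant" and b.gene_id in pathway
    ]
    merged = merge_overlapping([b.locus.region for b in distant])
    net = RegulatoryNetwork()
    X = log_expression(expr)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    all_genes = list(expr.gene_ids)
    for region in merged:
        targets = {
            b.gene_id for b in distant if b.locus.region.overlaps(region)
        }
        region_genes = [
            g for g in _genes_in_region(expr.gene_annotations, region)
            if g in gene_index
        ]
        if not region_genes or not targets:
            continue
        pc_cut = pc_alpha / len(region_genes)
        for gid in region_genes:
            xg = X[gene_index[gid]]
            if xg.std() == 0:
                continue
            with np.errstate(invalid="ignore"):
                pcc = np.array(
                    [
                        np.corrcoef(xg, X[gene_index[t]])[0, 1]
                        if X[gene_index[t]].std() > 0 else np.nan
                        for t in all_genes
                    ]
                )
            order = np.argsort(np.nan_to_num(pcc, nan=-np.inf))
            universe = [g for g in all_genes if g != gid]
            group = targets - {gid}
            if not group:
                continue
            for sign, ranked_idx in ((+1, order[::-1]), (-1, order)):
                ranked = [all_genes[k] for k in ranked_idx if all_genes[k] != gid]
                pc, d = iga_pc(ranked, group)
                if pc < pc_cut:
                    prefix = set(ranked[:d])
                    for t in sorted(group & prefix):
                        net.add(gid, t, sign, pc, float(pcc[gene_index[t]]))
    return net, merged


def seed_expansion(
    seed_genes: Sequence[str],
    expr: ExpressionTable,
    pcc_abs_min: Optional[float] = None,
    min_seed_links: int = 3,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> List[str]:
    """Genes correlated (|PCC| above the permutation threshold) with at
    least ``min_seed_links`` seed genes."""
    seeds = [g for g in seed_genes if g in expr.gene_ids]
    if not seeds:
        raise ValueError("no seed gene present in the expression table")
    X = log_expression(expr)
    if pcc_abs_min is None:
        pos, neg = pcc_threshold(X, n_perm=n_perm, alpha=alpha, seed=seed)
        pcc_abs_min = max(abs(pos), abs(neg))
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    S = X[[gene_index[g] for g in seeds]]
    out = []
    for g in expr.gene_ids:
        if g in seeds:
            continue
        xg = X[gene_index[g]]
        if xg.std() == 0:
            continue
        links = 0
        for srow in S:
            if srow.std() == 0:
                continue
            if abs(np.corrcoef(xg, srow)[0, 1]) > pcc_abs_min:
                links += 1
        if links >= min_seed_links:
            out.append(g)
    return out
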