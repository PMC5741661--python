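"""Windowed diversity, differentiation, LD and expression-variability stats.

Window tracks are plain DataFrames with columns ``chrom, start, end`` plus
the statistic, on a sliding grid (default 20 kb windows, 10 kb step for
diversity; the sweep callers use the same grids). Nucleotide diversity is
normalized per window length by default; a callable-length override exists
because transcriptome-derived SNPs cover only genic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .containers import MISSING, ExpressionTable, GenotypeTable


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp."""

    size: int = 20_000
    step: int = 10_000

    def __post_init__(self):
        if self.size <= 0 or self.step <= 0 or self.step > self.size:
            raise ValueError("need 0 < step <= size")


def chrom_lengths_from(gt: GenotypeTable) -> Dict[str, int]:
    """Fallback chromosome lengths: max observed position per chromosome."""
    out = {}
    for c in dict.fromkeys(gt.chrom):
        out[c] = int(gt.pos[gt.chrom == c].max())
    return out


def window_grid(chrom_lengths: Dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """All windows [k*step, k*step+size) with start < chromosome length."""
    rows = []
    for c, L in chrom_lengths.items():
        starts = np.arange(0, L, spec.step)
        for s in starts:
            rows.append((c, int(s), int(min(s + spec.size, L))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _site_index(gt: GenotypeTable):
    """Per-chromosome sorted 0-based positions and variant indices."""
    out = {}
    for c in dict.fromkeys(gt.chrom):
        idx = np.nonzero(gt.chrom == c)[0]
        out[c] = (gt.pos[idx] - 1, idx)
    return out


def _window_sum(gt, per_site: np.ndarray, grid: pd.DataFrame) -> np.ndarray:
    """Sum a per-site statistic over each window of the grid."""
    sums = np.zeros(len(grid))
    by_chrom = _site_index(gt)
    for c, sub in grid.groupby("chrom", sort=False):
        if c not in by_chrom:
            continue
        pos0, idx = by_chrom[c]
        vals = per_site[idx]
        lo = np.searchsorted(pos0, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, sub["end"].to_numpy(), side="left")
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        sums[sub.index] = csum[hi] - csum[lo]
    return sums


def site_pi(gt: GenotypeTable, sample_idx: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity n/(n-1) * 2p(1-p); NaN if n < 2."""
    g = gt.genotypes[sample_idx]
    obs = g != MISSING
    n = 2 * obs.sum(axis=0)
    alt = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n
        pi = n / (n - 1) * 2.0 * p * (1.0 - p)
    pi[n < 2] = np.nan
    return pi


def window_pi(
    gt: GenotypeTable,
    group: str,
    spec: WindowSpec = WindowSpec(),
    chrom_lengths: Optional[Dict[str, int]] = None,
    callable_length: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-window nucleotide diversity (per bp) for one group."""
    sample_idx = gt.sample_indices(group)
    if len(sample_idx) < 2:
        raise ValueError(f"group {group} needs >= 2 samples")
    grid = window_grid(chrom_lengths or chrom_lengths_from(gt), spec)
    per_site = np.nan_to_num(site_pi(gt, sample_idx), nan=0.0)
    sums = _window_sum(gt, per_site, grid)
    denom = (
        np.asarray(callable_length, dtype=float)
        if callable_length is not None
        else (grid["end"] - grid["start"]).to_numpy(dtype=float)
    )
    out = grid.copy()
    out["pi"] = sums / denom
    out.attrs["group"] = group
    return out


def pi_ratio(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window ratio pi_a / pi_b; windows with pi_b == 0 flagged NaN."""
    for col in ("chrom", "start", "end"):
        if not track_a[col].equals(track_b[col]):
            raise ValueError("window grids differ between tracks")
    out = track_a[["chrom", "start", "end"]].copy()
    pa = track_a["pi"].to_numpy()
    pb = track_b["pi"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pa / pb
    ratio[pb == 0] = np.nan
    out["ratio"] = ratio
    return out


def wc_fst_components(gt: GenotypeTable, idx_a: np.ndarray, idx_b: np.ndarray):
    """Weir-Cockerham (1984) variance components a, b, c per SNP, r = 2."""
    comps = []
    for idx in (idx_a, idx_b):
        g = gt.genotypes[idx]
        obs = g != MISSING
        n_i = obs.sum(axis=0).astype(float)
        alt = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = alt / (2 * n_i)
            h_i = np.where(obs, g == 1, False).sum(axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    valid = (n1 >= 2) & (n2 >= 2)
    # sites monomorphic across both groups carry no information
    poly = ~((p_bar == 0) | (p_bar == 1))
    valid &= poly
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def hudson_fst_components(gt: GenotypeTable, idx_a, idx_b):
    """Hudson estimator numerator/denominator per SNP."""
    comps = []
    for idx in (idx_a, idx_b):
        g = gt.genotypes[idx]
        obs = g != MISSING
        n = (2 * obs.sum(axis=0)).astype(float)
        alt = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / n
        comps.append((n, p))
    (n1, p1), (n2, p2) = comps
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    valid = (n1 >= 4) & (n2 >= 4) & (den > 0)
    num[~valid] = np.nan
    den[~valid] = np.nan
    return num, den


def window_fst(
    gt: GenotypeTable,
    group_a: str,
    group_b: str,
    spec: WindowSpec = WindowSpec(),
    chrom_lengths: Optional[Dict[str, int]] = None,
    estimator: str = "wc",
):
    """Per-SNP and per-window Fst between two groups.

    Returns ``(per_snp, per_window)``; the window value is the ratio of
    summed variance components (WC) or summed numerator/denominator
    (Hudson), not the mean of ratios.
    """
    idx_a, idx_b = gt.sample_indices(group_a), gt.sample_indices(group_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if estimator == "wc":
        a, b, c = wc_fst_components(gt, idx_a, idx_b)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = hudson_fst_components(gt, idx_a, idx_b)
    else:
        raise ValueError("estimator must be 'wc' or 'hudson'")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_snp_fst = num / den
    per_snp = pd.DataFrame(
        {"variant_id": gt.variant_ids, "chrom": gt.chrom, "pos": gt.pos,
         "fst": per_snp_fst}
    )
    grid = window_grid(chrom_lengths or chrom_lengths_from(gt), spec)
    num_w = _window_sum(gt, np.nan_to_num(num, nan=0.0), grid)
    den_w = _window_sum(gt, np.nan_to_num(den, nan=0.0), grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst_w = np.where(den_w > 0, num_w / den_w, np.nan)
    per_window = grid.copy()
    per_window["fst"] = fst_w
    return per_snp, per_window


def expression_cv(expr: ExpressionTable, sample_idx: Iterable[int]) -> pd.DataFrame:
    """Per-gene coefficient of variation: sample SD (n-1) / mean; NaN at mean 0."""
    idx = np.asarray(list(sample_idx), dtype=np.int64)
    if len(idx) < 2:
        raise ValueError("need >= 2 samples for CV")
    vals = expr.values[:, idx]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return pd.DataFrame({"gene_id": expr.gene_ids, "cv": cv})


def pair_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes, pairwise-complete."""
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = gi[ok].astype(float), gj[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_r2(
    gt: GenotypeTable,
    max_dist: int = 5_000_000,
    maf_min: float = 0.05,
    missing_max: float = 0.25,
    het_max: float = 0.88,
    sample_idx: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """All intra-chromosomal SNP pairs within ``max_dist`` passing filters.

    r^2 is the squared Pearson correlation of unphased genotype codes over
    samples non-missing at both sites (composite LD).
    """
    sub = gt if sample_idx is None else gt.take_samples(sample_idx)
    keep = (
        (sub.maf() >= maf_min)
        & (sub.missing_rate() <= missing_max)
        & (np.nan_to_num(sub.het_rate(), nan=1.0) <= het_max)
    )
    sub = sub.take_variants(np.nonzero(keep)[0])
    rows = []
    for c in dict.fromkeys(sub.chrom):
        cidx = np.nonzero(sub.chrom == c)[0]
        pos = sub.pos[cidx]
        G = sub.genotypes[:, cidx]
        for ii in range(len(cidx)):
            jmax = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            for jj in range(ii + 1, jmax):
                r2 = pair_r2(G[:, ii], G[:, jj])
                if np.isnan(r2):
                    continue
                rows.append(
                    (sub.variant_ids[cidx[ii]], sub.variant_ids[cidx[jj]],
                     int(pos[jj] - pos[ii]), r2)
                )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "r2"])


def ld_decay(pairs: pd.DataFrame, bin_size: int = 1_000, max_r2_dist: int = 1_000):
    """Distance-binned decay curve, its maximum, and the half-decay distance.

    ``max_r2`` is the mean r^2 over pairs at distance <= ``max_r2_dist``.
    The curve is forced monotone (cumulative minimum) before thresholding;
    the half-decay distance is the first bin midpoint at or below
    max_r2 / 2, or inf if the curve never drops that low.
    """
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    near = pairs.loc[pairs["distance"] <= max_r2_dist, "r2"]
    if near.empty:
        raise ValueError("no pairs within the max-r2 distance")
    max_r2 = float(near.mean())
    bins = (pairs["distance"].to_numpy() // bin_size).astype(int)
    curve = (
        pd.DataFrame({"bin": bins, "r2": pairs["r2"].to_numpy()})
        .groupby("bin")["r2"].mean().sort_index()
    )
    mid = (curve.index.to_numpy() + 0.5) * bin_size
    smoothed = np.minimum.accumulate(curve.to_numpy())
    below = np.nonzero(smoothed <= max_r2 / 2)[0]
    half = float(mid[below[0]]) if below.size else float("inf")
    curve_df = pd.DataFrame({"distance": mid, "mean_r2": curve.to_numpy(),
                             "smoothed_r2": smoothed})
    return curve_df, max_r2, half


def background_ld(
    gt: GenotypeTable,
    n_pairs: int = 10_000,
    seed: int = 0,
    quantile: float = 0.95,
    decay_curve: Optional[pd.DataFrame] = None,
    maf_min: float = 0.05,
):
    """Background LD from random inter-chromosomal SNP pairs.

    Returns ``(r2_background, bg_decay_distance)``: the chosen quantile of
    the inter-chromosomal r^2 distribution, and the first distance at which
    the (smoothed) intra-chromosomal decay curve falls to that level (NaN
    when no curve is supplied, inf when the curve never reaches it).
    """
    chroms = list(dict.fromkeys(gt.chrom))
    if len(chroms) < 2:
        raise ValueError("background LD needs >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    keep = np.nonzero(gt.maf() >= maf_min)[0]
    chrom_of = gt.chrom[keep]
    vals = []
    attempts = 0
    while len(vals) < n_pairs and attempts < 20 * n_pairs:
        attempts += 1
        i, j = rng.choice(len(keep), size=2, replace=False)
        if chrom_of[i] == chrom_of[j]:
            continue
        r2 = pair_r2(gt.genotypes[:, keep[i]], gt.genotypes[:, keep[j]])
        if not np.isnan(r2):
            vals.append(r2)
    r2_bg = float(np.quantile(vals, quantile))
    if decay_curve is None:
        return r2_bg, float("nan")
    smoothed = decay_curve["smoothed_r2"].to_numpy()
    below = np.nonzero(smoothed <= r2_bg)[0]
    dist = (
        float(decay_curve["distance"].to_numpy()[below[0]])
        if below.size
        else float("inf")
    )
    return r2_bg, dist
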