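"""Linear mixed-model association engine with transforms and locus grouping.

The engine follows the two-step mixed-model approximation used for
large-scale expression mapping: variance components are estimated once per
response by REML on the kinship spectrum, then every SNP is tested by
generalized least squares under the fixed covariance sigma_g^2 K +
sigma_e^2 I. Supporting pieces: a standardized-genotype (Balding-Nichols
scaled) kinship matrix, rank-based normal quantile transformation of
responses, PCA-based expression-outlier flagging and hidden-factor
covariates, Bonferroni/suggestive thresholds, and grouping of significant
SNPs into loci using LD and distance rules calibrated from background LD.

Hidden factors are principal components of the transformed expression
matrix; they are a PCA stand-in for factor-analysis approaches to expression
confounding, not a reimplementation of any of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, ExpressionTable, GenotypeTable, Region


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class SignificantLocus:
    """A block of >= 3 linked significant SNPs with its lead SNP."""

    region: Region
    members: List[str]
    lead_snp: str
    lead_neglog10p: float

    def __post_init__(self):
        if len(self.members) < 3:
            raise ValueError("locus needs >= 3 member SNPs")
        if self.lead_snp not in self.members:
            raise ValueError("lead SNP must be a member")


def _dosage_matrix(gt: GenotypeTable, variant_idx=None) -> np.ndarray:
    """Float dosages with per-SNP mean imputation of missing calls."""
    G = gt.genotypes.astype(float) if variant_idx is None else (
        gt.genotypes[:, variant_idx].astype(float)
    )
    G[G == MISSING] = np.nan
    mu = np.nanmean(G, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    return np.where(np.isnan(G), mu[None, :], G)


def bn_kinship(gt: GenotypeTable, maf_min: float = 0.05) -> np.ndarray:
    """Kinship from genotypes standardized by sqrt(2p(1-p)).

    K = Z Z^T / m over SNPs with MAF >= ``maf_min``; missing genotypes are
    mean-imputed per SNP. The result is a symmetric PSD Gram matrix.
    """
    if gt.n_samples < 2:
        raise ValueError("kinship needs >= 2 samples")
    keep = np.nonzero(gt.maf() >= max(maf_min, 1e-12))[0]
    if keep.size == 0:
        raise ValueError("no SNPs pass the MAF filter")
    G = _dosage_matrix(gt, keep)
    p = G.mean(axis=0) / 2.0
    Z = (G - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    K = Z @ Z.T / Z.shape[1]
    return (K + K.T) / 2.0


def quantile_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based normal scores: Phi^-1(rank / (n + 1)), average ties."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need >= 3 values")
    if np.all(values == values[0]):
        warnings.warn("constant vector; quantile transform returns zeros")
        return np.zeros_like(values)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf(ranks / (len(values) + 1.0))


def _expression_pcs(log_expr_by_sample: np.ndarray, n_pc: int):
    """Sample scores of the first PCs of a samples x genes matrix."""
    X = log_expr_by_sample - log_expr_by_sample.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > 1e-10 * s.max()).sum()) if s.size else 0
    return U[:, :min(n_pc, rank)] * s[: min(n_pc, rank)], rank


def expression_outliers(expr: ExpressionTable, n_pc: int = 3,
                        sd_cut: float = 2.5) -> List[str]:
    """Samples > ``sd_cut`` SD from the mean on any of the first PCs of the
    log2(x+1) expression matrix."""
    if len(expr.sample_ids) < n_pc + 2:
        raise ValueError("too few samples for outlier PCA")
    X = np.log2(expr.values.T + 1.0)
    scores, rank = _expression_pcs(X, n_pc)
    if rank < n_pc:
        warnings.warn(f"expression matrix rank {rank} < {n_pc}; using {rank} PCs")
    flagged = set()
    for k in range(scores.shape[1]):
        col = scores[:, k]
        sd = col.std()
        if sd == 0:
            continue
        flagged |= {
            expr.sample_ids[i]
            for i in np.nonzero(np.abs(col - col.mean()) > sd_cut * sd)[0]
        }
    return sorted(flagged)


def hidden_factors(transformed_expr: np.ndarray, n_factors: int = 10) -> np.ndarray:
    """First ``n_factors`` PCs of a samples x genes transformed matrix,
    returned as fixed covariates."""
    n = transformed_expr.shape[0]
    if n_factors >= n:
        raise ValueError("n_factors must be < number of samples")
    if n_factors == 0:
        return np.zeros((n, 0))
    scores, _ = _expression_pcs(transformed_expr, n_factors)
    return scores


def emma_reml(y: np.ndarray, covariates: Optional[np.ndarray],
              K: np.ndarray) -> VarianceComponents:
    """REML variance components under y ~ N(Xb, sigma_g^2 K + sigma_e^2 I).

    One-dimensional REML over lambda = sigma_g^2 / sigma_e^2 on the spectrum
    of the covariate-projected kinship (grid on log lambda, then bounded
    refinement).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None or covariates.size == 0 else (
        np.column_stack([np.ones(n), covariates])
    )
    q = X.shape[1]
    if np.allclose(y, y[0]):
        return VarianceComponents(0.0, 0.0)
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("kinship matrix is not PSD")

    # project out covariates, diagonalize S K S on its row space
    Q, _ = np.linalg.qr(X, mode="complete")
    B = Q[:, q:]  # n x (n-q), orthonormal basis of the residual space
    Kb = B.T @ K @ B
    xi, V = np.linalg.eigh((Kb + Kb.T) / 2.0)
    eta = V.T @ (B.T @ y)
    m = len(eta)

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        d = lam * xi + 1.0
        sig_e2 = float((eta**2 / d).sum() / m)
        return 0.5 * (m * np.log(sig_e2) + np.log(d).sum())

    grid = np.linspace(-10, 10, 41)
    vals = [neg_reml(g) for g in grid]
    if max(vals) - min(vals) < 1e-9:
        # flat restricted likelihood (e.g. K = I): components unidentifiable;
        # convention is the sigma_g^2 = 0 boundary
        return VarianceComponents(0.0, float((eta**2).sum() / m))
    k0 = int(np.argmin(vals))
    lo = grid[max(k0 - 1, 0)]
    hi = grid[min(k0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    lam = float(np.exp(res.x))
    d = lam * xi + 1.0
    sig_e2 = float((eta**2 / d).sum() / m)
    # boundary handling: lambda pinned at grid edge means (near-)unidentifiable
    if res.x <= grid[0] + 1e-6:
        return VarianceComponents(0.0, sig_e2)
    return VarianceComponents(lam * sig_e2, sig_e2)


def lmm_scan(
    y: np.ndarray,
    covariates: Optional[np.ndarray],
    K: np.ndarray,
    gt: GenotypeTable,
    vc: Optional[VarianceComponents] = None,
) -> pd.DataFrame:
    """Per-SNP GLS effect, SE and Wald p under fixed variance components.

    Components are estimated once (if not supplied) and reused for every
    SNP; the covariance is whitened by its inverse square root and each SNP
    tested by ordinary least squares on the whitened data. Zero-variance
    SNPs are reported with NaN statistics.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if vc is None:
        vc = emma_reml(y, covariates, K)
    V = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(n)
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    w = np.clip(w, 1e-12 * max(w.max(), 1.0), None)
    A = U @ np.diag(1.0 / np.sqrt(w)) @ U.T  # V^{-1/2}

    X0 = np.ones((n, 1)) if covariates is None or covariates.size == 0 else (
        np.column_stack([np.ones(n), covariates])
    )
    yt = A @ y
    Xt = A @ X0
    G = _dosage_matrix(gt)
    Gt = A @ G

    # residualize transformed response and genotypes on covariates
    Qx, _ = np.linalg.qr(Xt)
    yr = yt - Qx @ (Qx.T @ yt)
    Gr = Gt - Qx @ (Qx.T @ Gt)
    df = n - X0.shape[1] - 1

    gss = (Gr**2).sum(axis=0)
    gy = Gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gss
        rss = (yr**2).sum() - beta * gy
        se = np.sqrt(np.clip(rss, 0, None) / df / gss)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    degenerate = gss <= 1e-12 * max(float(gss.max(initial=0.0)), 1.0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance SNPs skipped")
    for arr in (beta, se, tstat):
        arr[degenerate] = np.nan
    pvals[degenerate] = np.nan
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {"variant_id": gt.variant_ids, "chrom": gt.chrom, "pos": gt.pos,
             "beta": beta, "se": se, "p": pvals,
             "neglog10p": -np.log10(pvals)}
        )
    return out


def significance_thresholds(m_tests: int, alpha: float = 0.05):
    """Bonferroni-style threshold alpha / m; returns (p, -log10 p to 2 dp)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    p = alpha / m_tests
    return p, round(-np.log10(p), 2)


def group_significant_snps(
    result: pd.DataFrame,
    gt: GenotypeTable,
    p_threshold: float,
    r2_min: float = 0.1,
    max_gap_bp: int = 4_700_000,
    min_snps: int = 3,
) -> List[SignificantLocus]:
    """Group significant SNPs into loci by distance and LD chaining.

    Walking each chromosome in position order, a significant SNP extends
    the current group when it lies within ``max_gap_bp`` of the previous
    member and has r^2 > ``r2_min`` with it; groups with fewer than
    ``min_snps`` members are discarded as false-positive signals.
    """
    from .popstats import pair_r2

    sig = result[result["p"] <= p_threshold].dropna(subset=["p"])
    loci: List[SignificantLocus] = []
    vindex = {v: j for j, v in enumerate(gt.variant_ids)}
    for c in dict.fromkeys(sig["chrom"]):
        sub = sig[sig["chrom"] == c].sort_values("pos")
        group: List[pd.Series] = []
        for _, row in sub.iterrows():
            if group:
                prev = group[-1]
                close = row["pos"] - prev["pos"] < max_gap_bp
                linked = False
                if close:
                    r2 = pair_r2(
                        gt.genotypes[:, vindex[prev["variant_id"]]],
                        gt.genotypes[:, vindex[row["variant_id"]]],
                    )
                    linked = np.isfinite(r2) and r2 > r2_min
                if not (close and linked):
                    loci.extend(_finalize_group(group, min_snps))
                    group = []
            group.append(row)
        loci.extend(_finalize_group(group, min_snps))
    return loci


def _finalize_group(group, min_snps: int) -> List[SignificantLocus]:
    if len(group) < min_snps:
        return []
    lead = min(group, key=lambda r: r["p"])
    start = int(min(r["pos"] for r in group)) - 1
    end = int(max(r["pos"] for r in group))
    return [
        SignificantLocus(
            region=Region(group[0]["chrom"], start, end, stat_name="locus",
                          stat_value=float(-np.log10(lead["p"])),
                          support=len(group)),
            members=[r["variant_id"] for r in group],
            lead_snp=lead["variant_id"],
            lead_neglog10p=float(-np.log10(lead["p"])),
        )
    ]
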