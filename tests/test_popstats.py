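"""Diversity, differentiation, LD and CV statistics against oracles."""

import numpy as np
import pandas as pd
import pytest

from domestiscan.containers import MISSING
from domestiscan.popstats import (
    WindowSpec,
    background_ld,
    expression_cv,
    ld_decay,
    ld_r2,
    pair_r2,
    pi_ratio,
    wc_fst_components,
    window_fst,
    window_pi,
)
from domestiscan.containers import ExpressionTable
from domestiscan.simulate import SimConfig, simulate_founder_haplotypes, simulate_population

from conftest import make_gt

M = MISSING


def brute_force_pi(haplotypes, length):
    """Mean pairwise haplotype difference per bp over all haplotype pairs."""
    hs = np.concatenate([haplotypes[:, :, 0], haplotypes[:, :, 1]], axis=0)
    n = hs.shape[0]
    total = 0.0
    for i in range(n):
        total += np.abs(hs[i + 1:] - hs[i]).sum()
    return total / (n * (n - 1) / 2) / length


class TestWindowPi:
    def test_single_site_example(self):
        # 2 samples, both het: 4 alleles, 2 alt; avg pairwise difference 2/3
        gt = make_gt([[1], [1]], pos=[5], groups={"S0": "g", "S1": "g"})
        track = window_pi(gt, "g", WindowSpec(10, 10), {"chr1": 10})
        assert track.pi[0] == pytest.approx((4 / 3) * 0.5 / 10)
        assert track.pi[0] == pytest.approx(0.06667, rel=1e-3)

    def test_monomorphic_window_zero(self):
        gt = make_gt([[0, 0], [0, 0], [0, 0]], groups={f"S{i}": "g" for i in range(3)})
        track = window_pi(gt, "g", WindowSpec(100, 100), {"chr1": 100})
        assert track.pi[0] == 0.0

    def test_matches_brute_force_pairwise_differences(self):
        cfg = SimConfig(seed=2, n_variants=400, n_genes=5,
                        chrom_lengths={"LG1": 1_000_000},
                        group_sizes={"serriola": 8, "stem": 10},
                        drift={"serriola": 0.1, "stem": 0.3},
                        missing_rate_range=(0.0, 0.0))
        gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        idx = gt.sample_indices("stem")
        track = window_pi(gt, "stem", WindowSpec(1_000_000, 1_000_000),
                          cfg.chrom_lengths)
        expected = brute_force_pi(gt.haplotypes[idx], 1_000_000)
        assert track.pi[0] == pytest.approx(expected, rel=1e-9)

    def test_sample_order_invariance(self):
        cfg = SimConfig(seed=2, n_variants=200, n_genes=5,
                        chrom_lengths={"LG1": 500_000},
                        group_sizes={"serriola": 8, "stem": 10},
                        drift={"serriola": 0.1, "stem": 0.3})
        gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        perm = np.random.default_rng(0).permutation(gt.n_samples)
        track_a = window_pi(gt, "stem", WindowSpec(100_000, 100_000), cfg.chrom_lengths)
        track_b = window_pi(gt.take_samples(perm), "stem",
                            WindowSpec(100_000, 100_000), cfg.chrom_lengths)
        assert np.allclose(track_a.pi, track_b.pi, equal_nan=True)

    def test_group_too_small_rejected(self):
        gt = make_gt([[0], [0]], groups={"S0": "a", "S1": "b"})
        with pytest.raises(ValueError, match=">= 2"):
            window_pi(gt, "a")


class TestPiRatio:
    def grid(self, pa, pb):
        base = pd.DataFrame({"chrom": ["c"] * len(pa),
                             "start": np.arange(len(pa)) * 10,
                             "end": (np.arange(len(pa)) + 1) * 10})
        a = base.copy(); a["pi"] = pa
        b = base.copy(); b["pi"] = pb
        return a, b

    def test_equal_tracks_ratio_one(self):
        a, b = self.grid([0.1, 0.2], [0.1, 0.2])
        assert np.allclose(pi_ratio(a, b)["ratio"], 1.0)

    def test_zero_denominator_flagged(self):
        a, b = self.grid([0.1], [0.0])
        assert np.isnan(pi_ratio(a, b)["ratio"][0])

    def test_grid_mismatch_rejected(self):
        a, _ = self.grid([0.1], [0.1])
        b, _ = self.grid([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError, match="grids"):
            pi_ratio(a, b)


class TestFst:
    def test_hand_computed_weir_cockerham(self):
        # n1 = n2 = 10 samples; p1 = 0.9, p2 = 0.1; all homozygous calls
        ga = [[2]] * 9 + [[0]]
        gb = [[2]] * 1 + [[0]] * 9
        gt = make_gt(ga + gb)
        a, b, c = wc_fst_components(gt, np.arange(10), np.arange(10, 20))
        # independent hand computation of the variance components
        n_bar, r = 10.0, 2.0
        p1, p2 = 0.9, 0.1
        n_c = (r * n_bar - (100 + 100) / (r * n_bar)) / (r - 1)
        p_bar = 0.5
        s2 = (10 * (p1 - p_bar) ** 2 + 10 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = 0.0
        a_exp = n_bar / n_c * (s2 - (p_bar * (1 - p_bar) - s2 / 2 - 0.0) / (n_bar - 1))
        b_exp = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 / 2 - 0.0)
        assert a[0] == pytest.approx(a_exp, rel=1e-12)
        assert b[0] == pytest.approx(b_exp, rel=1e-12)
        assert c[0] == 0.0

    def test_fixed_difference_approaches_one(self):
        gt = make_gt([[2]] * 40 + [[0]] * 40)
        a, b, c = wc_fst_components(gt, np.arange(40), np.arange(40, 80))
        assert a[0] / (a[0] + b[0] + c[0]) > 0.97

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(60, 50)).astype(np.int8)
        gt = make_gt(g, groups={f"S{i}": ("a" if i < 30 else "b") for i in range(60)})
        snp, win = window_fst(gt, "a", "b", WindowSpec(1000, 1000), {"chr1": 1000})
        assert abs(win.fst[0]) < 0.03

    def test_hudson_option_agrees_in_sign(self):
        gt = make_gt([[2]] * 20 + [[0]] * 20,
                     groups={f"S{i}": ("a" if i < 20 else "b") for i in range(40)})
        _, wc = window_fst(gt, "a", "b", WindowSpec(1000, 1000), {"chr1": 1000})
        _, hu = window_fst(gt, "a", "b", WindowSpec(1000, 1000), {"chr1": 1000},
                           estimator="hudson")
        assert wc.fst[0] > 0.9 and hu.fst[0] > 0.9


class TestExpressionCv:
    def test_direct_formula(self):
        expr = ExpressionTable(["g1"], ["a", "b", "c"], [[2.0, 4.0, 6.0]])
        cv = expression_cv(expr, [0, 1, 2])
        assert cv.cv[0] == pytest.approx(0.5)

    def test_constant_gene_zero(self):
        expr = ExpressionTable(["g1"], ["a", "b"], [[3.0, 3.0]])
        assert expression_cv(expr, [0, 1]).cv[0] == 0.0

    def test_all_zero_gene_undefined(self):
        expr = ExpressionTable(["g1"], ["a", "b"], [[0.0, 0.0]])
        assert np.isnan(expression_cv(expr, [0, 1]).cv[0])


class TestLd:
    def test_pair_r2_examples(self):
        assert pair_r2(np.array([0, 0, 2, 2]), np.array([0, 0, 2, 2])) == pytest.approx(1.0)
        assert pair_r2(np.array([0, 0, 2, 2]), np.array([0, 2, 0, 2])) == pytest.approx(0.0)
        assert pair_r2(np.array([0, 1, 2, 2]), np.array([0, 0, 2, 2])) == pytest.approx(9 / 11)

    def test_allele_swap_invariance(self):
        x = np.array([0, 1, 2, 2, 0, 1])
        y = np.array([0, 0, 2, 2, 1, 1])
        assert pair_r2(x, y) == pytest.approx(pair_r2(2 - x, y))

    def test_filters_apply(self):
        # one SNP with 50% missing excluded by missing_max=0.25
        g = np.array([[0, 0], [2, M], [0, 0], [2, M]], dtype=np.int8)
        pairs = ld_r2(make_gt(g), max_dist=1000, maf_min=0.05, missing_max=0.25)
        assert pairs.empty

    def test_decay_exponential_closed_form(self):
        rng = np.random.default_rng(0)
        lam, mx = 30_000.0, 0.8
        d = rng.integers(1, 200_000, size=20_000)
        pairs = pd.DataFrame({"id_a": "a", "id_b": "b", "distance": d,
                              "r2": mx * np.exp(-d / lam)})
        _, max_r2, half = ld_decay(pairs)
        assert abs(half - lam * np.log(2)) <= 1_000  # within one bin
        assert max_r2 == pytest.approx(mx, rel=0.05)

    def test_decay_flat_curve_infinite(self):
        pairs = pd.DataFrame({"id_a": "a", "id_b": "b",
                              "distance": [500, 5_000, 50_000],
                              "r2": [0.6, 0.6, 0.6]})
        _, max_r2, half = ld_decay(pairs)
        assert max_r2 == pytest.approx(0.6)
        assert half == np.inf

    def test_decay_requires_short_range_pairs(self):
        pairs = pd.DataFrame({"id_a": "a", "id_b": "b",
                              "distance": [50_000], "r2": [0.2]})
        with pytest.raises(ValueError, match="max-r2"):
            ld_decay(pairs)


@pytest.fixture(scope="module")
def panmictic():
    cfg = SimConfig(seed=4, n_variants=2000, n_genes=5, selfing_rate=0.0,
                    copy_prob=0.0, block_length=2000, n_founders=30,
                    domestication_drift=0.0,
                    drift={g: 0.0 for g in ("serriola", "butterhead",
                                            "crisphead", "romaine", "stem")},
                    chrom_lengths={"LG1": 5_000_000, "LG2": 5_000_000},
                    missing_rate_range=(0.0, 0.0))
    gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
    return gt


class TestBackgroundLd:

    def test_matches_independence_oracle(self, panmictic):
        r2bg, _ = background_ld(panmictic, n_pairs=2000, seed=1)
        n = panmictic.n_samples
        rng = np.random.default_rng(7)
        null = []
        for _ in range(4000):
            x = rng.binomial(2, 0.3, size=n)
            y = rng.binomial(2, 0.3, size=n)
            if x.std() and y.std():
                null.append(np.corrcoef(x, y)[0, 1] ** 2)
        assert r2bg == pytest.approx(np.quantile(null, 0.95), rel=0.35)

    def test_deterministic(self, panmictic):
        a, _ = background_ld(panmictic, n_pairs=500, seed=9)
        b, _ = background_ld(panmictic, n_pairs=500, seed=9)
        assert a == b

    def test_structure_inflates_background(self, panmictic):
        cfg = SimConfig(seed=4, n_variants=2000, n_genes=5,
                        chrom_lengths={"LG1": 5_000_000, "LG2": 5_000_000},
                        missing_rate_range=(0.0, 0.0))
        gt, _ = simulate_population(simulate_founder_haplotypes(cfg), cfg)
        flat, _ = background_ld(panmictic, n_pairs=1500, seed=1)
        structured, _ = background_ld(gt, n_pairs=1500, seed=1)
        assert structured > flat

    def test_single_chromosome_rejected(self):
        gt = make_gt([[0, 2], [2, 0], [0, 0], [2, 2]])
        with pytest.raises(ValueError, match="chromosomes"):
            background_ld(gt)
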