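"""eQTL classification, hotspot scan, iGA and network construction."""

import numpy as np
import pytest
from scipy import stats as sps

from domestiscan.assoc import SignificantLocus
from domestiscan.containers import ExpressionTable, GeneAnnotation, Region
from domestiscan.eqtlnet import (
    EqtlBlock,
    build_network,
    classify_eqtl,
    hotspot_scan,
    iga_pc,
    log_expression,
    master_regulators,
    pcc_threshold,
    seed_expansion,
)


def locus(chrom, start, end, lead="v0", members=None):
    members = members or [lead, "va", "vb"]
    return SignificantLocus(Region(chrom, start, end), members, lead, 8.0)


class TestClassify:
    def test_containment_is_local(self):
        gene = GeneAnnotation("g", "c1", 1_500_000, 1_600_000)
        assert classify_eqtl(locus("c1", 1_000_000, 2_000_000), gene) == "local"

    def test_other_chromosome_distant(self):
        gene = GeneAnnotation("g", "c2", 100, 200)
        assert classify_eqtl(locus("c1", 0, 1_000_000), gene) == "distant"

    def test_half_open_abutment_distant(self):
        gene = GeneAnnotation("g", "c1", 1_000_000, 1_100_000)
        assert classify_eqtl(locus("c1", 500_000, 1_000_000), gene) == "distant"

    def test_every_block_classified_once(self):
        genes = [GeneAnnotation(f"g{i}", "c1", i * 1000, i * 1000 + 500)
                 for i in range(20)]
        blocks = [EqtlBlock(g.gene_id, locus("c1", 5_000, 6_000),
                            classify_eqtl(locus("c1", 5_000, 6_000), g))
                  for g in genes]
        n_local = sum(b.classification == "local" for b in blocks)
        n_distant = sum(b.classification == "distant" for b in blocks)
        assert n_local + n_distant == len(blocks)


class TestHotspots:
    def blocks_at(self, positions):
        out, pos_map = [], {}
        for i, (c, p) in enumerate(positions):
            vid = f"v{i}"
            pos_map[vid] = (c, p)
            out.append(EqtlBlock(f"g{i}", locus(c, max(0, p - 1), p + 1, lead=vid,
                                                members=[vid, "a", "b"]),
                                 "distant"))
        return out, pos_map

    def test_concentrated_window_detected(self):
        rng = np.random.default_rng(0)
        uniform = [("c1", int(p)) for p in rng.integers(1, 10_000_000, size=70)]
        clustered = [("c1", int(p)) for p in rng.integers(5_000_000, 5_200_000, size=30)]
        blocks, pos_map = self.blocks_at(uniform + clustered)
        hs = hotspot_scan(blocks, {"c1": 10_000_000}, pos_map)
        assert len(hs) >= 1
        top = max(hs, key=lambda h: h.count)
        assert top.region.start <= 5_000_000 <= top.region.end + 400_000
        # binomial tail for the clustered window is astronomically small
        p = sps.binom.sf(29, 100, 400_000 / 10_000_000)
        assert p < 1e-15

    def test_single_eqtl_no_hotspot(self):
        blocks, pos_map = self.blocks_at([("c1", 5_000_000)])
        assert hotspot_scan(blocks, {"c1": 10_000_000}, pos_map) == []

    def test_no_distant_blocks_empty(self):
        assert hotspot_scan([], {"c1": 1_000_000}, {}) == []

    def test_uniform_null_rarely_calls(self):
        nfp = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            pos = [("c1", int(p)) for p in rng.integers(1, 10_000_000, size=100)]
            blocks, pos_map = self.blocks_at(pos)
            nfp += len(hotspot_scan(blocks, {"c1": 10_000_000}, pos_map))
        assert nfp <= 1


class TestPccThreshold:
    def test_iid_normal_matches_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 180))
        pos, neg = pcc_threshold(X, n_perm=2000, alpha=0.05, seed=2)
        expect = 1.96 / np.sqrt(180)
        assert pos == pytest.approx(expect, rel=0.2)
        assert neg == pytest.approx(-expect, rel=0.2)

    def test_deterministic(self):
        X = np.random.default_rng(3).normal(size=(50, 30))
        assert pcc_threshold(X, 200, seed=5) == pcc_threshold(X, 200, seed=5)

    def test_alpha_one_extremes(self):
        X = np.random.default_rng(4).normal(size=(50, 30))
        pos, neg = pcc_threshold(X, 200, alpha=1.0, seed=6)
        assert -1 <= pos <= 0 or pos <= 0.01
        assert neg >= -1


def exhaustive_pc(ranked, members):
    """Enumerate hypergeometric tails over all prefixes ending at members."""
    N, G = len(ranked), len(set(members) & set(ranked))
    best = 1.0
    g = 0
    for d in range(1, N + 1):
        if ranked[d - 1] in members:
            g += 1
            # tail by enumeration over the hypergeometric pmf
            tail = sum(sps.hypergeom.pmf(k, N, G, d) for k in range(g, min(G, d) + 1))
            best = min(best, tail)
    return best


class TestIga:
    def test_top_ranked_pair_example(self):
        ranked = ["a", "b", "c", "d", "e"]
        pc, d = iga_pc(ranked, {"a", "b"})
        assert pc == pytest.approx(0.1)
        assert d == 2

    def test_bottom_ranked_pair_is_one(self):
        ranked = ["c", "d", "e", "a", "b"]
        pc, d = iga_pc(ranked, {"a", "b"})
        assert pc == pytest.approx(sps.hypergeom.sf(0, 5, 2, 4))

    def test_group_is_everything(self):
        ranked = ["a", "b", "c"]
        pc, _ = iga_pc(ranked, {"a", "b", "c"})
        assert pc == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            iga_pc(["a", "b"], set())

    @pytest.mark.parametrize("n,g", [(4, 1), (5, 2), (6, 3), (7, 2)])
    def test_matches_exhaustive_enumeration(self, n, g):
        rng = np.random.default_rng(n * 10 + g)
        genes = [f"x{i}" for i in range(n)]
        for _ in range(20):
            ranked = list(rng.permutation(genes))
            members = set(rng.choice(genes, size=g, replace=False))
            pc, _ = iga_pc(ranked, members)
            assert pc == pytest.approx(exhaustive_pc(ranked, members), rel=1e-9)


def toy_expression(n_samples=60, seed=0):
    """30 genes; g0 drives g1..g5 strongly (alternating sign)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(3, 1, size=(30, n_samples))
    for t in range(1, 6):
        sign = 1 if t % 2 else -1
        X[t] = 3 + sign * 0.9 * (X[0] - 3) + rng.normal(0, 0.3, n_samples)
    annotations = {
        f"g{i}": GeneAnnotation(f"g{i}", "c1", i * 100_000, i * 100_000 + 1_000)
        for i in range(30)
    }
    expr = ExpressionTable([f"g{i}" for i in range(30)],
                           [f"s{i}" for i in range(n_samples)],
                           np.clip(2.0 ** X - 1, 0, None),
                           gene_annotations=annotations)
    return expr


class TestMasterRegulators:
    def make_inputs(self):
        expr = toy_expression()
        # hotspot over g0's neighborhood; targets g1..g5 have distant eQTLs there
        hs_region = Region("c1", 0, 400_000, stat_name="hotspot")
        from domestiscan.eqtlnet import Hotspot

        hotspots = [Hotspot(hs_region, count=5, p_adjusted=1e-10)]
        pos_map = {"lead0": ("c1", 50_000)}
        blocks = [EqtlBlock("g0",
                            SignificantLocus(Region("c1", 0, 1_000),
                                             ["lead0", "a", "b"], "lead0", 9.0),
                            "local")]
        for t in range(1, 6):
            pos_map[f"lead{t}"] = ("c1", 60_000 + t)
            blocks.append(
                EqtlBlock(f"g{t}",
                          SignificantLocus(Region("c1", 50_000, 60_010),
                                           [f"lead{t}", "a", "b"], f"lead{t}", 8.0),
                          "distant")
            )
        return expr, hotspots, blocks, pos_map

    def test_regulator_with_local_eqtl_called(self):
        expr, hotspots, blocks, pos_map = self.make_inputs()
        cands = master_regulators(hotspots, blocks, expr, snp_positions=pos_map)
        assert any(c.gene_id == "g0" and len(c.targets) >= 3 for c in cands)

    def test_gene_without_local_eqtl_excluded(self):
        expr, hotspots, blocks, pos_map = self.make_inputs()
        blocks = [b for b in blocks if b.gene_id != "g0"]  # drop g0's local eQTL
        cands = master_regulators(hotspots, blocks, expr, snp_positions=pos_map)
        assert all(c.gene_id != "g0" for c in cands)

    def test_gene_outside_hotspot_excluded(self):
        expr, hotspots, blocks, pos_map = self.make_inputs()
        # move the hotspot away from every gene interval
        from domestiscan.eqtlnet import Hotspot

        hotspots = [Hotspot(Region("c1", 5_000_000, 5_400_000), 5, 1e-10)]
        cands = master_regulators(hotspots, blocks, expr, snp_positions=pos_map)
        assert cands == []


class TestNetwork:
    def test_regulator_and_signed_edges_recovered(self):
        expr = toy_expression()
        pathway = [f"g{t}" for t in range(1, 6)]
        blocks = []
        for t in range(1, 6):
            blocks.append(
                EqtlBlock(f"g{t}",
                          SignificantLocus(Region("c1", 0, 100_000),
                                           [f"l{t}", "a", "b"], f"l{t}", 8.0),
                          "distant")
            )
        net, merged = build_network(blocks, pathway, expr)
        df = net.to_frame()
        assert len(merged) == 1
        assert "g0" in set(df.regulator)
        g0 = df[df.regulator == "g0"]
        signs = dict(zip(g0.target, g0.sign))
        assert signs.get("g1", 1) == 1 and signs.get("g2", -1) == -1

    def test_no_self_edges(self):
        expr = toy_expression()
        pathway = ["g0"] + [f"g{t}" for t in range(1, 6)]
        blocks = [EqtlBlock(g, SignificantLocus(Region("c1", 0, 100_000),
                                                ["l", "a", "b"], "l", 8.0),
                            "distant") for g in pathway]
        net, _ = build_network(blocks, pathway, expr)
        df = net.to_frame()
        if len(df):
            assert np.all(df.regulator != df.target)


class TestSeedExpansion:
    def test_admission_requires_three_seed_links(self):
        expr = toy_expression()
        # g1, g3, g5 all mirror g0; so does g0 itself -> g0-correlated genes qualify
        seeds = ["g1", "g2", "g3"]
        admitted = seed_expansion(seeds, expr, pcc_abs_min=0.5, min_seed_links=3)
        assert "g0" in admitted  # correlated with all three seeds
        assert "g10" not in admitted  # independent noise gene

    def test_two_links_insufficient(self):
        expr = toy_expression()
        admitted = seed_expansion(["g1", "g2", "g10"], expr,
                                  pcc_abs_min=0.5, min_seed_links=3)
        # g0 correlates with g1, g2 but not the noise gene g10
        assert "g0" not in admitted

    def test_unknown_seed_rejected(self):
        expr = toy_expression()
        with pytest.raises(ValueError, match="seed"):
            seed_expansion(["nope"], expr)
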