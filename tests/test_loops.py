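import math

import numpy as np
import pandas as pd
import pytest

from synteny3d.io_formats import GeneRecord, OrthologTable
from synteny3d.loops import (
    LoopRecord,
    associate_genes,
    conserved_loops,
    cross_chromosome_class,
    loop_identity_overlap,
    merge_resolutions,
    scaling_slopes,
    size_vs_ancestral_spacing,
)


def call(chrom, s1, s2, res=100_000, width=None):
    w = width or res
    return {"chrom": chrom, "a1": (s1, s1 + w), "a2": (s2, s2 + w),
            "fdr": None, "resolution": res}


def loop(lid, chrom, a1, a2, genes1=(), genes2=(), sample="s", res=100_000):
    return LoopRecord(lid, sample, chrom, a1, a2, res,
                      frozenset(genes1), frozenset(genes2))


class TestMergeResolutions:
    def test_coarse_within_window_dropped(self):
        fine = [call("c1", 1_000_000, 3_000_000, 50_000)]
        coarse = [call("c1", 1_040_000, 3_040_000)]  # both anchors 40 kb away
        merged = merge_resolutions(fine, coarse)
        assert len(merged) == 1
        assert merged[0].source_resolution == 50_000

    def test_coarse_outside_window_kept(self):
        fine = [call("c1", 1_000_000, 3_000_000, 50_000)]
        coarse = [call("c1", 1_060_000, 3_000_000)]  # one anchor 60 kb away
        assert len(merge_resolutions(fine, coarse)) == 2

    def test_empty_fine_list_is_identity(self):
        coarse = [call("c1", 0, 500_000), call("c1", 1_000_000, 2_000_000)]
        merged = merge_resolutions([], coarse)
        assert len(merged) == 2

    def test_idempotent_and_chromosome_aware(self):
        fine = [call("c1", 1_000_000, 3_000_000, 50_000)]
        coarse = [call("c2", 1_000_000, 3_000_000)]  # same coords, other chrom
        assert len(merge_resolutions(fine, coarse)) == 2


class TestAssociateGenes:
    GENES = [
        GeneRecord("g1", "c1", 1_000_000, 1_040_000),
        GeneRecord("g2", "c1", 3_010_000, 3_060_000),
        GeneRecord("g3", "c1", 8_000_000, 8_050_000),
    ]

    def test_gene_sets_and_geneless_flag(self):
        loops = [loop("L1", "c1", (1_000_000, 1_050_000), (3_000_000, 3_050_000)),
                 loop("L2", "c1", (5_000_000, 5_050_000), (8_000_000, 8_050_000))]
        out = associate_genes(loops, self.GENES)
        l1 = next(l for l in out if l.loop_id == "L1")
        l2 = next(l for l in out if l.loop_id == "L2")
        assert l1.genes1 == {"g1"} and l1.genes2 == {"g2"} and l1.gene_associated
        assert not l2.gene_associated  # empty anchor1 set

    def test_identical_gene_sets_merged_to_outermost(self):
        loops = [loop("L1", "c1", (1_000_000, 1_050_000), (3_000_000, 3_050_000)),
                 loop("L2", "c1", (950_000, 1_050_000), (3_050_000, 3_100_000))]
        out = associate_genes(loops, self.GENES)
        assert len(out) == 1
        merged = out[0]
        assert merged.anchor1[0] == 950_000 and merged.anchor2[1] == 3_100_000
        assert merged.size == 2_150_000

    def test_merge_never_decreases_size(self):
        loops = [loop("L1", "c1", (1_000_000, 1_050_000), (3_000_000, 3_050_000)),
                 loop("L2", "c1", (950_000, 1_050_000), (3_050_000, 3_100_000))]
        biggest = max(l.size for l in loops)
        out = associate_genes(loops, self.GENES)
        assert out[0].size >= biggest

    def test_disjoint_gene_sets_not_merged(self):
        loops = [loop("L1", "c1", (1_000_000, 1_050_000), (3_000_000, 3_050_000)),
                 loop("L2", "c1", (1_000_000, 1_050_000), (8_000_000, 8_050_000))]
        assert len(associate_genes(loops, self.GENES)) == 2

    def test_size_cap(self):
        loops = [loop("L1", "c1", (1_000_000, 1_050_000), (3_000_000, 3_050_000))]
        assert associate_genes(loops, self.GENES, max_loop_size=1_000_000) == []


def _orthos():
    table = pd.DataFrame(
        {"B": [f"b{k}" for k in range(6)]}, index=[f"a{k}" for k in range(6)]
    )
    return OrthologTable(table, "A")


class TestConservedLoops:
    def test_swapped_anchor_order_still_conserved(self):
        la = loop("LA", "c1", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["a0"], genes2=["a1"], sample="A")
        lb = loop("LB", "c2", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["b1"], genes2=["b0"], sample="B")  # anchors reversed
        edges, groups = conserved_loops({"A": [la], "B": [lb]}, _orthos(), "A")
        assert edges[("A", "B")] == [("LA", "LB")]
        assert groups[0]["species"] == ["A", "B"]

    def test_both_orthologs_in_one_anchor_not_conserved(self):
        la = loop("LA", "c1", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["a0"], genes2=["a1"], sample="A")
        lb = loop("LB", "c2", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["b0", "b1"], genes2=["b5"], sample="B")
        edges, _ = conserved_loops({"A": [la], "B": [lb]}, _orthos(), "A")
        assert edges[("A", "B")] == []

    def test_single_spanning_gene_cannot_satisfy_both_anchors(self):
        la = loop("LA", "c1", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["a0"], genes2=["a0"], sample="A")
        lb = loop("LB", "c2", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["b0"], genes2=["b0"], sample="B")
        edges, _ = conserved_loops({"A": [la], "B": [lb]}, _orthos(), "A")
        assert edges[("A", "B")] == []

    def test_symmetry(self):
        la = loop("LA", "c1", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["a0"], genes2=["a1"], sample="A")
        lb = loop("LB", "c2", (0, 100_000), (1_000_000, 1_100_000),
                  genes1=["b0"], genes2=["b1"], sample="B")
        e1, _ = conserved_loops({"A": [la], "B": [lb]}, _orthos(), "A")
        la.conserved_in.clear()
        lb.conserved_in.clear()
        e2, _ = conserved_loops({"B": [lb], "A": [la]}, _orthos(), "A")
        assert len(e1[("A", "B")]) == len(e2[("B", "A")]) == 1


class TestScalingSlopes:
    def test_two_point_slope(self):
        groups = [{"species": ["A", "B"],
                   "sizes": {"A": 1_000_000.0, "B": 2_000_000.0}}]
        slopes, _ = scaling_slopes(groups, {"A": 3_000_000_000, "B": 5_000_000_000})
        assert slopes[0] == pytest.approx(5e-4)

    def test_identical_sizes_slope_zero(self):
        groups = [{"species": ["A", "B"], "sizes": {"A": 1e6, "B": 1e6}}]
        slopes, p = scaling_slopes(groups, {"A": 3e9, "B": 5e9})
        assert slopes == [0.0] and p == 1.0

    def test_equal_genomes_skipped_with_warning(self):
        groups = [{"species": ["A", "B"], "sizes": {"A": 1e6, "B": 2e6}}]
        with pytest.warns(UserWarning, match="genome sizes equal"):
            slopes, p = scaling_slopes(groups, {"A": 3e9, "B": 3e9})
        assert slopes == [] and math.isnan(p)

    def test_consistent_positive_slopes_significant(self):
        rng = np.random.default_rng(0)
        genomes = {"A": 3e9, "B": 4.5e9, "C": 5.5e9}
        groups = [
            {"species": list(genomes),
             "sizes": {sp: 1e-4 * g + rng.normal(0, 5e4) for sp, g in genomes.items()}}
            for _ in range(60)
        ]
        _, p = scaling_slopes(groups, genomes)
        assert p < 0.05


class TestCrossChromosomeClass:
    GENES_B = {"b0": GeneRecord("b0", "c2", 0, 1000),
               "b1": GeneRecord("b1", "c2", 5000, 6000),
               "b2": GeneRecord("b2", "c7", 0, 1000)}

    def test_spanning_two_chroms(self):
        lp = loop("L", "c1", (0, 1000), (10_000, 11_000),
                  genes1=["a0", "a1"], genes2=["a2"])
        omap = {"a0": "b0", "a1": "b1", "a2": "b2"}
        assert cross_chromosome_class(lp, self.GENES_B, omap) is True

    def test_single_chrom_false(self):
        lp = loop("L", "c1", (0, 1000), (10_000, 11_000),
                  genes1=["a0"], genes2=["a1"])
        omap = {"a0": "b0", "a1": "b1"}
        assert cross_chromosome_class(lp, self.GENES_B, omap) is False

    def test_single_ortholog_cannot_span(self):
        lp = loop("L", "c1", (0, 1000), (10_000, 11_000),
                  genes1=["a0"], genes2=["a9"])
        assert cross_chromosome_class(lp, self.GENES_B, {"a0": "b0"}) is False


class TestSizeVsSpacing:
    def _loops_linear(self, n, noise, rng):
        other, omap, loops = {}, {}, []
        for k in range(n):
            spacing = 200_000 + k * 10_000
            size = 2 * spacing + rng.normal(0, noise)
            ga, gb = f"a{k}_1", f"a{k}_2"
            omap[ga], omap[gb] = f"o{k}_1", f"o{k}_2"
            other[f"o{k}_1"] = GeneRecord(f"o{k}_1", "c9", 10_000 * k * 100,
                                          10_000 * k * 100 + 1000)
            other[f"o{k}_2"] = GeneRecord(f"o{k}_2", "c9",
                                          10_000 * k * 100 + 1000 + spacing,
                                          10_000 * k * 100 + 2000 + spacing)
            loops.append(loop(f"L{k}", "c1", (0, 1000), (1000 + int(size), 2000 + int(size)),
                              genes1=[ga], genes2=[gb]))
        return loops, other, omap

    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(1)
        loops, other, omap = self._loops_linear(20, 0.0, rng)
        assert size_vs_ancestral_spacing(loops, other, omap) == pytest.approx(1.0)

    def test_permuted_relation_near_zero(self):
        rng = np.random.default_rng(2)
        loops, other, omap = self._loops_linear(200, 0.0, rng)
        sizes = [lp.size for lp in loops]
        rng.shuffle(sizes)
        shuffled = [
            LoopRecord(lp.loop_id, lp.sample_id, lp.chrom, (0, 1000),
                       (1000 + s, 2000 + s), lp.source_resolution, lp.genes1, lp.genes2)
            for lp, s in zip(loops, sizes)
        ]
        assert size_vs_ancestral_spacing(shuffled, other, omap) < 0.05

    def test_too_few_loops_missing(self):
        rng = np.random.default_rng(3)
        loops, other, omap = self._loops_linear(2, 0.0, rng)
        assert size_vs_ancestral_spacing(loops, other, omap) is None


class TestLoopIdentityOverlap:
    def _ctx(self, keysets):
        out = {}
        for ctx, keys in keysets.items():
            out[ctx] = [
                loop(f"{ctx}{k}", "c1", (s * 1_000_000, s * 1_000_000 + 100_000),
                     ((s + 5) * 1_000_000, (s + 5) * 1_000_000 + 100_000),
                     genes1=[f"g{s}a"], genes2=[f"g{s}b"])
                for k, s in enumerate(keys)
            ]
        return out

    def test_identical_lists_full_overlap(self):
        samples = self._ctx({"t1": [0, 1, 2], "t2": [0, 1, 2],
                             "pad": list(range(10))})
        df = loop_identity_overlap(samples, "GENESET")
        row = df[(df.context_a == "t1") & (df.context_b == "t2")].iloc[0]
        assert row.overlap == 3
        # minimal attainable enrichment p for this universe: 1 / C(10, 3)
        assert row.p_enrich == pytest.approx(1 / math.comb(10, 3), rel=1e-12)

    def test_disjoint_lists_zero_overlap(self):
        samples = self._ctx({"t1": [0, 1], "t2": [2, 3]})
        df = loop_identity_overlap(samples, "GENESET")
        assert df.loc[0, "overlap"] == 0

    def test_hypergeometric_matches_enumeration(self):
        """10-key universe, two draws of 5 sharing 4: tail enumeration with
        binomial coefficients is the oracle."""
        samples = self._ctx({"t1": [0, 1, 2, 3, 4],
                             "t2": [0, 1, 2, 3, 9],
                             "pad": list(range(10))})
        df = loop_identity_overlap(samples, "GENESET")
        row = df[(df.context_a == "t1") & (df.context_b == "t2")].iloc[0]
        assert row.universe == 10 and row.overlap == 4
        comb = math.comb
        p_enrich = sum(comb(5, k) * comb(5, 5 - k) for k in (4, 5)) / comb(10, 5)
        p_deplete = sum(comb(5, k) * comb(5, 5 - k) for k in (0, 1, 2, 3, 4)) / comb(10, 5)
        assert row.p_enrich == pytest.approx(p_enrich, rel=1e-12)
        assert row.p_deplete == pytest.approx(p_deplete, rel=1e-12)

    def test_coord_mode_mixed_resolution_rejected(self):
        samples = self._ctx({"t1": [0], "t2": [1]})
        samples["t2"][0].source_resolution = 50_000
        with pytest.raises(ValueError, match="resolution"):
            loop_identity_overlap(samples, "COORD")


def test_planted_conservation_recovered(small_dataset):
    """All planted orthologous loops detected as 3-way conserved; private
    loops never flagged."""
    ds = small_dataset
    merged = {}
    for sp in ds.config.ingroup_species:
        calls = ds.loop_calls[sp]
        merged[sp] = associate_genes(
            merge_resolutions(calls[50_000], calls[100_000], sample_id=sp),
            ds.genes[sp],
        )
    edges, groups = conserved_loops(merged, ds.orthologs, "squid")
    n_conserved_truth = int(ds.truth["loops"]["species"].str.contains(",").sum())
    three_way = [g for g in groups if len(g["species"]) == 3]
    assert len(three_way) == n_conserved_truth
    assert all(len(g["species"]) == 3 for g in groups)
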