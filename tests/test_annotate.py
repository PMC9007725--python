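import numpy as np
import pandas as pd
import pytest

from capmeth.annotate import (
    CodingClass,
    CpGContext,
    GenicAnnotation,
    GenicCategory,
    annotate_cpg_context,
    annotate_genic,
    build_context_map,
    classify_coding,
    context_at,
    summarize_annotation,
)
from capmeth.regions import GeneModel, GenomicInterval, TargetRegion

from . import oracles


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def reg(start, end, rid="r", chrom="chr1"):
    return TargetRegion(GenomicInterval(chrom, start, end), rid)


class TestContextMap:
    def test_single_island_geometry(self):
        cmap = build_context_map([iv(10000, 10500)], {"chr1": 100_000})
        tiles = {(s, e): c for s, e, c in cmap["chr1"]}
        assert tiles[(10000, 10500)] == CpGContext.ISLAND
        assert tiles[(8000, 10000)] == CpGContext.N_SHORE
        assert tiles[(10500, 12500)] == CpGContext.S_SHORE
        assert tiles[(6000, 8000)] == CpGContext.N_SHELF
        assert tiles[(12500, 14500)] == CpGContext.S_SHELF
        assert tiles[(0, 6000)] == CpGContext.OPEN_SEA
        assert tiles[(14500, 100_000)] == CpGContext.OPEN_SEA

    def test_no_islands_all_open_sea(self):
        cmap = build_context_map([], {"chr1": 5000})
        assert cmap["chr1"] == [(0, 5000, CpGContext.OPEN_SEA)]

    def test_close_islands_split_at_midpoint(self):
        # 3 kb gap: shores collide; each base goes to the nearer island
        cmap = build_context_map([iv(10000, 10400), iv(13400, 13800)], {"chr1": 50_000})
        assert context_at(cmap, "chr1", 10400) == CpGContext.S_SHORE
        assert context_at(cmap, "chr1", 13399) == CpGContext.N_SHORE
        # midpoint: gap [10400,13400), split at 11900; tie base goes left
        assert context_at(cmap, "chr1", 11899) == CpGContext.S_SHORE
        assert context_at(cmap, "chr1", 11900) == CpGContext.N_SHORE

    def test_partition_covers_every_base_once(self):
        cmap = build_context_map([iv(3000, 3500), iv(9000, 9200)], {"chr1": 20_000})
        tiles = cmap["chr1"]
        assert tiles[0][0] == 0 and tiles[-1][1] == 20_000
        for (s1, e1, _), (s2, e2, _) in zip(tiles, tiles[1:]):
            assert e1 == s2

    def test_overlapping_islands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_context_map([iv(100, 300), iv(200, 400)], {"chr1": 1000})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = 30_000
        starts = np.sort(rng.choice(chrom_len - 500, 4, replace=False))
        islands = []
        prev_end = 0
        for s in starts:
            s = max(s, prev_end)
            e = min(int(s + rng.integers(100, 500)), chrom_len)
            if s < e:
                islands.append(iv(int(s), e))
                prev_end = e
        cmap = build_context_map(islands, {"chr1": chrom_len})
        for x in rng.integers(0, chrom_len, 300):
            assert context_at(cmap, "chr1", int(x)) == oracles.base_context(int(x), islands)


class TestRegionContext:
    CMAP = None

    def setup_method(self):
        self.islands = [iv(10000, 10500)]
        self.cmap = build_context_map(self.islands, {"chr1": 100_000})

    def test_fully_inside_island(self):
        assert annotate_cpg_context(reg(10100, 10200), self.cmap) == CpGContext.ISLAND

    def test_island_priority_beats_larger_shore_overlap(self):
        # 40% island, 60% shore: island still wins by priority
        r = reg(9700, 10200)
        assert annotate_cpg_context(r, self.cmap) == CpGContext.ISLAND

    def test_open_sea_far_from_island(self):
        assert annotate_cpg_context(reg(30000, 30500), self.cmap) == CpGContext.OPEN_SEA

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            annotate_cpg_context(reg(0, 10, chrom="chrZ"), self.cmap)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_priority_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        islands = [iv(5000, 5600), iv(9000, 9300)]
        cmap = build_context_map(islands, {"chr1": 40_000})
        for _ in range(60):
            start = int(rng.integers(0, 39_000))
            r = reg(start, start + int(rng.integers(50, 1000)))
            assert annotate_cpg_context(r, cmap) == oracles.region_context(r, islands)

    def test_priority_monotone_under_enlargement(self):
        tier = {CpGContext.ISLAND: 0, CpGContext.N_SHORE: 1, CpGContext.S_SHORE: 1,
                CpGContext.N_SHELF: 2, CpGContext.S_SHELF: 2, CpGContext.OPEN_SEA: 3}
        r = reg(10400, 10450)
        grown = reg(10400, 16000)
        assert tier[annotate_cpg_context(grown, self.cmap)] <= tier[
            annotate_cpg_context(r, self.cmap)
        ]


def make_coding_gene(gene_id="g1", strand="+"):
    # exons [1000,1400), [2000,2300), [3000,3500); CDS from 1200 to 3200
    exons = (iv(1000, 1400), iv(2000, 2300), iv(3000, 3500))
    cds = (iv(1200, 1400), iv(2000, 2300), iv(3000, 3200))
    return GeneModel(gene_id, strand, iv(1000, 3500), exons, cds)


class TestGenic:
    def test_intron_of_coding_gene(self):
        ann = annotate_genic(reg(1500, 1600), [make_coding_gene()])
        assert ann.category == GenicCategory.INTRONIC
        assert ann.distance == 0

    def test_exon_beats_intron(self):
        ann = annotate_genic(reg(1300, 1700), [make_coding_gene()])
        assert ann.category == GenicCategory.EXONIC

    def test_utr5_on_plus_strand(self):
        assert annotate_genic(reg(1050, 1100), [make_coding_gene()]).category == GenicCategory.UTR5

    def test_utr_flips_with_strand(self):
        assert annotate_genic(reg(1050, 1100), [make_coding_gene(strand="-")]).category == GenicCategory.UTR3

    def test_upstream_minus_strand_is_higher_coordinates(self):
        # 500 bp past the transcript end of a minus-strand gene -> UPSTREAM
        ann = annotate_genic(reg(4000, 4050), [make_coding_gene(strand="-")])
        assert ann.category == GenicCategory.UPSTREAM
        assert ann.distance == 500

    def test_intergenic_beyond_window(self):
        ann = annotate_genic(reg(8000, 8100), [make_coding_gene()])
        assert ann.category == GenicCategory.INTERGENIC
        assert ann.nearest_gene == "g1"
        assert ann.distance == 4500

    def test_noncoding_gene_categories(self):
        nc = GeneModel("nc1", "+", iv(1000, 2000), (iv(1000, 1200), iv(1800, 2000)))
        assert annotate_genic(reg(1100, 1150), [nc]).category == GenicCategory.NCRNA_EXONIC
        assert annotate_genic(reg(1400, 1500), [nc]).category == GenicCategory.NCRNA_INTRONIC

    def test_empty_gene_set_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            ann = annotate_genic(reg(0, 10), [])
        assert ann.category == GenicCategory.INTERGENIC
        assert ann.distance is None

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_base_category_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        chrom_len = 20_000
        genes = []
        pos = 500
        for i in range(4):
            n_ex = int(rng.integers(1, 4))
            exons = []
            p = pos
            for j in range(n_ex):
                e = p + int(rng.integers(100, 400))
                exons.append(iv(p, e))
                p = e + int(rng.integers(150, 600))
            tx = iv(exons[0].start, exons[-1].end)
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < 0.6 and exons[0].length > 60:
                lo = exons[0].start + 30
                hi = exons[-1].end - 30
                cds = tuple(
                    iv(max(ex.start, lo), min(ex.end, hi))
                    for ex in exons if ex.start < hi and ex.end > lo
                )
            else:
                cds = ()
            genes.append(GeneModel(f"g{i}", strand, tx, tuple(exons), cds))
            pos = tx.end + int(rng.integers(300, 2500))
        for _ in range(80):
            start = int(rng.integers(0, chrom_len - 600))
            r = reg(start, start + int(rng.integers(30, 600)))
            got = annotate_genic(r, genes)
            cat, gid, dist = oracles.region_genic(r, genes, chrom_len)
            assert got.category == cat
            assert got.nearest_gene == gid
            assert got.distance == dist


class TestCodingAndSummary:
    @pytest.mark.parametrize("cat,expected", [
        (GenicCategory.EXONIC, CodingClass.CODING),
        (GenicCategory.UTR5, CodingClass.NONCODING),
        (GenicCategory.INTRONIC, CodingClass.NONCODING),
        (GenicCategory.INTERGENIC, CodingClass.NONCODING),
        (GenicCategory.NCRNA_EXONIC, CodingClass.NONCODING),
    ])
    def test_coding_iff_cds_exonic(self, cat, expected):
        assert classify_coding(GenicAnnotation(cat, "g", 0 if cat != GenicCategory.INTERGENIC else 5)) == expected

    def test_summary_percentages(self):
        s = pd.Series(["A", "B", "C", "C"])
        out = summarize_annotation(s)
        assert out.loc["C", "count"] == 2
        assert out.loc["C", "percent"] == 50.0
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_summary_matches_planted_mix(self, rng):
        labels = ["NONCODING"] * 92 + ["CODING"] * 8
        s = pd.Series(rng.permutation(labels))
        out = summarize_annotation(s)
        assert out.loc["NONCODING", "percent"] == pytest.approx(92.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_annotation(pd.Series([], dtype=object))
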