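"""Context classification, genic labels, and stratified proportion tables."""

import numpy as np
import pytest

import methylfollicle as mf
from methylfollicle.annotation import primary_genic_label, proportions_from_counts
from methylfollicle.io_formats import GeneModel, GenomicInterval


@pytest.fixture
def island_index():
    islands = [GenomicInterval("chr1", 10_000, 12_000)]
    return mf.AnnotationIndex(islands, [], shore_width=2000)


@pytest.fixture
def gene_index():
    plus = GeneModel.from_exons(
        "gp", "GP", "coding", "chr1", "+",
        [GenomicInterval("chr1", 50_000, 50_400), GenomicInterval("chr1", 51_000, 51_500)],
    )
    minus = GeneModel.from_exons(
        "gm", "GM", "noncoding", "chr1", "-",
        [GenomicInterval("chr1", 80_000, 80_400), GenomicInterval("chr1", 81_000, 81_500)],
    )
    return mf.AnnotationIndex([], [plus, minus])


class TestContext:
    def test_inside_island(self, island_index):
        assert island_index.classify_cpg_context("chr1", 10_500) == "island"

    def test_shore_within_flank(self, island_index):
        assert island_index.classify_cpg_context("chr1", 12_500) == "shore"
        assert island_index.classify_cpg_context("chr1", 9_500) == "shore"

    def test_far_site_is_other(self, island_index):
        assert island_index.classify_cpg_context("chr1", 20_001) == "other"

    def test_unseen_chromosome_is_other(self, island_index):
        assert island_index.classify_cpg_context("chr9", 10_500) == "other"

    def test_island_precedence_over_neighbor_flank(self):
        # second island sits inside the first island's would-be flank
        islands = [
            GenomicInterval("chr1", 10_000, 12_000),
            GenomicInterval("chr1", 12_500, 13_000),
        ]
        index = mf.AnnotationIndex(islands, [])
        assert index.classify_cpg_context("chr1", 12_700) == "island"

    def test_shores_never_overlap_islands(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.choice(200_000, size=30, replace=False))
        islands = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(200, 2000)))
            for s in starts
        ]
        index = mf.AnnotationIndex(islands, [])
        for shore in index.shores():
            for island in islands:
                assert shore.end <= island.start or shore.start >= island.end


class TestGenicLabels:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (49_600, ["promoter"]),  # 500 bp upstream of + TSS at 50,000
            (47_000, ["1-5 kb"]),  # 3 kb upstream
            (50_200, ["exon"]),
            (50_700, ["intron"]),
            (30_000, ["intergenic"]),
        ],
    )
    def test_plus_strand_bands(self, gene_index, pos, expected):
        assert gene_index.annotate_genic(("chr1", pos)) == expected

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (81_900, ["promoter"]),  # minus strand: upstream is to the right
            (84_600, ["1-5 kb"]),
            (80_200, ["exon"]),
            (80_700, ["intron"]),
        ],
    )
    def test_minus_strand_bands(self, gene_index, pos, expected):
        assert gene_index.annotate_genic(("chr1", pos)) == expected

    def test_multi_label_region(self, gene_index):
        region = GenomicInterval("chr1", 49_500, 50_300)  # spans promoter + exon
        assert gene_index.annotate_genic(region) == ["promoter", "exon"]

    def test_enhancer_requires_track(self):
        enh = [GenomicInterval("chr1", 1000, 2000)]
        with_track = mf.AnnotationIndex([], [], enhancers=enh)
        without = mf.AnnotationIndex([], [])
        assert with_track.annotate_genic(("chr1", 1500)) == ["enhancer"]
        assert without.annotate_genic(("chr1", 1500)) == ["intergenic"]

    def test_label_list_never_empty(self, gene_index):
        assert gene_index.annotate_genic(("chr7", 123)) == ["intergenic"]

    def test_primary_label_precedence(self):
        assert primary_genic_label(["intron", "promoter"]) == "promoter"
        assert primary_genic_label([]) == "intergenic"


class TestBiotypeSplit:
    def _dms(self, pos):
        return mf.CpGTestResult("chr1", pos, 1, 1, 80.0, 20.0, 60.0, 1e-8)

    def test_all_coding(self, gene_index):
        split = mf.feature_biotype_split([self._dms(50_100)], gene_index)
        assert (split.coding_fraction, split.noncoding_fraction) == (1.0, 0.0)

    def test_even_split(self, gene_index):
        sites = [self._dms(50_100), self._dms(80_300)]
        split = mf.feature_biotype_split(sites, gene_index)
        assert split.coding_fraction == pytest.approx(0.5)
        assert split.n_features == 2

    def test_no_features_flagged(self, gene_index):
        split = mf.feature_biotype_split([self._dms(5)], gene_index)
        assert split.n_features == 0 and split.note == "no features in window"

    def test_fractions_over_unique_features_not_sites(self, gene_index):
        sites = [self._dms(50_100), self._dms(50_200), self._dms(50_300)]
        split = mf.feature_biotype_split(sites, gene_index)
        assert split.n_features == 1


class TestProportions:
    def _dms(self, pos, direction):
        diff = 40.0 if direction == "hyper" else -40.0
        return mf.CpGTestResult(
            "chr1", pos, 1, 1, 50 + diff, 50.0, diff, 1e-8,
            q_value=1e-6, is_dms=True, direction=direction,
        )

    def test_partition_and_percent_sum(self, island_index):
        sites = [
            self._dms(10_100, "hyper"),
            self._dms(10_200, "hypo"),
            self._dms(12_500, "hypo"),
            self._dms(50_000, "hyper"),
        ]
        table = mf.proportions_table(sites, "context", island_index)
        for stratum, expected_total in (("hyper", 2), ("hypo", 2), ("all", 4)):
            rows = table.stratum(stratum)
            assert sum(r.count for r in rows) == expected_total
            assert sum(r.percent for r in rows) == pytest.approx(100.0, abs=0.1)

    def test_single_category_hits_hundred(self, island_index):
        sites = [self._dms(10_100, "hyper"), self._dms(10_200, "hyper")]
        table = mf.proportions_table(sites, "context", island_index)
        assert table.percent("all", "island") == 100.0

    def test_unknown_classifier(self, island_index):
        with pytest.raises(ValueError):
            mf.proportions_table([], "nope", island_index)

    def test_from_printed_counts(self):
        table = proportions_from_counts({"island": 343, "shore": 313, "other": 3173})
        assert table.percent("all", "island") == 9.0
        assert table.percent("all", "shore") == 8.2
        assert table.percent("all", "other") == 82.9
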