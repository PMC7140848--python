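"""Aligner exactness, category assignment and the classification table."""

import numpy as np
import pandas as pd
import pytest

from mirpipe.classify import (Annotation, GenomeIndex, align_tag,
                              assign_category, brute_force_align,
                              build_category_table, format_percent,
                              match_known, revcomp)


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(7)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=10_000))}


@pytest.fixture(scope="module")
def genome_index(random_genome):
    return GenomeIndex(random_genome)


class TestAligner:
    def test_exact_substring_hit(self, random_genome, genome_index):
        tag = random_genome["chr1"][500:524]
        hits = align_tag(tag, genome_index, 0)
        assert any(h.start == 500 and h.strand == "+" and h.mismatches == 0
                   for h in hits)

    def test_reverse_complement_hit(self, random_genome, genome_index):
        tag = revcomp(random_genome["chr1"][800:824])
        hits = align_tag(tag, genome_index, 0)
        assert any(h.start == 800 and h.strand == "-" for h in hits)

    def test_no_hit_returns_empty(self, genome_index):
        assert align_tag("A" * 24, genome_index, 0) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2, 3])
    def test_equals_brute_force_scan(self, random_genome, genome_index,
                                     max_mm):
        """Seeded pigeonhole search is exact for 0-3 mismatches."""
        rng = np.random.default_rng(max_mm)
        for trial in range(15):
            if trial % 2 == 0:  # planted hit with mutations
                start = int(rng.integers(0, 9_900))
                tag = list(random_genome["chr1"][start:start + 24])
                for pos in rng.choice(24, size=max_mm, replace=False):
                    tag[pos] = "ACGT"[int(rng.integers(4))]
                tag = "".join(tag)
            else:
                tag = "".join(rng.choice(list("ACGT"), size=24))
            fast = align_tag(tag, genome_index, max_mm)
            slow = brute_force_align(tag, random_genome, max_mm)
            assert fast == slow

    def test_short_tag_precondition(self, genome_index):
        with pytest.raises(ValueError):
            align_tag("ACGTACGTACGTACG", genome_index, 3)  # 15 nt, needs 20


class TestAssignCategory:
    @pytest.fixture
    def annotation(self):
        return Annotation(pd.DataFrame([
            dict(chrom="chr1", start=100, end=200, strand="+",
                 feature="tRNA", name="trna1"),
            dict(chrom="chr1", start=300, end=400, strand="+",
                 feature="Exon", name="exon1"),
            dict(chrom="chr1", start=350, end=380, strand="+",
                 feature="Mature", name="mat1"),
        ]))

    def _hit(self, start, end):
        from mirpipe.classify import AlignmentHit
        return AlignmentHit("N" * (end - start), "chr1", start, end, "+", 0)

    def test_no_hits_is_unmapped(self, annotation):
        assert assign_category([], annotation) == "Unmapped"

    def test_trna_locus(self, annotation):
        assert assign_category([self._hit(120, 141)], annotation) == "tRNA"

    def test_priority_mature_over_exon(self, annotation):
        assert assign_category([self._hit(355, 376)], annotation) == "Mature"

    def test_intergenic_when_nothing_overlaps(self, annotation):
        assert assign_category([self._hit(5000, 5021)], annotation) == \
            "Intergenic"

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            Annotation(pd.DataFrame([
                dict(chrom="chr1", start=10, end=10, strand="+",
                     feature="Exon", name="bad")]))


class TestCategoryTable:
    def test_printed_percentages(self):
        """Percentage formatting reproduces published table cells."""
        assert format_percent(98_508, 25_331_960) == "0.39"
        assert format_percent(1_076_247, 19_999_279) == "5.38"
        assert format_percent(9_454_199, 22_632_118) == "41.77"
        assert format_percent(1_283_163, 26_275_173) == "4.88"
        assert format_percent(939_369, 27_647_469) == "3.4"
        assert format_percent(25_331_960, 25_331_960) == "100"

    def test_counts_sum_to_total_and_cells_formatted(self):
        from collections import Counter
        counts = {"lib": Counter(
            {"Intergenic": 50, "Mature": 30, "rRNA": 15, "Unmapped": 5})}
        table = build_category_table(counts)
        t = table.set_index("category")
        assert t.at["Total", "lib_count"] == 100
        assert t.at["rRNA", "lib_cell"] == "15(15%)"
        body = t.drop("Total")["lib_count"].sum()
        assert body == 100

    def test_all_unmapped(self):
        from collections import Counter
        table = build_category_table({"lib": Counter({"Unmapped": 10})})
        t = table.set_index("category")
        assert t.at["Unmapped", "lib_pct"] == 100.0
        assert t.at["Mature", "lib_count"] == 0


class TestMatchKnown:
    CATALOG = {"mirA": "ACGTACGTACGTACGTACGTA",
               "mirB": "TTTTACGTACGTACGTACGTA"}

    def test_exact_match(self):
        m = match_known("ACGTACGTACGTACGTACGTA", self.CATALOG)
        assert m.catalog_id == "mirA" and m.mismatches == 0

    def test_three_mismatches_still_matches(self):
        tag = "TCGTGCGTCCGTACGTACGTA"  # 3 mismatches vs mirA, 4 vs mirB
        m = match_known(tag, self.CATALOG)
        assert m is not None and m.catalog_id == "mirA" and m.mismatches == 3

    def test_four_mismatches_is_novel(self):
        tag = "TCGTGCGTCCGTGCGTACGTA"  # 4 mismatches vs mirA, 5 vs mirB
        assert match_known(tag, self.CATALOG) is None

    def test_length_mismatch_never_matches(self):
        assert match_known("ACGTACGTACGTACGTACGT", self.CATALOG) is None

    def test_tie_broken_lexicographically(self):
        catalog = {"z_mir": "AAAACCCCGGGGTTTTAAAAC",
                   "a_mir": "AAAACCCCGGGGTTTTAAAAC"}
        m = match_known("AAAACCCCGGGGTTTTAAAAC", catalog)
        assert m.catalog_id == "a_mir"

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            match_known("ACGT", {})


class TestSyntheticClassRecovery:
    def test_planted_class_fractions_recovered(self, small_config, small_run,
                                               small_reference):
        """Structural-RNA class fractions recovered within 3 sigma."""
        from mirpipe.benchmark import ncrna_fraction_zscores
        _, _, _, truth = small_reference
        _, bundle = small_run
        z = ncrna_fraction_zscores(bundle, truth, small_config)
        assert (z["z"].abs() <= 3.0).all(), z.to_string()
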