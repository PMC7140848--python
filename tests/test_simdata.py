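"""Synthetic study generator: determinism, truth consistency, composition."""

import numpy as np
import pandas as pd
import pytest

from mirpipe import simdata
from mirpipe.rnafold import fold_mfe
from mirpipe.simdata import (LibrarySpec, PlacementError, SimConfig,
                             default_libraries, make_reference,
                             simulate_library, simulate_qpcr)


class TestConfigValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, ncrna_fractions={"rRNA": 0.7, "tRNA": 0.4})

    def test_placement_error_names_offenders(self):
        with pytest.raises(PlacementError, match="genome_length"):
            make_reference(SimConfig(seed=1, genome_length=2_000,
                                     n_known_mirnas=40))

    def test_unknown_library_rejected(self, small_config, small_reference):
        _, _, _, truth = small_reference
        with pytest.raises(KeyError):
            simulate_library(truth, "XX_99h", small_config)


class TestMakeReference:
    def test_empty_catalog_case(self):
        config = SimConfig(seed=5, n_known_mirnas=0, n_novel_precursors=0,
                           genome_length=30_000)
        genome, annotation, catalog, truth = make_reference(config)
        assert catalog == {}
        assert set(annotation["feature"]) <= {
            "rRNA", "tRNA", "snRNA", "snoRNA", "Rfam_other", "Exon", "Intron"}

    def test_deterministic(self):
        a = make_reference(SimConfig(seed=42, genome_length=40_000,
                                     n_known_mirnas=5, n_novel_precursors=3))
        b = make_reference(SimConfig(seed=42, genome_length=40_000,
                                     n_known_mirnas=5, n_novel_precursors=3))
        assert a[0] == b[0]
        assert a[1].equals(b[1])
        assert a[2] == b[2]
        assert a[3].planted_counts.equals(b[3].planted_counts)

    def test_loci_inside_genome_and_disjoint(self, small_config,
                                             small_reference):
        genome, _, _, truth = small_reference
        loci = truth.planted_loci.sort_values("start")
        assert (loci["start"] >= 0).all()
        assert (loci["end"] <= len(genome["chr1"])).all()
        assert (loci["start"].to_numpy()[1:]
                >= loci["end"].to_numpy()[:-1]).all()

    def test_planted_hairpin_fold_recovers_designed_pairs(self):
        """Folding an excised planted precursor recovers >= 80% of the
        designed stem pairing."""
        config = SimConfig(seed=9, genome_length=30_000, n_known_mirnas=0,
                           n_novel_precursors=1)
        genome, _, _, truth = make_reference(config)
        (name, info), = truth.precursors.items()
        st = fold_mfe(info["seq"])
        assert st.mfe < 0
        designed = set(map(tuple, info["designed_pairs"]))
        recovered = designed & set(map(tuple, st.pairs))
        assert len(recovered) / len(designed) >= 0.8

    def test_truth_directions_consistent_with_counts(self, small_reference):
        """Planted 'up' miRNAs have treated/control mean ratio > 1."""
        _, _, _, truth = small_reference
        de = truth.planted_de.set_index("mirna")
        for mirna, row in de.iterrows():
            if row["direction"] == "ns":
                continue
            geno = "HS" if row["membership"] == "HS-only" else "HT"
            c0 = truth.planted_counts.at[mirna, f"{geno}_0h"]
            c6 = truth.planted_counts.at[mirna, f"{geno}_6h"]
            if row["direction"] == "up":
                assert c6 > c0
            else:
                assert c6 < c0

    def test_novel_precursors_absent_from_catalog(self, small_reference):
        _, _, catalog, truth = small_reference
        novel_seqs = {truth.mature_seqs[n] for n in truth.mature_seqs
                      if n.startswith("nov")}
        assert novel_seqs.isdisjoint(set(catalog.values()))


class TestSimulateLibrary:
    def test_zero_depth_is_empty(self, small_reference):
        _, _, _, truth = small_reference
        config = SimConfig(seed=1, libraries=[LibrarySpec("HT", 0, 0)])
        assert simulate_library(truth, "HT_0h", config) == []

    def test_deterministic(self, small_config, small_reference):
        _, _, _, truth = small_reference
        a = simulate_library(truth, "HT_6h", small_config)
        b = simulate_library(truth, "HT_6h", small_config)
        assert a == b

    def test_read_count_matches_depth(self, small_config, small_reference):
        _, _, _, truth = small_reference
        reads = simulate_library(truth, "HS_0h", small_config)
        assert len(reads) == small_config.library("HS_0h").depth

    def test_planted_abundance_recovered_at_low_dispersion(self):
        """A miRNA planted at known abundance lands within 3 binomial sigma
        of its expectation when dispersion -> 0 (Poisson sampling)."""
        depth = 100_000
        config = SimConfig(seed=21, dispersion=0.0, genome_length=60_000,
                           n_known_mirnas=6, n_novel_precursors=2,
                           libraries=[LibrarySpec("HT", 0, depth)])
        _, _, _, truth = make_reference(config)
        reads = simulate_library(truth, "HT_0h", config)
        seqs = [seq for _, seq in reads]
        for mirna, mean in truth.planted_counts["HT_0h"].items():
            tag = truth.mature_seqs[mirna] + config.adapter
            observed = sum(1 for s in seqs if s == tag)
            sigma = np.sqrt(mean)
            assert abs(observed - mean) <= 3 * sigma + 1


class TestSimulateQpcr:
    def test_noiseless_construction_is_exact(self, small_reference):
        """With zero noise 2^-ddCt equals 2^planted-lfc exactly."""
        from mirpipe.downstream import qpcr_table
        _, _, _, truth = small_reference
        ct = simulate_qpcr(truth, noise_sd=0.0, seed=1)
        table = qpcr_table(ct).set_index("mirna")
        de = truth.planted_de.set_index("mirna")
        for mirna, row in table.iterrows():
            assert row["relative_expression"] == pytest.approx(
                2.0 ** de.at[mirna, "lfc"])

    def test_negative_noise_rejected(self, small_reference):
        _, _, _, truth = small_reference
        with pytest.raises(ValueError):
            simulate_qpcr(truth, noise_sd=-1.0, seed=1)

    def test_noisy_fixture_correlates_with_truth(self, small_reference):
        """8 assays at 0.2 Ct noise give r^2 >= 0.8 against planted lfc."""
        from mirpipe.downstream import corr_validation, qpcr_table
        _, _, _, truth = small_reference
        ct = simulate_qpcr(truth, noise_sd=0.2, seed=33)
        table = qpcr_table(ct).set_index("mirna")
        de = truth.planted_de.set_index("mirna")
        planted = [de.at[m, "lfc"] for m in table.index]
        _, r2 = corr_validation(table["qpcr_log2fc"], planted)
        assert r2 >= 0.8
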