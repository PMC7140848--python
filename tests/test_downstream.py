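"""Target scanning, consensus, enrichment, qPCR quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from mirpipe.classify import revcomp
from mirpipe.downstream import (TargetHit, consensus_targets, corr_validation,
                                ddct, enrich_terms, hypergeom_enrich,
                                scan_targets, score_target)

MIRNA = "TCAAGCTGGTGTCTGGATGAG"


class TestScoreTarget:
    def test_perfect_site_scores_zero(self):
        penalty, aln = score_target(MIRNA, revcomp(MIRNA))
        assert penalty == 0.0
        assert set(aln) == {"|"}

    def test_gu_outside_core_is_half_point(self):
        # give miRNA position 20 (1-based, weight 1) a G and the opposing
        # target base a T -> single G:U wobble
        q = list(MIRNA)
        q[19] = "G"
        site = list(revcomp("".join(q)))
        site[len(site) - 20] = "T"
        penalty, _ = score_target("".join(q), "".join(site))
        assert penalty == pytest.approx(0.5)

    def test_mismatch_in_core_is_doubled(self):
        site = list(revcomp(MIRNA))
        pos = 10  # miRNA position 10 (1-based), inside the 2-13 core
        site[len(site) - pos] = MIRNA[pos - 1]  # same base cannot pair
        penalty, _ = score_target(MIRNA, "".join(site))
        assert penalty == pytest.approx(2.0)

    def test_gap_costs_two_doubled_in_core(self):
        # a 1-nt target bulge outside the core
        site = revcomp(MIRNA)
        bulged = site[:3] + "A" + site[3:]  # near miRNA 3' end -> weight 1
        penalty, aln = score_target(MIRNA, bulged)
        assert penalty <= 2.0 and "-" in aln


class TestScanAndConsensus:
    def test_planted_sites_found_by_both_scorers(self):
        rng = np.random.default_rng(2)
        transcripts = {}
        planted = {}
        for i in range(20):
            name = f"tx{i}"
            seq = "".join(rng.choice(list("ACGT"), size=200))
            pos = int(rng.integers(30, 150))
            site = revcomp(MIRNA)
            transcripts[name] = seq[:pos] + site + seq[pos + len(site):]
            planted[name] = pos
        hits_a, hits_b = scan_targets("m", MIRNA, transcripts)
        found_a = {(h.transcript_id, h.start) for h in hits_a}
        found_b = {(h.transcript_id, h.start) for h in hits_b}
        for name, pos in planted.items():
            assert (name, pos) in found_a, "scorer A missed a perfect site"
            assert (name, pos) in found_b, "scorer B missed a perfect site"
        consensus = consensus_targets(hits_a, hits_b)
        assert {(h.transcript_id, h.start) for h in consensus} >= set(
            (n, p) for n, p in planted.items())

    def test_recall_matches_exhaustive_window_scan(self):
        """Every window under the cutoff is reported (brute-force check)."""
        rng = np.random.default_rng(8)
        tx = {"t": "".join(rng.choice(list("ACGT"), size=400))}
        hits_a, _ = scan_targets("m", MIRNA, tx, cutoff=14.0)
        got = {(h.start, h.end) for h in hits_a}
        n = len(MIRNA)
        seq = tx["t"]
        for start in range(len(seq) - n + 1):
            penalty, _ = score_target(MIRNA, seq[start:start + n])
            if penalty <= 14.0:
                assert (start, start + n) in got

    def test_site_over_cutoff_absent(self):
        site = revcomp(MIRNA)
        mutated = list(site)
        for pos in (0, 4, 9):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[pos]]
        tx = {"t": "A" * 50 + "".join(mutated) + "A" * 50}
        hits_a, _ = scan_targets("m", MIRNA, tx, cutoff=4.0)
        assert all(not (50 <= h.start < 50 + len(site)) or
                   h.penalty_score <= 4.0 for h in hits_a)

    def test_consensus_is_subset_and_requires_both(self):
        h = TargetHit("m", "t", 10, 31, 1.0, 0.9, "", frozenset("A"))
        only_a = consensus_targets([h], [])
        assert only_a == []
        partner = TargetHit("m", "t", 12, 33, 2.0, 0.8, "", frozenset("B"))
        merged = consensus_targets([h], [partner])
        assert len(merged) == 1 and merged[0].scorers == frozenset("AB")


class TestHypergeometric:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_enrich(0, 5, 10, 50) == 1.0

    def test_complete_overlap_combinatorial_value(self):
        assert hypergeom_enrich(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_saturated_case(self):
        assert hypergeom_enrich(7, 7, 7, 7) == pytest.approx(1.0)

    def test_matches_brute_force_grid(self):
        """Exhaustive agreement with direct pmf summation for N <= 60."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = float(hypergeom.pmf(
                np.arange(k, min(n, K) + 1), N, K, n).sum()) if k else 1.0
            assert hypergeom_enrich(k, n, K, N) == pytest.approx(
                expected, rel=1e-9, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(6, 5, 10, 50)


class TestEnrichTerms:
    def _term_map(self):
        rows = []
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        for g in genes:
            for t in rng.choice([f"T{j}" for j in range(8)], size=2,
                                replace=False):
                rows.append(dict(gene=g, term_id=t, term_name=t,
                                 namespace="bp"))
        for g in genes[:10]:
            rows.append(dict(gene=g, term_id="T_hot", term_name="hot",
                             namespace="bp"))
        return pd.DataFrame(rows)

    def test_planted_term_ranks_first(self):
        tm = self._term_map()
        result = enrich_terms([f"g{i}" for i in range(8)], tm)
        assert result.iloc[0]["term_id"] == "T_hot"
        assert result.iloc[0]["p_adj"] <= 0.05

    def test_study_equals_universe_gives_p_one(self):
        tm = self._term_map()
        result = enrich_terms(sorted(set(tm["gene"])), tm)
        assert np.allclose(result["p"], 1.0)

    def test_unknown_study_gene_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            enrich_terms(["ghost"], self._term_map())

    def test_null_calibration(self):
        """Uniformly drawn study sets: fraction of p <= 0.05 stays near or
        below nominal over many replicates."""
        tm = self._term_map()
        genes = sorted(set(tm["gene"]))
        rng = np.random.default_rng(123)
        n_sig = n_tests = 0
        for _ in range(400):
            study = list(rng.choice(genes, size=8, replace=False))
            res = enrich_terms(study, tm)
            n_sig += int((res["p"] <= 0.05).sum())
            n_tests += len(res)
        assert n_sig / n_tests <= 0.07


class TestQpcr:
    def test_all_equal_ct_gives_unity(self):
        assert ddct(20, 20, 20, 20) == 1.0

    def test_worked_examples(self):
        assert ddct(24, 20, 26, 20) == 4.0  # ddCt = -2
        assert ddct(26, 20, 25, 20) == 0.5  # ddCt = +1

    def test_shift_invariance(self):
        base = ddct(24.3, 19.2, 26.1, 20.4)
        assert ddct(27.3, 22.2, 29.1, 23.4) == pytest.approx(base)

    def test_correlation_closed_forms(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        r, r2 = corr_validation(x, x)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)
        r, r2 = corr_validation(x, -x)
        assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8)
        y = 1.3 * x + rng.normal(scale=0.3, size=8)
        _, r2 = corr_validation(x, y)
        # independent computation: R^2 of the least-squares fit
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = (resid ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            corr_validation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
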