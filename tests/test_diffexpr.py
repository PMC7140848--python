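"""Exact two-library test, normalization, FDR and DE calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from mirpipe.diffexpr import (ac_pvalue, bh_fdr, call_direction, floor_zero,
                              log2fc, low_expression_filter, membership,
                              normalize_tpm, run_contrast)


class TestNormalization:
    def test_published_count_normalizes_to_tpm(self):
        assert normalize_tpm(155, 25_331_960) == pytest.approx(6.1188, abs=1e-4)

    def test_zero_count(self):
        assert normalize_tpm(0, 1000) == 0.0

    def test_total_equals_count(self):
        assert normalize_tpm(1000, 1000) == 1e6

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_tpm(5, 0)

    def test_floor_replaces_only_exact_zero(self):
        assert floor_zero(0.0) == 0.01
        assert floor_zero(0.005) == 0.005
        assert floor_zero(6.1188) == 6.1188

    def test_low_expression_filter(self):
        expr = pd.DataFrame({"l1": [0.2, 0.2, 2.0], "l2": [0.5, 1.0, 3.0],
                             "l3": [0.9, 0.4, 4.0]},
                            index=["dropped", "kept_boundary", "kept"])
        kept = low_expression_filter(expr)
        assert list(kept.index) == ["kept_boundary", "kept"]


class TestLog2FoldChange:
    def test_equal_gives_zero(self):
        assert log2fc(5.0, 5.0) == 0.0

    def test_doubling_gives_one(self):
        assert log2fc(3.0, 6.0) == 1.0

    def test_published_count_ratio(self):
        # 26 vs 111 at equal effective totals prints as -2.09
        assert f"{log2fc(111.0, 26.0):.2f}" == "-2.09"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2fc(0.0, 5.0)


class TestExactTest:
    def test_point_mass_closed_forms(self):
        assert ac_pvalue(0, 0, 10, 10).point_mass == pytest.approx(0.5)
        assert ac_pvalue(1, 1, 10, 10).point_mass == pytest.approx(0.25)

    @pytest.mark.parametrize("x,y", [(0, 0), (155, 47), (1494, 494),
                                     (30, 1), (0, 37), (97, 477)])
    def test_tails_match_negative_binomial_oracle(self, x, y):
        """p(y|x) is NB(x+1, 1/(1+r)); tails must agree to 1e-10."""
        n1, n2 = 25_331_960.0, 22_632_118.0
        q = 1.0 / (1.0 + n2 / n1)
        res = ac_pvalue(x, y, n1, n2)
        assert res.point_mass == pytest.approx(nbinom.pmf(y, x + 1, q),
                                               rel=1e-10)
        assert res.lower_tail == pytest.approx(nbinom.cdf(y, x + 1, q),
                                               rel=1e-10)
        assert res.upper_tail == pytest.approx(nbinom.sf(y - 1, x + 1, q),
                                               rel=1e-10)

    def test_distribution_sums_to_one(self):
        n1, n2 = 1e6, 1.3e6
        x = 40
        total = sum(ac_pvalue(x, y, n1, n2).point_mass for y in range(400))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_tail_identity_at_point(self):
        res = ac_pvalue(12, 30, 5e5, 6e5)
        assert res.lower_tail + res.upper_tail == pytest.approx(
            1.0 + res.point_mass, abs=1e-12)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_with_equal_totals(self, x, y):
        """Swapping the libraries preserves the point mass exactly; the
        two-sided p can differ only through tail discreteness, which is
        bounded by one point mass (the tails condition on x, so the swap
        shifts each tail sum by at most the shared p(y|x))."""
        a = ac_pvalue(x, y, 1e6, 1e6)
        b = ac_pvalue(y, x, 1e6, 1e6)
        assert a.point_mass == pytest.approx(b.point_mass, rel=1e-9)
        assert abs(a.p_two_sided - b.p_two_sided) <= 2 * a.point_mass + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_pvalue(-1, 5, 1e6, 1e6)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        assert np.allclose(bh_fdr(p),
                           multipletests(p, method="fdr_bh")[1])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestCalls:
    def test_direction_thresholds(self):
        assert call_direction(3.70, 1e-6) == "up"
        assert call_direction(-0.5, 1e-9) == "ns"  # below lfc threshold
        assert call_direction(-2.0, 0.5) == "ns"  # not significant
        assert call_direction(-1.71, 3.28e-5, alpha=0.01) == "down"

    def test_membership_labels(self):
        ht = pd.DataFrame({"mirna_id": ["a", "b", "c", "d"],
                           "direction": ["up", "down", "ns", "ns"]})
        hs = pd.DataFrame({"mirna_id": ["a", "b", "c", "d"],
                           "direction": ["ns", "up", "down", "ns"]})
        labels = membership(ht, hs)
        assert labels["a"] == "HT-only"
        assert labels["b"] == "both"
        assert labels["c"] == "HS-only"
        assert labels["d"] == "none"

    def test_prefiltered_contrast_keeps_low_rows(self):
        """A miRNA under 1 TPM in the contrast pair is still tested when the
        caller filtered across all libraries (prefiltered=True)."""
        counts = pd.DataFrame({"l1": [0, 500], "l2": [0, 480]},
                              index=["silent_here", "expressed"])
        totals = {"l1": 1e6, "l2": 1e6}
        assert len(run_contrast(counts, totals, "l1", "l2")) == 1
        df = run_contrast(counts, totals, "l1", "l2", prefiltered=True)
        assert set(df["mirna_id"]) == {"silent_here", "expressed"}
        row = df.set_index("mirna_id").loc["silent_here"]
        assert row["log2fc"] == 0.0 and row["direction"] == "ns"

    def test_run_contrast_recovers_planted_change(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame({
            "l1": rng.poisson(200, size=20), "l2": rng.poisson(200, size=20)},
            index=[f"m{i}" for i in range(20)])
        counts.loc["m0", "l2"] = 820  # ~4x planted change
        df = run_contrast(counts, {"l1": 1e5, "l2": 1e5}, "l1", "l2")
        row = df.set_index("mirna_id").loc["m0"]
        assert row["direction"] == "up"
        assert row["log2fc"] == pytest.approx(2.0, abs=0.35)
        assert (df.set_index("mirna_id").drop("m0")["direction"] == "ns").all()
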