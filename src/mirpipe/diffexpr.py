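"""Exact count-based differential expression between two sRNA libraries.

Expression is normalized to reads per million clean reads
(``N = c / T * 1e6``); exact zeros are floored to 0.01 so that fold changes
``log2(N2/N1)`` stay finite, and miRNAs below 1 TPM in every library are
dropped before testing.

Significance comes from the exact two-library count model: conditional on a
tag's count ``x`` in library 1 (clean total ``N1``), its count ``y`` in
library 2 (total ``N2``) follows

    p(y|x) = r^y * (x+y)! / (x! y!) * (1+r)^-(x+y+1),    r = N2/N1,

a negative-binomial distribution with ``x+1`` successes at success
probability ``1/(1+r)`` — the identity the tests use as an independent
oracle.  The lower tail ``C = P(y' <= y | x)`` and upper tail
``D = P(y' >= y | x)`` combine into the two-sided p-value
``min(1, 2*min(C, D))``, adjusted across miRNAs by Benjamini-Hochberg.

p-values are computed from raw counts with the clean-read totals; fold
changes from floored TPM.  Defaults: FDR <= 0.01 and |log2FC| >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ZERO_FLOOR = 0.01


def normalize_tpm(count: float, total_clean_reads: float) -> float:
    """Reads per million clean reads, full precision."""
    if total_clean_reads <= 0:
        raise ValueError("total clean reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean_reads * 1e6


def floor_zero(tpm: float) -> float:
    """Replace an exact zero by 0.01; small positives pass through."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    return ZERO_FLOOR if tpm == 0 else tpm


def low_expression_filter(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop rows (miRNAs) whose pre-floor TPM is < 1 in every library."""
    return expr.loc[(expr >= 1.0).any(axis=1)]


def log2fc(n1: float, n2: float) -> float:
    if n1 <= 0 or n2 <= 0:
        raise ValueError("log2 fold change needs positive (floored) TPM")
    return math.log2(n2 / n1)


@dataclass(frozen=True)
class ExactTestResult:
    x: int
    y: int
    n1_total: float
    n2_total: float
    point_mass: float
    lower_tail: float  # C(y' <= y | x)
    upper_tail: float  # D(y' >= y | x)
    p_two_sided: float


def _log_point_mass(x: int, y: int, log_r: float) -> float:
    return (y * log_r
            + math.lgamma(x + y + 1) - math.lgamma(x + 1) - math.lgamma(y + 1)
            - (x + y + 1) * math.log1p(math.exp(log_r)))


def ac_pvalue(x: int, y: int, n1_total: float, n2_total: float) -> ExactTestResult:
    """Exact two-library test for one tag (log-space, overflow-safe).

    The lower tail is accumulated with the stable recurrence
    ``p(y+1|x) = p(y|x) * r/(1+r) * (x+y+1)/(y+1)``; the upper tail closes
    via ``D = 1 - C + p(y|x)``.
    """
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ValueError("counts must be non-negative integers")
    if n1_total <= 0 or n2_total <= 0:
        raise ValueError("library totals must be positive")
    r = n2_total / n1_total
    log_r = math.log(r)
    log_p = _log_point_mass(x, y, log_r)
    point = math.exp(log_p)
    # Both tails by forward recurrence p(y+1|x) = p(y|x)*r/(1+r)*(x+y+1)/(y+1),
    # accumulated in log space so deep tails neither underflow nor suffer the
    # catastrophic cancellation of the 1 - C + p closure.
    log_ratio_base = log_r - math.log1p(r)
    log_p_cur = _log_point_mass(x, 0, log_r)
    log_c = log_p_cur
    for yy in range(0, y):
        log_p_cur += log_ratio_base + math.log((x + yy + 1) / (yy + 1))
        log_c = np.logaddexp(log_c, log_p_cur)
    c = min(math.exp(log_c), 1.0)
    # upper tail: sum from y until past the mode and negligible
    log_p_cur = log_p
    log_d = log_p
    yy = y
    while True:
        step = log_ratio_base + math.log((x + yy + 1) / (yy + 1))
        log_p_cur += step
        log_d = np.logaddexp(log_d, log_p_cur)
        yy += 1
        if step < 0 and log_p_cur < log_d - 45.0:
            break
    d = min(math.exp(log_d), 1.0)
    p2 = min(1.0, 2.0 * min(c, d))
    return ExactTestResult(x, y, n1_total, n2_total, point, c, d, p2)


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class DERecord:
    mirna_id: str
    contrast: str
    count1: int
    count2: int
    tpm1: float
    tpm2: float
    log2fc: float
    p: float
    fdr: float
    direction: str  # up / down / ns


def run_contrast(
    counts: pd.DataFrame,
    totals: dict[str, float],
    lib1: str,
    lib2: str,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
    contrast_name: str | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Full exact-test contrast ``lib2 vs lib1`` over a count matrix.

    ``counts``: miRNA x library integer matrix; ``totals``: clean-read totals
    per library (the normalization denominators).  Unless ``prefiltered``,
    rows failing the <1-TPM-everywhere filter (over these two libraries) are
    dropped — callers with the full library set should filter across all
    libraries first and pass ``prefiltered=True``.
    """
    name = contrast_name or f"{lib2}_vs_{lib1}"
    tpm = counts[[lib1, lib2]].apply(
        lambda col: col / totals[col.name] * 1e6)
    keep = tpm.index if prefiltered else low_expression_filter(tpm).index
    records = []
    for mirna in keep:
        x = int(counts.at[mirna, lib1])
        y = int(counts.at[mirna, lib2])
        res = ac_pvalue(x, y, totals[lib1], totals[lib2])
        n1 = floor_zero(tpm.at[mirna, lib1])
        n2 = floor_zero(tpm.at[mirna, lib2])
        records.append((mirna, name, x, y, n1, n2, log2fc(n1, n2), res.p_two_sided))
    df = pd.DataFrame(records, columns=[
        "mirna_id", "contrast", "count1", "count2", "tpm1", "tpm2",
        "log2fc", "p"])
    df["fdr"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    df["direction"] = [
        call_direction(lfc, fdr, alpha, lfc_threshold)
        for lfc, fdr in zip(df["log2fc"], df["fdr"])
    ]
    return df


def call_direction(lfc: float, fdr: float, alpha: float = 0.01,
                   lfc_threshold: float = 1.0) -> str:
    """up / down / ns from an adjusted p-value and a fold-change threshold."""
    if fdr <= alpha:
        if lfc >= lfc_threshold:
            return "up"
        if lfc <= -lfc_threshold:
            return "down"
    return "ns"


def membership(ht_calls: pd.DataFrame, hs_calls: pd.DataFrame) -> pd.Series:
    """Genotype-membership labels from per-contrast DE tables.

    A miRNA significant (direction != ns) in at least one contrast of a
    genotype counts for that genotype, once — labels are HT-only / HS-only /
    both / none.
    """
    def sig_set(calls: pd.DataFrame) -> set[str]:
        if calls.empty:
            return set()
        return set(calls.loc[calls["direction"] != "ns", "mirna_id"])

    ht = sig_set(ht_calls)
    hs = sig_set(hs_calls)
    universe = sorted(
        set(ht_calls.get("mirna_id", pd.Series(dtype=str)))
        | set(hs_calls.get("mirna_id", pd.Series(dtype=str))))
    labels = {}
    for m in universe:
        if m in ht and m in hs:
            labels[m] = "both"
        elif m in ht:
            labels[m] = "HT-only"
        elif m in hs:
            labels[m] = "HS-only"
        else:
            labels[m] = "none"
    return pd.Series(labels, name="membership")
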