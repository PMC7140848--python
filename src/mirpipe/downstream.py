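"""Target prediction, term enrichment and qPCR concordance.

Target sites are scored with the plant-miRNA penalty scheme used by the
TargetFinder/TAPIR lineage of tools: mismatch 1.0, G:U wobble 0.5, gap 2.0,
all doubled within miRNA positions 2-13 (5'->3'); a site passes scorer A at
penalty <= 4.0 and scorer B additionally requires the duplex stacking energy
to reach 70% of the perfect-complement duplex under the folding energy
model.  Only sites called by both scorers (>= 50% overlap) survive the
consensus.

Term enrichment is the upper-tail hypergeometric test (log-space) with
Benjamini-Hochberg correction, against a configurable gene universe
(default: every gene in the supplied term map).

qPCR relative expression uses 2^-ddCt with U6 as the default reference and
an assumed amplification efficiency of exactly 2; sequencing concordance is
the Pearson correlation (and r^2) between qPCR and sequencing log2 fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr

from .classify import revcomp
from .diffexpr import bh_fdr
from .rnafold import _PAIR_INDEX, _STACK, encode

CORE_START, CORE_END = 2, 13  # 1-based inclusive positions doubled
PENALTY_MISMATCH = 1.0
PENALTY_GU = 0.5
PENALTY_GAP = 2.0
DEFAULT_CUTOFF = 4.0
DEFAULT_ENERGY_RATIO = 0.7


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int
    end: int
    penalty_score: float
    energy_ratio: float
    alignment: str
    scorers: frozenset


def _pair_class(q: str, t: str) -> int:
    """0 = Watson-Crick, 1 = G:U wobble, 2 = mismatch, for a miRNA base and
    the target base read 3'->5' (antiparallel)."""
    if (q, t) in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        return 0
    if (q, t) in (("G", "T"), ("T", "G")):
        return 1
    return 2


def _position_weight(i: int) -> float:
    return 2.0 if CORE_START <= i + 1 <= CORE_END else 1.0


def score_target(mirna: str, window: str) -> tuple[float, str]:
    """Optimal gapped duplex penalty of a miRNA against a target window.

    The miRNA is read 5'->3' against the window read 3'->5'; gaps are
    unpaired target bases (window may exceed the miRNA length by the number
    of gaps).  Returns (penalty, alignment string of '|' pair, 'o' wobble,
    'x' mismatch, '-' gap).
    """
    q = mirna.upper().replace("U", "T")
    t = window.upper().replace("U", "T")[::-1]  # 3'->5'
    n, m = len(q), len(t)
    if not (n <= m):
        raise ValueError("window shorter than miRNA")
    INF = 1e18
    dp = np.full((n + 1, m + 1), INF)
    dp[0, 0] = 0.0
    for j in range(1, m + 1):
        dp[0, j] = dp[0, j - 1] + PENALTY_GAP * _position_weight(0)
    for i in range(1, n + 1):
        w = _position_weight(i - 1)
        for j in range(1, m + 1):
            cls = _pair_class(q[i - 1], t[j - 1])
            sub = (0.0 if cls == 0 else
                   PENALTY_GU * w if cls == 1 else PENALTY_MISMATCH * w)
            dp[i, j] = dp[i - 1, j - 1] + sub
            gap = dp[i, j - 1] + PENALTY_GAP * w
            if gap < dp[i, j]:
                dp[i, j] = gap
    # traceback for the alignment string
    i, j = n, m
    ops = []
    while i > 0 or j > 0:
        w = _position_weight(max(i - 1, 0))
        if i > 0 and j > 0:
            cls = _pair_class(q[i - 1], t[j - 1])
            sub = (0.0 if cls == 0 else
                   PENALTY_GU * w if cls == 1 else PENALTY_MISMATCH * w)
            if abs(dp[i, j] - (dp[i - 1, j - 1] + sub)) < 1e-9:
                ops.append("|ox"[cls])
                i, j = i - 1, j - 1
                continue
        ops.append("-")
        j -= 1
    return float(dp[n, m]), "".join(reversed(ops))


def duplex_energy(mirna: str, window: str) -> float:
    """Summed stacking energy of the ungapped duplex alignment (miRNA 5'->3'
    against the window 3'->5'), used for the energy-ratio criterion of
    scorer B.  Unpaired positions break the stack."""
    q = encode(mirna)
    t = encode(window)[::-1]
    n = min(len(q), len(t))
    energy = 0.0
    prev_pt = -1
    for i in range(n):
        pt = int(_PAIR_INDEX[q[i], t[i]])
        if pt >= 0 and prev_pt >= 0:
            energy += _STACK[prev_pt, pt]
        prev_pt = pt
    return energy


def energy_ratio(mirna: str, window: str) -> float:
    """Duplex stacking energy relative to the perfect-complement duplex."""
    perfect = duplex_energy(mirna, revcomp(mirna))
    if perfect >= 0:
        return 0.0
    e = duplex_energy(mirna, window)
    return max(0.0, min(1.0, e / perfect))


def scan_targets(
    mirna_id: str,
    mirna: str,
    transcriptome: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    energy_cutoff: float = DEFAULT_ENERGY_RATIO,
    max_gaps: int = 1,
) -> tuple[list[TargetHit], list[TargetHit]]:
    """All windows within the penalty cutoff, per scorer.

    Scorer A: penalty <= cutoff.  Scorer B: penalty <= cutoff and energy
    ratio >= energy_cutoff.  Ungapped windows are pre-screened with a
    vectorized scan; gapped alignment is run on windows near the cutoff.
    Returns (hits_A, hits_B).
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    q = mirna.upper().replace("U", "T")
    n = len(q)
    # position weights and penalty lookup for the vectorized ungapped scan
    weights = np.array([_position_weight(i) for i in range(n)])
    qc = encode(q)
    pen_table = np.full((4, 4), PENALTY_MISMATCH)
    for a in range(4):
        for b in range(4):
            if _PAIR_INDEX[a, b] >= 0:
                pen_table[a, b] = 0.0 if (a, b) not in ((2, 3), (3, 2)) else PENALTY_GU
    hits_a: list[TargetHit] = []
    hits_b: list[TargetHit] = []
    for tx_id, seq in transcriptome.items():
        s = seq.upper().replace("U", "T")
        if len(s) < n:
            continue
        tc = encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(tc, n)[:, ::-1]
        ungapped = (pen_table[qc[None, :], windows] * weights[None, :]).sum(axis=1)
        # gapped alignment can only lower the penalty by replacing scored
        # positions; rescue margin = one gap's doubled cost
        candidates = np.nonzero(ungapped <= cutoff + 2 * PENALTY_GAP * 2)[0]
        seen: set[tuple[int, int]] = set()
        for start in candidates:
            for extra in range(0, max_gaps + 1):
                end = start + n + extra
                if end > len(s):
                    continue
                penalty, aln = score_target(q, s[start:end])
                if penalty <= cutoff and (start, end) not in seen:
                    er = energy_ratio(q, s[start:end])
                    hit = TargetHit(mirna_id, tx_id, int(start), int(end),
                                    penalty, er, aln, frozenset("A"))
                    hits_a.append(hit)
                    if er >= energy_cutoff:
                        hits_b.append(TargetHit(
                            mirna_id, tx_id, int(start), int(end), penalty,
                            er, aln, frozenset("B")))
                    seen.add((start, end))
    return hits_a, hits_b


def consensus_targets(hits_a: list[TargetHit],
                      hits_b: list[TargetHit],
                      min_overlap: float = 0.5) -> list[TargetHit]:
    """Sites called by both scorers: same miRNA and transcript with >= 50%
    reciprocal-minimum overlap, merged keeping scorer provenance."""
    out = []
    by_key: dict[tuple[str, str], list[TargetHit]] = {}
    for h in hits_b:
        by_key.setdefault((h.mirna_id, h.transcript_id), []).append(h)
    for ha in hits_a:
        for hb in by_key.get((ha.mirna_id, ha.transcript_id), []):
            inter = min(ha.end, hb.end) - max(ha.start, hb.start)
            shortest = min(ha.end - ha.start, hb.end - hb.start)
            if inter > 0 and inter / shortest >= min_overlap:
                out.append(TargetHit(
                    ha.mirna_id, ha.transcript_id,
                    min(ha.start, hb.start), max(ha.end, hb.end),
                    min(ha.penalty_score, hb.penalty_score),
                    max(ha.energy_ratio, hb.energy_ratio),
                    ha.alignment, frozenset("AB")))
                break
    return out


def hypergeom_enrich(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), log-space.

    ``k`` study genes annotated with the term, study size ``n``, ``K``
    universe genes with the term, universe size ``N``.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    log_terms = []
    log_denom = _log_comb(N, n)
    for i in range(k, hi + 1):
        log_terms.append(_log_comb(K, i) + _log_comb(N - K, n - i) - log_denom)
    m = max(log_terms)
    return float(min(1.0, np.exp(m) * np.exp(np.array(log_terms) - m).sum()))


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adj: float = np.nan
    significant: bool = False


def enrich_terms(
    study_genes: set[str] | list[str],
    term_map: pd.DataFrame,
    universe_genes: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One upper-tail test per term with >= 1 study gene, BH-corrected.

    ``term_map`` columns: gene, term_id and optionally term_name, namespace.
    The universe defaults to every gene in the term map; study genes must be
    a subset of it.
    """
    study = set(study_genes)
    universe = set(universe_genes) if universe_genes is not None \
        else set(term_map["gene"])
    missing = study - universe
    if missing:
        raise ValueError(f"study gene(s) absent from universe: {sorted(missing)}")
    N, n = len(universe), len(study)
    rows = []
    for term_id, grp in term_map.groupby("term_id"):
        genes = set(grp["gene"]) & universe
        k = len(genes & study)
        if k == 0:
            continue
        p = hypergeom_enrich(k, n, len(genes), N)
        rows.append(dict(
            term_id=term_id,
            term_name=grp["term_name"].iloc[0] if "term_name" in grp else "",
            namespace=grp["namespace"].iloc[0] if "namespace" in grp else "",
            k=k, n=n, K=len(genes), N=N, p=p))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace",
                                     "k", "n", "K", "N", "p"])
    if len(df):
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["p_adj"] <= alpha
        df = df.sort_values("p_adj", kind="stable").reset_index(drop=True)
    return df


def ddct(ct_target_treat: float, ct_ref_treat: float,
         ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression 2^-ddCt with assumed amplification efficiency 2."""
    ddct_value = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_value))


def qpcr_table(ct: pd.DataFrame, reference: str = "U6") -> pd.DataFrame:
    """Per-miRNA relative expression from a long Ct table.

    ``ct`` columns: sample, group (control/treatment), gene, ct and a
    ``mirna`` column tying each reference measurement to its target assay.
    """
    rows = []
    for mirna, grp in ct.groupby("mirna"):
        def one(group: str, gene: str) -> float:
            sel = grp[(grp["group"] == group) & (grp["gene"] == gene)]
            if sel.empty:
                raise ValueError(
                    f"missing Ct for gene {gene!r} in group {group!r}")
            return float(sel["ct"].iloc[0])

        rel = ddct(one("treatment", mirna), one("treatment", reference),
                   one("control", mirna), one("control", reference))
        rows.append(dict(mirna=mirna, relative_expression=rel,
                         qpcr_log2fc=float(np.log2(rel))))
    return pd.DataFrame(rows, columns=["mirna", "relative_expression",
                                       "qpcr_log2fc"])


def corr_validation(qpcr_log2fc, seq_log2fc) -> tuple[float, float]:
    """Pearson r and r^2 between qPCR and sequencing log2 fold changes."""
    x = np.asarray(qpcr_log2fc, dtype=float)
    y = np.asarray(seq_log2fc, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite fold changes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in fold changes")
    r = float(pearsonr(x, y).statistic)
    return r, r * r
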