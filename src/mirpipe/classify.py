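"""Genome mapping and annotation-based classification of unique tags.

Tags are aligned ungapped to both strands of the reference with up to
``max_mismatches`` (default 3) Hamming mismatches, using pigeonhole seeding
over an exact k-mer index: a tag split into ``m+1`` segments must match one
segment exactly in any hit with <= m mismatches, so candidate positions from
segment lookups followed by full verification find every hit.

Reads are then partitioned into the mapping categories used for library
accounting (Mature, Precursor, rRNA, tRNA, snRNA, snoRNA, other structural
sncRNA, Exon, Intron, Intergenic, Unmapped).  A tag overlapping several
features takes the highest-priority category, with priority favouring the
most specific annotation.  Tags within 3 mismatches of a same-length
known-miRNA catalog entry are conserved-miRNA candidates; catalog-absent
genome-mapped tags feed the novel-miRNA discovery stage.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# highest priority first; most specific annotation wins
DEFAULT_PRIORITY = (
    "Mature", "Precursor", "rRNA", "tRNA", "snRNA", "snoRNA",
    "Rfam_other", "Exon", "Intron", "Intergenic",
)
CATEGORY_ORDER = ("Total", "Intergenic", "Intron", "Exon", "Precursor",
                  "Mature", "Rfam_other", "rRNA", "snRNA", "snoRNA", "tRNA",
                  "Unmapped")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    tag_sequence: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    mismatches: int


class GenomeIndex:
    """Exact k-mer index over the forward strand of each chromosome."""

    def __init__(self, genome: dict[str, str], k: int = 5):
        self.genome = {c: s.upper().replace("U", "T") for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _hamming_leq(a: str, b: str, limit: int) -> int:
    """Mismatch count, or limit+1 as soon as it is exceeded."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return mism
    return mism


def _strand_hits(tag: str, index: GenomeIndex, max_mismatches: int):
    n = len(tag)
    k = index.k
    n_seg = max_mismatches + 1
    seg_len = n // n_seg
    if seg_len < k:
        raise ValueError(
            f"tag of length {n} too short for pigeonhole seeding with k={k} "
            f"at {max_mismatches} mismatches (need length >= "
            f"{n_seg * k})")
    positions: set[tuple[str, int]] = set()
    # pigeonhole: some segment must match exactly in any qualifying hit, and
    # that segment contains its own first k-mer exactly
    for s in range(n_seg):
        off = s * seg_len
        for chrom, pos in index.lookup(tag[off:off + k]):
            start = pos - off
            if start >= 0 and start + n <= len(index.genome[chrom]):
                positions.add((chrom, start))
    out = []
    for chrom, start in positions:
        mism = _hamming_leq(tag, index.genome[chrom][start:start + n],
                            max_mismatches)
        if mism <= max_mismatches:
            out.append((chrom, start, mism))
    return out


def align_tag(tag: str, index: GenomeIndex,
              max_mismatches: int = 0) -> list[AlignmentHit]:
    """All ungapped hits of ``tag`` on both strands with <= max_mismatches.

    Exact up to the seeding guarantee: with segment length >= k the
    pigeonhole argument covers every qualifying position (verified against a
    brute-force scan in the tests).  Reverse-strand hits report the genome
    interval of the match with strand '-'.
    """
    tag = tag.upper().replace("U", "T")
    n = len(tag)
    hits = [
        AlignmentHit(tag, chrom, start, start + n, "+", mism)
        for chrom, start, mism in _strand_hits(tag, index, max_mismatches)
    ]
    hits += [
        AlignmentHit(tag, chrom, start, start + n, "-", mism)
        for chrom, start, mism in _strand_hits(revcomp(tag), index,
                                               max_mismatches)
    ]
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits


class Annotation:
    """Feature intervals (0-based half-open) with vectorized overlap lookup."""

    def __init__(self, features: pd.DataFrame):
        required = {"chrom", "start", "end", "feature", "name"}
        if not required <= set(features.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if (features["end"] <= features["start"]).any():
            bad = features[features["end"] <= features["start"]].iloc[0]
            raise ValueError(f"malformed annotation interval: {bad.to_dict()}")
        self.features = features.reset_index(drop=True)
        self._by_chrom = {
            chrom: (grp["start"].to_numpy(), grp["end"].to_numpy(),
                    grp["feature"].to_numpy(), grp["name"].to_numpy())
            for chrom, grp in self.features.groupby("chrom")
        }

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, str]]:
        if chrom not in self._by_chrom:
            return []
        s, e, feat, name = self._by_chrom[chrom]
        mask = (s < end) & (e > start)
        return list(zip(feat[mask], name[mask]))


def assign_category(hits: list[AlignmentHit], annotation: Annotation,
                    priority: tuple[str, ...] = DEFAULT_PRIORITY) -> str:
    """Category of a tag given its genome hits: Unmapped without hits, the
    highest-priority feature overlapped by any hit, else Intergenic."""
    if not hits:
        return "Unmapped"
    rank = {cat: i for i, cat in enumerate(priority)}
    best = "Intergenic"
    for hit in hits:
        for feat, _name in annotation.overlapping(hit.chrom, hit.start, hit.end):
            if feat in rank and rank[feat] < rank.get(best, len(priority)):
                best = feat
    return best


def format_percent(count: int, total: int) -> str:
    """Percentage rounded to 2 decimals, trailing zeros stripped ('0.39',
    '3.4', '100') — the display convention of the classification table."""
    pct = round(count / total * 100, 2)
    text = f"{pct:.2f}".rstrip("0").rstrip(".")
    return text


def build_category_table(
    category_counts: dict[str, Counter],
) -> pd.DataFrame:
    """Read-weighted classification table.

    ``category_counts`` maps library id -> Counter(category -> reads).
    Output has one row per category (fixed order), and per library a count
    column and a percentage-of-total column; full precision is retained in
    the numeric columns and the display string uses 2 decimals.
    """
    rows = []
    for cat in CATEGORY_ORDER:
        row: dict = {"category": cat}
        for lib, counts in category_counts.items():
            total = sum(counts.values())
            value = total if cat == "Total" else counts.get(cat, 0)
            row[f"{lib}_count"] = value
            row[f"{lib}_pct"] = value / total * 100 if total else 0.0
            row[f"{lib}_cell"] = (
                f"{value:,}({format_percent(value, total)}%)" if total else "0"
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    for lib, counts in category_counts.items():
        total = sum(counts.values())
        body = table.loc[table["category"] != "Total", f"{lib}_count"].sum()
        if body != total:
            raise AssertionError(f"category counts do not sum to Total in {lib}")
    return table


@dataclass(frozen=True)
class KnownMatch:
    tag_sequence: str
    catalog_id: str
    mismatches: int


def match_known(tag: str, catalog: dict[str, str],
                max_mismatches: int = 3) -> KnownMatch | None:
    """Best same-length catalog entry within Hamming distance 3.

    Ties on mismatch count break lexicographically by catalog id; ``None``
    routes the tag to the novel-candidate pool.
    """
    if not catalog:
        raise ValueError("empty known-miRNA catalog")
    tag = tag.upper().replace("U", "T")
    best: KnownMatch | None = None
    for cid in sorted(catalog):
        ref = catalog[cid].upper().replace("U", "T")
        if len(ref) != len(tag):
            continue
        mism = _hamming_leq(tag, ref, max_mismatches)
        if mism <= max_mismatches and (best is None or mism < best.mismatches):
            best = KnownMatch(tag, cid, mism)
            if mism == 0:
                break
    return best


def brute_force_align(tag: str, genome: dict[str, str],
                      max_mismatches: int = 0) -> list[AlignmentHit]:
    """Sliding-window scan over every position and both strands — the oracle
    the seeded aligner is verified against on small genomes."""
    tag = tag.upper().replace("U", "T")
    n = len(tag)
    t_arr = np.frombuffer(tag.encode(), dtype=np.uint8)
    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper().replace("U", "T")
        g = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(g) < n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, n)
        for strand, pattern in (("+", t_arr),
                                ("-", np.frombuffer(revcomp(tag).encode(),
                                                    dtype=np.uint8))):
            mism = (windows != pattern).sum(axis=1)
            for start in np.nonzero(mism <= max_mismatches)[0]:
                hits.append(AlignmentHit(tag, chrom, int(start),
                                         int(start) + n, strand,
                                         int(mism[start])))
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits
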