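"""Novel miRNA calling from genome-mapped, catalog-absent tags.

For each candidate tag the stage excises two precursor windows (tag as the
5' arm extending downstream, and as the 3' arm extending upstream), folds
them, trims each window to the stem-loop that actually contains the tag,
locates the miRNA/miRNA* duplex with the canonical 2-nt 3' overhang, and
applies the community (Meyers-style) annotation gate for plant miRNAs:

* precursor folds into a single stem-loop with negative MFE,
* MFEI at or above a threshold (default 0.85),
* at most one bulge in the duplex, no larger than 2 nt,
* fewer than three duplex mismatches.

A G:U wobble counts as paired; between two paired anchors with ``a``
unpaired bases on the mature strand and ``b`` on the star strand,
``min(a, b)`` positions count as mismatches and an asymmetric remainder as
one bulge of size ``|a - b|``.  Observation of the star sequence among the
sequenced tags is reported and only required in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import rnafold
from .classify import AlignmentHit, revcomp
from .rnafold import HairpinStructure, fold_mfe, hairpin_loops

DEFAULT_WINDOW_UP = 20
DEFAULT_WINDOW_DOWN = 180
# (upstream, downstream) window extents tried in order (most parsimonious
# precursor first); long random flanks can fold over a genuine short
# hairpin, so compact windows are evaluated before the full-length one
WINDOW_LADDER = ((0, 55), (5, 60), (DEFAULT_WINDOW_UP, 70),
                 (DEFAULT_WINDOW_UP, DEFAULT_WINDOW_DOWN))
DEFAULT_MFEI_THRESHOLD = 0.85
DEFAULT_MIN_EXPRESSION = 5


@dataclass
class DuplexReport:
    mature_interval: tuple[int, int]  # on the (trimmed) precursor
    star_interval: tuple[int, int]
    n_mismatches: int
    n_bulges: int
    max_bulge_size: int
    mature_arm: str  # 5p / 3p


@dataclass
class NovelMirnaCall:
    tag_sequence: str
    chrom: str
    precursor_start: int
    precursor_end: int
    strand: str
    precursor_seq: str
    structure: HairpinStructure | None
    duplex: DuplexReport | None
    star_observed: bool
    verdict: bool
    reasons: list[str] = field(default_factory=list)


def excise_candidates(
    hit: AlignmentHit,
    genome: dict[str, str],
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> list[tuple[str, int, int, int]]:
    """Candidate precursor windows around a genome hit.

    Returns ``(sequence, genome_start, genome_end, tag_offset)`` tuples, one
    with the tag as the 5' arm and one as the 3' arm, clipped at chromosome
    ends; minus-strand candidates are reverse-complemented so the tag reads
    5'->3' within the returned sequence and ``tag_offset`` locates it there.
    """
    chrom_seq = genome[hit.chrom]
    n = len(chrom_seq)
    out = []
    if hit.strand == "+":
        specs = [
            (max(0, hit.start - window_up), min(n, hit.end + window_down)),
            (max(0, hit.start - window_down), min(n, hit.end + window_up)),
        ]
        for gstart, gend in specs:
            seq = chrom_seq[gstart:gend].upper().replace("U", "T")
            out.append((seq, gstart, gend, hit.start - gstart))
    else:
        # tag's 5' end maps to the genomic end coordinate
        specs = [
            (max(0, hit.start - window_down), min(n, hit.end + window_up)),
            (max(0, hit.start - window_up), min(n, hit.end + window_down)),
        ]
        for gstart, gend in specs:
            seq = revcomp(chrom_seq[gstart:gend].upper().replace("U", "T"))
            out.append((seq, gstart, gend, gend - hit.end))
    return out


def _pair_tree(pairs: list[tuple[int, int]]) -> dict[tuple[int, int], tuple[int, int] | None]:
    """Parent (directly enclosing pair) of every pair."""
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    for p in sorted(pairs):
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent[p] = stack[-1] if stack else None
        stack.append(p)
    return parent


def _n_hairpins_within(pairs: list[tuple[int, int]], span: tuple[int, int]) -> int:
    return sum(1 for i, j in hairpin_loops(pairs)
               if span[0] <= i and j <= span[1])


def trim_to_hairpin(
    structure: HairpinStructure, mature: tuple[int, int], slack: int = 4,
    max_walk_loop: int = 8,
) -> tuple[int, int] | None:
    """Outermost pair span of the stem-loop containing the mature interval.

    Starting from each hairpin loop the stem is walked outward through its
    parent chain while the enclosing region still holds exactly one hairpin
    and the connecting interior loop stays small (``max_walk_loop`` unpaired
    bases) — flanking genomic sequence often forms spurious enclosing stems
    joined to a genuine hairpin by large loops, which must not be absorbed
    into the precursor.  The widest such span covering ``mature`` wins.  A
    mature whose terminal bases are unpaired may stick out of the stem by
    up to ``slack`` nt, in which case the returned interval is widened to
    include it.  ``None`` when the mature tag is not inside any single
    stem-loop.
    """
    pairs = structure.pairs
    parent = _pair_tree(pairs)
    best: tuple[int, int] | None = None
    for loop in hairpin_loops(pairs):
        span = loop
        while True:
            par = parent.get(span)
            if par is None or _n_hairpins_within(pairs, par) != 1:
                break
            gap = (span[0] - par[0] - 1) + (par[1] - span[1] - 1)
            if gap > max_walk_loop:
                break
            span = par
        if span[0] - slack <= mature[0] and mature[1] - 1 <= span[1] + slack:
            cand = (min(span[0], mature[0]), max(span[1], mature[1] - 1))
            if best is None or cand[1] - cand[0] > best[1] - best[0]:
                best = cand
    return best


def duplex_stats(structure: HairpinStructure,
                 mature: tuple[int, int]) -> DuplexReport:
    """miRNA/miRNA* duplex statistics on a single-hairpin structure.

    The star interval comes from the pairing partners of the mature arm with
    the canonical 2-nt 3' overhang; recomputing the mature from the reported
    star inverts the construction on a clean duplex.
    """
    loops = hairpin_loops(structure.pairs)
    if len(loops) != 1:
        raise ValueError("duplex statistics need exactly one hairpin loop")
    hi, hj = loops[0]
    m1, m2 = mature
    if m1 <= hi and m2 - 1 >= hj:
        raise LoopSpanningError("mature interval straddles the hairpin loop")
    partner = structure.partner()
    arm = "5p" if m2 - 1 <= hi else "3p"
    if not (m2 - 1 <= hi or m1 >= hj):
        raise LoopSpanningError("mature interval straddles the hairpin loop")

    def nearest_partner(pos: int, lo: int, hi_: int, step: int) -> int | None:
        q = pos
        while lo <= q <= hi_:
            if q in partner:
                return partner[q]
            q += step
        return None

    # anchor partners: the star spans the partners of the mature 5' end and
    # of position m2-3 (the mature 3' duplex end, excluding its own 2-nt
    # overhang), plus the star's 2-nt 3' overhang opposite the mature 5'
    # end; written in coordinates this is [partner(m2-3), partner(m1)+3)
    # regardless of which arm carries the mature, and the construction
    # inverts exactly on a clean duplex.
    p5 = nearest_partner(m1, m1, m2 - 1, +1)
    p3 = nearest_partner(m2 - 3, m1, m2 - 1, -1)
    if p5 is None or p3 is None:
        raise ValueError("mature arm entirely unpaired; no duplex")
    lo, hi_p = sorted((p3, p5))
    n = len(structure.sequence)
    star = (max(0, lo), min(n, hi_p + 3))
    # walk the duplex between anchors counting symmetric/asymmetric loops
    mism = 0
    bulges: list[int] = []
    paired_m = [q for q in range(m1, m2) if q in partner]
    for a, b in zip(paired_m, paired_m[1:]):
        gap_m = b - a - 1
        gap_s = abs(partner[a] - partner[b]) - 1
        mism += min(gap_m, gap_s)
        if gap_m != gap_s:
            bulges.append(abs(gap_m - gap_s))
    # unpaired overhang inside the mature interval counts as mismatches
    mism += (paired_m[0] - m1) + (m2 - 1 - paired_m[-1])
    return DuplexReport(
        mature_interval=(m1, m2),
        star_interval=star,
        n_mismatches=mism,
        n_bulges=len(bulges),
        max_bulge_size=max(bulges, default=0),
        mature_arm=arm,
    )


class LoopSpanningError(ValueError):
    """Mature interval overlaps the hairpin loop."""


def meyers_check(
    structure: HairpinStructure,
    duplex: DuplexReport | None,
    mfei_threshold: float = DEFAULT_MFEI_THRESHOLD,
    star_observed: bool = False,
    strict_star: bool = False,
) -> tuple[bool, list[str]]:
    """Apply the plant-miRNA annotation gate; returns (pass, failure codes)."""
    reasons = []
    if len(hairpin_loops(structure.pairs)) != 1:
        reasons.append("multi-loop")
    if structure.mfe >= 0:
        reasons.append("mfe")
    if structure.mfei < mfei_threshold:
        reasons.append("mfei")
    if duplex is None:
        reasons.append("no-duplex")
    else:
        if duplex.n_bulges > 1:
            reasons.append("bulge-count")
        if duplex.max_bulge_size > 2:
            reasons.append("bulge-size")
        if duplex.n_mismatches >= 3:
            reasons.append("mismatch-count")
    if strict_star and not star_observed:
        reasons.append("star-not-observed")
    return (not reasons, reasons)


def evaluate_candidate(
    tag: str,
    hit: AlignmentHit,
    genome: dict[str, str],
    observed_tags: set[str] | None = None,
    mfei_threshold: float = DEFAULT_MFEI_THRESHOLD,
    strict_star: bool = False,
    window_ladder: tuple[tuple[int, int], ...] = WINDOW_LADDER,
) -> NovelMirnaCall:
    """Fold candidate excision windows, keep the best-passing candidate.

    For each (up, down) extent in ``window_ladder`` both orientations (tag
    as 5' and as 3' arm) are folded, trimmed to the stem-loop containing the
    tag and refolded so that MFE/MFEI describe the precursor rather than
    arbitrary flanking sequence.  Extents are tried shortest first and the
    search stops at the first passing window (the most parsimonious
    precursor); otherwise the best-folding failure is reported.
    """
    observed_tags = observed_tags or set()
    best_call: NovelMirnaCall | None = None
    windows: list[tuple[str, int, int, int]] = []
    for up, down in window_ladder:
        windows.extend(excise_candidates(hit, genome, up, down))
    for seq, gstart, gend, off in windows:
        structure = fold_mfe(seq)
        mature = (off, off + len(tag))
        span = trim_to_hairpin(structure, mature)
        reasons: list[str]
        if span is None:
            call = NovelMirnaCall(tag, hit.chrom, gstart, gend, hit.strand,
                                  seq, structure, None, False, False,
                                  ["no-hairpin"])
        else:
            trimmed = seq[span[0]:span[1] + 1]
            sub = fold_mfe(trimmed)
            t_mature = (mature[0] - span[0], mature[1] - span[0])
            try:
                duplex = duplex_stats(sub, t_mature)
            except ValueError:
                duplex = None
            star_obs = False
            if duplex is not None:
                s1, s2 = duplex.star_interval
                star_seq = trimmed[s1:s2]
                star_obs = star_seq in observed_tags
            ok, reasons = meyers_check(sub, duplex, mfei_threshold,
                                       star_obs, strict_star)
            call = NovelMirnaCall(tag, hit.chrom, gstart, gend, hit.strand,
                                  trimmed, sub, duplex, star_obs, ok, reasons)
        if call.verdict:
            return call
        if best_call is None:
            best_call = call
        else:
            key = -(call.structure.mfe if call.structure else 0.0)
            best_key = -(best_call.structure.mfe if best_call.structure else 0.0)
            if key > best_key:
                best_call = call
    assert best_call is not None
    return best_call
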