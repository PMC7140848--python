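"""Raw small-RNA read cleaning and unique-tag collapsing.

Raw single-end reads carry the insert followed by the 3' sequencing adapter.
Cleaning applies the discard rules in a fixed order — no detectable adapter,
empty insert, poly-A artifact, then length bounds (15-30 nt inclusive by
default) — and collapses the surviving inserts into unique tags with
per-library read counts.  The discard ledger always balances:
``total_raw = total_clean + sum(discarded)``; the clean total is the
denominator of reads-per-million normalization downstream.

U residues are normalized to T on input.  No base-quality filtering is
applied by default (a configurable mean-quality floor exists but is off).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DISCARD_REASONS = ("no_adapter", "no_insert", "polya", "too_short", "too_long",
                   "low_quality")

_VALID = set("ACGTN")


@dataclass
class CleanParams:
    """Cleaning thresholds. ``adapter`` is the 3' adapter as sequenced."""

    adapter: str
    min_len: int = 15
    max_len: int = 30
    min_adapter_overlap: int = 6
    adapter_error_rate: float = 0.1
    polya_min_fraction: float = 0.9
    min_mean_quality: float | None = None  # off by default

    def __post_init__(self) -> None:
        self.adapter = normalize_seq(self.adapter)
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if not (0 <= self.adapter_error_rate < 0.5):
            raise ValueError("adapter_error_rate must be in [0, 0.5)")


@dataclass
class CleanStats:
    """Read accounting for one library."""

    total_raw: int = 0
    discarded: Counter = field(default_factory=Counter)
    total_clean: int = 0

    def check_ledger(self) -> None:
        if self.total_raw != self.total_clean + sum(self.discarded.values()):
            raise AssertionError("clean-read ledger does not balance")


def normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def trim_adapter(read: str, params: CleanParams) -> str | None:
    """Insert preceding the best 3'-adapter match, or ``None`` if no match.

    The adapter is located by semi-global suffix-prefix alignment: at every
    start position the overlapping adapter prefix may mismatch at up to
    ``adapter_error_rate`` of its length; overlaps shorter than
    ``min_adapter_overlap`` do not count.  The leftmost acceptable match wins
    (an adapter-only read yields a zero-length insert, which the caller
    classifies as ``no_insert``).
    """
    if not read:
        raise ValueError("empty read")
    read = normalize_seq(read)
    if not set(read) <= _VALID:
        bad = sorted(set(read) - _VALID)
        raise ValueError(f"non-ACGTN characters in read: {bad}")
    adapter = params.adapter
    pos = read.find(adapter)  # fast path: exact full-adapter hit
    if pos >= 0:
        return read[:pos]
    n, m = len(read), len(adapter)
    for i in range(0, n - params.min_adapter_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(params.adapter_error_rate * overlap)
        mism = 0
        seg = read[i:i + overlap]
        for a, b in zip(seg, adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return read[:i]
    return None


def is_polya(insert: str, min_fraction: float) -> bool:
    return bool(insert) and insert.count("A") / len(insert) >= min_fraction


def parse_fastq(handle: TextIO) -> Iterator[tuple[str, str, str]]:
    """(title, sequence, quality) records; raises on truncated input."""
    try:
        yield from FastqGeneralIterator(handle)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ: {exc}") from exc


def clean_reads(
    fastq: TextIO | Iterable[tuple[str, str, str]],
    params: CleanParams,
    library_id: str,
) -> tuple[dict[str, Counter], CleanStats]:
    """Clean one library and collapse survivors to unique tags.

    Returns ``(tags, stats)`` where ``tags`` maps insert sequence to a
    per-library ``Counter`` (so tag dicts from several libraries merge by
    simple update).
    """
    if hasattr(fastq, "read"):
        records = parse_fastq(fastq)  # type: ignore[arg-type]
    else:
        records = iter(fastq)  # type: ignore[assignment]
    stats = CleanStats()
    tags: dict[str, Counter] = {}
    qual_floor = params.min_mean_quality
    for _title, seq, qual in records:
        stats.total_raw += 1
        if qual_floor is not None and qual:
            mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
            if mean_q < qual_floor:
                stats.discarded["low_quality"] += 1
                continue
        insert = trim_adapter(seq, params)
        if insert is None:
            stats.discarded["no_adapter"] += 1
            continue
        if not insert:
            stats.discarded["no_insert"] += 1
            continue
        if is_polya(insert, params.polya_min_fraction):
            stats.discarded["polya"] += 1
            continue
        if len(insert) < params.min_len:
            stats.discarded["too_short"] += 1
            continue
        if len(insert) > params.max_len:
            stats.discarded["too_long"] += 1
            continue
        stats.total_clean += 1
        if insert not in tags:
            tags[insert] = Counter()
        tags[insert][library_id] += 1
    stats.check_ledger()
    return tags, stats


def merge_tags(tagsets: Iterable[dict[str, Counter]]) -> dict[str, Counter]:
    """Union per-library tag count dicts into one tag -> counts map."""
    merged: dict[str, Counter] = {}
    for tags in tagsets:
        for seq, counts in tags.items():
            if seq not in merged:
                merged[seq] = Counter()
            merged[seq].update(counts)
    return merged


def length_distribution(
    tags: dict[str, Counter], library_id: str
) -> dict[int, tuple[float, float]]:
    """Per-length (read fraction, unique-tag fraction) for one library."""
    read_counts: Counter = Counter()
    tag_counts: Counter = Counter()
    for seq, counts in tags.items():
        c = counts.get(library_id, 0)
        if c > 0:
            read_counts[len(seq)] += c
            tag_counts[len(seq)] += 1
    total_reads = sum(read_counts.values())
    total_tags = sum(tag_counts.values())
    if total_reads == 0:
        return {}
    return {
        length: (read_counts[length] / total_reads,
                 tag_counts[length] / total_tags)
        for length in sorted(read_counts)
    }
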