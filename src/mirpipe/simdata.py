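"""Self-contained synthetic small-RNA study with a machine-readable answer key.

The generator emulates the design of a two-genotype heat-stress experiment:
heat-tolerant (HT) and heat-sensitive (HS) genotypes sampled at 0, 6 and
12 h of heat treatment, one pooled sequencing library per condition.  It
produces a random reference genome with planted loci (known miRNA hairpins,
novel hairpins absent from the catalog, rRNA/tRNA/snRNA/snoRNA/other
structural RNA, exons and introns), a known-miRNA catalog, six FASTQ
libraries, a qPCR Ct table, a transcriptome with planted target sites and a
term-to-gene map with one planted enriched term — together with truth
tables recording every locus, expected count and planted effect.

Counts are negative-binomial around the planted per-library means
(``var = m + dispersion * m^2``); the default dispersion 0.01 reflects the
mildly overdispersed technical sampling of a single pooled library per
condition (the design pools biological replicates before sequencing, so no
replicate variance component exists).  Planted fold changes are +/-2 on the
log2 scale at both heat timepoints; two catalog miRNAs are switched off
entirely (zero counts) under treatment to exercise the 0 -> 0.01 TPM floor.
Hairpins are constructed by explicit reverse-complement arm design with
injected mismatches/bulges, so the discovery stage has an exact answer key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import revcomp
from . import io as mio

GENOTYPES = ("HT", "HS")
TIMEPOINTS = (0, 6, 12)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "Rfam_other")
_NCRNA_LEN = {"rRNA": 120, "tRNA": 75, "snRNA": 100, "snoRNA": 80,
              "Rfam_other": 90}


@dataclass
class LibrarySpec:
    genotype: str
    timepoint_h: int
    depth: int

    @property
    def library_id(self) -> str:
        return f"{self.genotype}_{self.timepoint_h}h"


def default_libraries(depth: int = 100_000) -> list[LibrarySpec]:
    return [LibrarySpec(g, t, depth) for g in GENOTYPES for t in TIMEPOINTS]


@dataclass
class SimConfig:
    """The stated world of the synthetic study; see the module docstring."""

    seed: int
    genome_length: int = 100_000
    n_known_mirnas: int = 30
    n_novel_precursors: int = 12
    ncrna_fractions: dict = field(default_factory=lambda: {
        "rRNA": 0.02, "tRNA": 0.02, "snRNA": 0.005, "snoRNA": 0.005,
        "Rfam_other": 0.01})
    libraries: list[LibrarySpec] = field(default_factory=default_libraries)
    adapter: str = DEFAULT_ADAPTER
    dispersion: float = 0.01
    artifact_rates: dict = field(default_factory=lambda: {
        "polya": 0.02, "no_insert": 0.02, "too_long": 0.02,
        "too_short": 0.02, "no_adapter": 0.02})
    # minor genomic read classes populating the classification table
    exon_fraction: float = 0.02
    intron_fraction: float = 0.01
    precursor_fraction: float = 0.005
    unmapped_fraction: float = 0.05
    background_pool_size: int = 1500
    n_ncrna_loci: int = 4  # loci per structural-RNA class
    n_gene_loci: int = 3  # exon-intron-exon gene models
    de_plan: dict | None = None  # filled by default_de_plan if None
    n_transcripts: int = 60
    transcript_length: int = 300
    n_terms: int = 12

    def __post_init__(self) -> None:
        fr = self.ncrna_fractions
        if any(v < 0 for v in fr.values()) or sum(fr.values()) >= 1:
            raise ValueError("ncRNA fractions must be >= 0 and sum < 1")
        if any(lib.depth < 0 for lib in self.libraries):
            raise ValueError("library depth must be non-negative")

    def library(self, library_id: str) -> LibrarySpec:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(f"unknown library descriptor {library_id!r}")


@dataclass
class TruthTable:
    """Answer key: planted loci, expected counts and planted effects."""

    planted_loci: pd.DataFrame  # name, class, chrom, start, end, strand
    planted_counts: pd.DataFrame  # miRNA x library expected mean counts
    planted_de: pd.DataFrame  # mirna, direction, membership, lfc
    mature_seqs: dict[str, str]
    precursors: dict[str, dict]  # name -> {seq, designed_pairs, mature span}
    pools: dict  # class -> (fragments, weights) used by simulate_library
    base_tpm: pd.Series


class PlacementError(ValueError):
    pass


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _design_hairpin(rng: np.random.Generator, mature_len: int = 21,
                    loop_len: int = 8, n_mismatches: int = 1,
                    n_bulges: int = 0, bulge_size: int = 1):
    """Explicit stem-loop: mature 5' arm, loop, reverse-complement star arm
    with injected mismatches/bulges.  Returns (sequence, designed pairs,
    mature interval, star sequence)."""
    while True:
        # G/C-only bases adjacent to the loop keep the all-A loop inert:
        # the loop cannot pair into either stem end, so the designed
        # pairing is also the thermodynamically preferred one
        mature = _rand_seq(rng, mature_len - 3) + \
            "".join(rng.choice(list("GC"), size=3))
        gc = (mature.count("G") + mature.count("C")) / mature_len
        if 0.4 <= gc <= 0.65:
            break
    loop = "A" * loop_len
    star = [_COMP[c] for c in reversed(mature)]
    # star position k pairs with mature position mature_len-1-k
    mism_pos = rng.choice(mature_len - 6, size=n_mismatches, replace=False) + 3 \
        if n_mismatches else np.array([], dtype=int)
    broken = set()
    for k in mism_pos:
        orig = star[k]
        choices = [b for b in "ACGT"
                   if b != orig and _COMP[b] != mature[mature_len - 1 - k]
                   and not (b == "G" and mature[mature_len - 1 - k] == "T")
                   and not (b == "T" and mature[mature_len - 1 - k] == "G")]
        star[k] = choices[rng.integers(len(choices))]
        broken.add(mature_len - 1 - int(k))
    insertions: dict[int, str] = {}
    if n_bulges:
        pos = int(rng.integers(5, mature_len - 5))
        insertions[pos] = _rand_seq(rng, bulge_size)
    star_seq = ""
    for k, base in enumerate(star):
        if k in insertions:
            star_seq += insertions[k]
        star_seq += base
    seq = mature + loop + star_seq
    pairs = []
    for m_pos in range(mature_len):
        if m_pos in broken:
            continue
        k = mature_len - 1 - m_pos  # star index pairing with m_pos
        offset = sum(len(v) for p, v in insertions.items() if p <= k)
        pairs.append((m_pos, mature_len + loop_len + k + offset))
    return seq, sorted(pairs), (0, mature_len), star_seq


def default_de_plan(known: list[str], novel: list[str],
                    lfc: float = 2.0) -> dict:
    """Planted effects: per miRNA a (membership, direction, lfc) assignment.

    Effects apply at both heat timepoints of the member genotype(s).  Two
    catalog miRNAs are silenced outright (lfc -inf, zero counts) to exercise
    the TPM zero floor.
    """
    plan: dict[str, dict] = {}

    def assign(names, n_ht, n_hs, n_both):
        blocks = (["HT-only"] * n_ht + ["HS-only"] * n_hs + ["both"] * n_both)
        blocks += ["none"] * (len(names) - len(blocks))
        for i, (name, member) in enumerate(zip(names, blocks)):
            direction = "up" if i % 2 == 0 else "down"
            plan[name] = {"membership": member, "direction": direction,
                          "lfc": lfc if direction == "up" else -lfc}
            if member == "none":
                plan[name] = {"membership": "none", "direction": "ns",
                              "lfc": 0.0}
        return plan

    assign(known, 6, 6, 6)
    assign(novel, 3, 3, 3)
    # zero-count plants: one HT-only and one HS-only catalog miRNA switched off
    downs = [n for n in known if plan[n]["membership"] == "HT-only"
             and plan[n]["direction"] == "down"]
    if downs:
        plan[downs[0]]["lfc"] = -np.inf
    downs = [n for n in known if plan[n]["membership"] == "HS-only"
             and plan[n]["direction"] == "down"]
    if downs:
        plan[downs[0]]["lfc"] = -np.inf
    return plan


def _planted_mean_counts(config: SimConfig, plan: dict,
                         base_tpm: pd.Series) -> pd.DataFrame:
    rows = {}
    for mirna, entry in plan.items():
        row = {}
        for lib in config.libraries:
            tpm = base_tpm[mirna]
            member = entry["membership"]
            affected = (member == "both"
                        or (member == "HT-only" and lib.genotype == "HT")
                        or (member == "HS-only" and lib.genotype == "HS"))
            if affected and lib.timepoint_h > 0:
                lfc = entry["lfc"]
                tpm = 0.0 if np.isinf(lfc) else tpm * 2.0 ** lfc
            row[lib.library_id] = tpm * lib.depth / 1e6
        rows[mirna] = row
    return pd.DataFrame(rows).T


def make_reference(config: SimConfig):
    """Build genome, annotation, known catalog and the truth table.

    Loci are placed left to right with random intergenic gaps; if the
    requested loci cannot fit the configured genome length a
    :class:`PlacementError` names the offending values.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    segments: list[str] = []
    features: list[dict] = []
    loci: list[dict] = []
    precursors: dict[str, dict] = {}
    mature_seqs: dict[str, str] = {}
    catalog: dict[str, str] = {}
    pos = 0

    def place(seq: str) -> int:
        nonlocal pos
        gap = int(rng.integers(40, 120))
        segments.append(_rand_seq(rng, gap))
        start = pos + gap
        segments.append(seq)
        pos = start + len(seq)
        return start

    known_names = [f"kno-miR{i + 1:03d}" for i in range(config.n_known_mirnas)]
    novel_names = [f"nov-pre{i + 1:03d}" for i in range(config.n_novel_precursors)]

    for name in known_names:
        n_mm = int(rng.integers(0, 3))  # <= 2 designed mismatches
        n_bulge = int(rng.integers(0, 2))
        seq, pairs, mspan, star = _design_hairpin(
            rng, n_mismatches=n_mm, n_bulges=n_bulge,
            bulge_size=int(rng.integers(1, 3)))
        start = place(seq)
        precursors[name] = {"seq": seq, "designed_pairs": pairs,
                            "mature_span": mspan, "start": start,
                            "strand": "+", "star": star}
        mature_seqs[name] = seq[mspan[0]:mspan[1]]
        catalog[name] = mature_seqs[name]
        features.append(dict(chrom=chrom, start=start, end=start + len(seq),
                             strand="+", feature="Precursor", name=name))
        features.append(dict(chrom=chrom, start=start + mspan[0],
                             end=start + mspan[1], strand="+",
                             feature="Mature", name=name + "_mature"))
        loci.append(dict(name=name, locus_class="known_precursor",
                         chrom=chrom, start=start, end=start + len(seq),
                         strand="+"))

    for i, name in enumerate(novel_names):
        seq, pairs, mspan, star = _design_hairpin(rng, n_mismatches=1,
                                                  n_bulges=0)
        strand = "-" if i % 4 == 3 else "+"
        genomic = seq if strand == "+" else revcomp(seq)
        start = place(genomic)
        precursors[name] = {"seq": seq, "designed_pairs": pairs,
                            "mature_span": mspan, "start": start,
                            "strand": strand, "star": star}
        mature_seqs[name] = seq[mspan[0]:mspan[1]]
        loci.append(dict(name=name, locus_class="novel_precursor",
                         chrom=chrom, start=start, end=start + len(genomic),
                         strand=strand))

    for cls in NCRNA_CLASSES:
        for i in range(config.n_ncrna_loci):
            name = f"{cls}_{i + 1}"
            seq = _rand_seq(rng, _NCRNA_LEN[cls])
            start = place(seq)
            features.append(dict(chrom=chrom, start=start,
                                 end=start + len(seq), strand="+",
                                 feature=cls, name=name))
            loci.append(dict(name=name, locus_class=cls, chrom=chrom,
                             start=start, end=start + len(seq), strand="+"))

    for i in range(config.n_gene_loci):
        for part, length in (("Exon", 200), ("Intron", 150), ("Exon", 200)):
            name = f"gene{i + 1}_{part.lower()}{len(features)}"
            seq = _rand_seq(rng, length)
            start = place(seq)
            features.append(dict(chrom=chrom, start=start,
                                 end=start + length, strand="+",
                                 feature=part, name=name))
            loci.append(dict(name=name, locus_class=part, chrom=chrom,
                             start=start, end=start + length, strand="+"))

    if pos > config.genome_length:
        raise PlacementError(
            f"planted loci need {pos} bases but genome_length="
            f"{config.genome_length} (n_known_mirnas={config.n_known_mirnas},"
            f" n_novel_precursors={config.n_novel_precursors})")
    segments.append(_rand_seq(rng, config.genome_length - pos))
    genome = {chrom: "".join(segments)}

    annotation = pd.DataFrame(
        features, columns=["chrom", "start", "end", "strand", "feature", "name"])
    loci_df = pd.DataFrame(
        loci, columns=["name", "locus_class", "chrom", "start", "end", "strand"])

    plan = config.de_plan or default_de_plan(known_names, novel_names)
    base = {}
    for name in known_names + novel_names:
        de = plan.get(name, {}).get("membership", "none") != "none"
        base[name] = float(rng.uniform(2000, 5000) if de
                           else rng.uniform(500, 3000))
    base_tpm = pd.Series(base)
    planted_counts = _planted_mean_counts(config, plan, base_tpm)
    planted_de = pd.DataFrame([
        dict(mirna=m, direction=e["direction"], membership=e["membership"],
             lfc=e["lfc"]) for m, e in plan.items()])

    pools = _build_pools(rng, genome[chrom], loci_df, config)
    truth = TruthTable(loci_df, planted_counts, planted_de, mature_seqs,
                       precursors, pools, base_tpm)
    return genome, annotation, catalog, truth


def _fragment_pool(rng, seq: str, n: int, lo=18, hi=28):
    frags = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        if len(seq) <= length:
            frags.append(seq)
        else:
            start = int(rng.integers(0, len(seq) - length))
            frags.append(seq[start:start + length])
    return frags


def _build_pools(rng, chrom_seq: str, loci: pd.DataFrame, config: SimConfig):
    """Fixed fragment pools with Zipf-like weights per read class, so that
    repeated sampling yields realistic tag-count distributions while keeping
    the unique-tag universe bounded."""
    pools: dict[str, tuple[list[str], np.ndarray]] = {}

    def zipf_weights(n):
        w = 1.0 / np.arange(1, n + 1)
        return w / w.sum()

    for cls in NCRNA_CLASSES:
        frags: list[str] = []
        for _, row in loci[loci["locus_class"] == cls].iterrows():
            frags += _fragment_pool(
                rng, chrom_seq[row["start"]:row["end"]], 12)
        pools[cls] = (frags, zipf_weights(len(frags)))

    for cls, key in (("Exon", "exon"), ("Intron", "intron")):
        frags = []
        for _, row in loci[loci["locus_class"] == cls].iterrows():
            frags += _fragment_pool(rng, chrom_seq[row["start"]:row["end"]], 15)
        pools[key] = (frags, zipf_weights(len(frags)))

    # loop/star fragments of known precursors (mapping category: Precursor)
    frags = []
    for _, row in loci[loci["locus_class"] == "known_precursor"].iterrows():
        sub = chrom_seq[row["start"] + 21:row["end"]]
        frags += _fragment_pool(rng, sub, 4, lo=18, hi=min(28, len(sub)))
    pools["precursor"] = (frags, zipf_weights(len(frags)))

    # intergenic background: fragments avoiding every planted locus, with
    # the 21/24-nt-dominant length profile typical of plant sRNA libraries
    lengths = np.arange(15, 31)
    length_w = np.full(len(lengths), 0.034)
    for ln, w in ((21, 0.25), (22, 0.08), (23, 0.08), (24, 0.18)):
        length_w[ln - 15] = w
    length_w /= length_w.sum()
    intervals = sorted(zip(loci["start"], loci["end"]))
    frags = []
    tries = 0
    while len(frags) < config.background_pool_size and tries < 50 * config.background_pool_size:
        tries += 1
        length = int(rng.choice(lengths, p=length_w))
        start = int(rng.integers(0, len(chrom_seq) - length))
        if any(s < start + length and e > start for s, e in intervals):
            continue
        frags.append(chrom_seq[start:start + length])
    pools["background"] = (frags, zipf_weights(len(frags)))

    # reads that map nowhere
    frags = [_rand_seq(rng, int(rng.integers(18, 29))) for _ in range(300)]
    pools["unmapped"] = (frags, zipf_weights(len(frags)))
    return pools


def _nb_counts(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion*m^2 (Poisson at 0)."""
    means = np.asarray(means, dtype=float)
    out = np.zeros(means.shape, dtype=np.int64)
    pos = means > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(means[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + means[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_library(truth: TruthTable, library_id: str,
                     config: SimConfig) -> list[tuple[str, str]]:
    """Simulate one library's reads as (id, sequence) tuples.

    Read identifiers are opaque serial numbers; sequences are insert +
    3' adapter except for the planted artifact classes.  A per-library seed
    derived from the master seed keeps libraries independent yet
    reproducible.
    """
    lib = config.library(library_id)
    lib_index = [l.library_id for l in config.libraries].index(library_id)
    rng = np.random.default_rng([config.seed, 1000 + lib_index])
    depth = lib.depth
    if depth == 0:
        return []
    adapter = config.adapter
    inserts: list[str] = []

    mirnas = list(truth.planted_counts.index)
    means = truth.planted_counts[library_id].to_numpy()
    counts = _nb_counts(rng, means, config.dispersion)
    for mirna, c in zip(mirnas, counts):
        if c > 0:
            inserts += [truth.mature_seqs[mirna]] * int(c)

    class_fracs: dict[str, float] = {}
    for cls in NCRNA_CLASSES:
        class_fracs[cls] = config.ncrna_fractions.get(cls, 0.0)
    class_fracs["exon"] = config.exon_fraction
    class_fracs["intron"] = config.intron_fraction
    class_fracs["precursor"] = config.precursor_fraction
    class_fracs["unmapped"] = config.unmapped_fraction
    for cls, frac in class_fracs.items():
        n = rng.binomial(depth, frac)
        frags, weights = truth.pools[cls]
        if n and frags:
            idx = rng.choice(len(frags), size=n, p=weights)
            inserts += [frags[i] for i in idx]

    reads: list[str] = [ins + adapter for ins in inserts]
    for kind, rate in config.artifact_rates.items():
        n = rng.binomial(depth, rate)
        for _ in range(n):
            if kind == "polya":
                reads.append("A" * int(rng.integers(20, 28)) + adapter)
            elif kind == "no_insert":
                reads.append(adapter)
            elif kind == "too_long":
                reads.append(_rand_seq(rng, int(rng.integers(31, 40))) + adapter)
            elif kind == "too_short":
                reads.append(_rand_seq(rng, int(rng.integers(5, 15))) + adapter)
            elif kind == "no_adapter":
                reads.append(_rand_seq(rng, 25))

    n_background = depth - len(reads)
    if n_background < 0:
        raise ValueError(
            "planted means plus artifact rates exceed library depth; "
            "reduce expression or fractions")
    frags, weights = truth.pools["background"]
    idx = rng.choice(len(frags), size=n_background, p=weights)
    reads += [frags[i] + adapter for i in idx]

    order = rng.permutation(len(reads))
    return [(f"{library_id}.{i + 1}", reads[j]) for i, j in enumerate(order)]


def simulate_qpcr(truth: TruthTable, noise_sd: float = 0.2,
                  seed: int = 0, n_mirnas: int = 8,
                  reference: str = "U6") -> pd.DataFrame:
    """Ct table for selected differentially expressed miRNAs.

    Construction guarantees ``-ddCt = planted log2FC + N(0, noise_sd)``:
    the reference gene sits at Ct 20 in both groups, the target at Ct 25 in
    control and ``25 - lfc + noise`` under treatment.  Columns: sample,
    group, gene, ct.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    de = truth.planted_de
    eligible = de[(de["direction"] != "ns") & np.isfinite(de["lfc"])]
    known = [m for m in eligible["mirna"] if m.startswith("kno")][:n_mirnas // 2]
    novel = [m for m in eligible["mirna"] if m.startswith("nov")][:n_mirnas - len(known)]
    chosen = known + novel
    rows = []
    for mirna in chosen:
        entry = de.set_index("mirna").loc[mirna]
        geno = "HS" if entry["membership"] == "HS-only" else "HT"
        lfc = float(entry["lfc"])
        noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        seq = truth.mature_seqs[mirna]
        rows += [
            dict(sample=f"{geno}_0h", group="control", gene=reference, ct=20.0,
                 mirna=mirna, sequence=""),
            dict(sample=f"{geno}_0h", group="control", gene=mirna, ct=25.0,
                 mirna=mirna, sequence=seq),
            dict(sample=f"{geno}_6h", group="treatment", gene=reference,
                 ct=20.0, mirna=mirna, sequence=""),
            dict(sample=f"{geno}_6h", group="treatment", gene=mirna,
                 ct=25.0 - lfc + noise, mirna=mirna, sequence=seq),
        ]
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct",
                                       "mirna", "sequence"])


def make_transcriptome(truth: TruthTable, config: SimConfig):
    """Transcripts with planted miRNA target sites plus a term-to-gene map
    containing one genuinely enriched term among the targets of heat-
    responsive miRNAs.  Returns (transcripts, target_truth, term_map)."""
    rng = np.random.default_rng([config.seed, 77])
    de = truth.planted_de
    de_mirnas = list(de.loc[de["direction"] != "ns", "mirna"])
    transcripts: dict[str, str] = {}
    target_rows = []
    names = [f"tx{i + 1:04d}" for i in range(config.n_transcripts)]
    for name in names:
        transcripts[name] = _rand_seq(rng, config.transcript_length)
    slots = list(names)
    rng.shuffle(slots)
    for k, mirna in enumerate(de_mirnas):
        tx = slots[k % len(slots)]
        site = revcomp(truth.mature_seqs[mirna])
        pos = int(rng.integers(20, config.transcript_length - len(site) - 20))
        s = transcripts[tx]
        transcripts[tx] = s[:pos] + site + s[pos + len(site):]
        target_rows.append(dict(mirna=mirna, transcript=tx, start=pos,
                                end=pos + len(site)))
    target_truth = pd.DataFrame(target_rows,
                                columns=["mirna", "transcript", "start", "end"])

    terms = [f"T{i + 1:04d}" for i in range(config.n_terms)]
    term_rows = []
    planted_term = "T9999"
    ht_targets = set(target_truth.loc[
        target_truth["mirna"].isin(
            de.loc[de["membership"] != "none", "mirna"]), "transcript"])
    for gene in names:
        k = int(rng.integers(2, 5))
        for t in rng.choice(terms, size=k, replace=False):
            term_rows.append(dict(gene=gene, term_id=t,
                                  term_name=f"process {t}",
                                  namespace="biological_process"))
        if gene in ht_targets or rng.random() < 0.03:
            term_rows.append(dict(gene=gene, term_id=planted_term,
                                  term_name="response to temperature stimulus",
                                  namespace="biological_process"))
    term_map = pd.DataFrame(term_rows,
                            columns=["gene", "term_id", "term_name",
                                     "namespace"])
    return transcripts, target_truth, term_map


def write_study(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise the full synthetic study on disk; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, catalog, truth = make_reference(config)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    mio.write_fasta(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    mio.write_gff3(annotation, paths["annotation"])
    paths["known_catalog"] = outdir / "known_mirnas.fa"
    mio.write_fasta(catalog, paths["known_catalog"])
    for lib in config.libraries:
        reads = simulate_library(truth, lib.library_id, config)
        p = outdir / f"{lib.library_id}.fastq"
        mio.write_fastq(reads, p)
        paths[f"fastq:{lib.library_id}"] = p
    qpcr = simulate_qpcr(truth, noise_sd=0.2, seed=config.seed + 7)
    paths["qpcr"] = outdir / "qpcr_ct.tsv"
    mio.write_tsv(qpcr, paths["qpcr"])
    transcripts, target_truth, term_map = make_transcriptome(truth, config)
    paths["transcriptome"] = outdir / "transcripts.fa"
    mio.write_fasta(transcripts, paths["transcriptome"])
    paths["term_map"] = outdir / "term_map.tsv"
    mio.write_tsv(term_map, paths["term_map"])
    paths["truth_loci"] = outdir / "truth_loci.tsv"
    mio.write_tsv(truth.planted_loci, paths["truth_loci"])
    paths["truth_de"] = outdir / "truth_de.tsv"
    mio.write_tsv(truth.planted_de, paths["truth_de"])
    paths["truth_counts"] = outdir / "truth_counts.tsv"
    mio.write_tsv(truth.planted_counts.reset_index(names="mirna"),
                  paths["truth_counts"])
    paths["truth_targets"] = outdir / "truth_targets.tsv"
    mio.write_tsv(target_truth, paths["truth_targets"])
    return paths
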