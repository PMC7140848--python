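"""Config-driven orchestration of the full analysis with report tables.

Stages run in order preprocess -> classify -> discovery -> differential
expression -> targets/enrichment/qPCR; every intermediate is written as TSV
and a JSON manifest records the package version, seed and every parameter
that affects any output, so two runs with the same config are byte
identical.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffexpr, discovery, downstream
from . import io as mio
from .classify import (Annotation, GenomeIndex, align_tag, assign_category,
                       build_category_table, match_known)
from .preprocess import CleanParams, clean_reads, length_distribution, merge_tags

GENOME_CATEGORIES = ("Mature", "Precursor", "rRNA", "tRNA", "snRNA",
                     "snoRNA", "Rfam_other", "Exon", "Intron", "Intergenic")
NCRNA_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "Rfam_other")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    known_catalog: str
    fastqs: dict  # library id -> path
    outdir: str
    adapter: str
    transcriptome: str | None = None
    term_map: str | None = None
    qpcr: str | None = None
    seed: int = 0
    min_len: int = 15
    max_len: int = 30
    max_mismatches_genome: int = 0
    max_mismatches_known: int = 3
    mfei_threshold: float = discovery.DEFAULT_MFEI_THRESHOLD
    min_candidate_expression: int = discovery.DEFAULT_MIN_EXPRESSION
    candidate_len_range: tuple = (19, 25)
    strict_star: bool = False
    alpha: float = 0.01
    lfc_threshold: float = 1.0
    target_cutoff: float = downstream.DEFAULT_CUTOFF
    energy_ratio_cutoff: float = downstream.DEFAULT_ENERGY_RATIO
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        for label in ("genome", "annotation", "known_catalog"):
            path = getattr(self, label)
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        for lib, path in self.fastqs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"FASTQ for {lib} not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _contrasts(library_ids: list[str]) -> list[tuple[str, str]]:
    """Heat-treated vs control contrasts within each genotype."""
    pairs = []
    for geno in ("HT", "HS"):
        control = f"{geno}_0h"
        if control not in library_ids:
            continue
        for tp in (6, 12):
            treated = f"{geno}_{tp}h"
            if treated in library_ids:
                pairs.append((control, treated))
    return pairs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # ---------------- preprocess ----------------
    params = CleanParams(adapter=config.adapter, min_len=config.min_len,
                         max_len=config.max_len)
    tagsets, stats, lengths = {}, {}, {}
    lib_ids = sorted(config.fastqs)
    try:
        for lib in lib_ids:
            with open(config.fastqs[lib]) as fh:
                tags, st = clean_reads(fh, params, lib)
            tagsets[lib] = tags
            stats[lib] = st
            lengths[lib] = length_distribution(tags, lib)
    except ValueError as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    tags = merge_tags(tagsets.values())
    totals = {lib: float(stats[lib].total_clean) for lib in lib_ids}
    bundle["clean_stats"] = pd.DataFrame([
        dict(library=lib, total_raw=stats[lib].total_raw,
             total_clean=stats[lib].total_clean,
             **{f"discarded_{k}": stats[lib].discarded.get(k, 0)
                for k in ("no_adapter", "no_insert", "polya", "too_short",
                          "too_long", "low_quality")})
        for lib in lib_ids])
    bundle["length_distribution"] = pd.DataFrame([
        dict(library=lib, length=length, read_fraction=rf, tag_fraction=tf)
        for lib in lib_ids
        for length, (rf, tf) in lengths[lib].items()])

    # ---------------- classify ----------------
    genome = mio.read_fasta(config.genome)
    annotation = Annotation(mio.read_gff3(config.annotation))
    catalog = mio.read_fasta(config.known_catalog)
    index = GenomeIndex(genome)
    categories: dict[str, str] = {}
    best_hits: dict[str, object] = {}
    for seq in tags:
        hits = align_tag(seq, index, config.max_mismatches_genome)
        categories[seq] = assign_category(hits, annotation)
        if hits:
            best_hits[seq] = hits[0]
    category_counts = {
        lib: Counter() for lib in lib_ids}
    for seq, counts in tags.items():
        cat = categories[seq]
        for lib in lib_ids:
            c = counts.get(lib, 0)
            if c:
                category_counts[lib][cat] += c
    bundle["category_table"] = build_category_table(category_counts)

    known_counts: dict[str, Counter] = {}
    novel_candidates: list[str] = []
    lo, hi = config.candidate_len_range
    for seq, counts in tags.items():
        cat = categories[seq]
        if cat in NCRNA_CATEGORIES or cat == "Unmapped":
            continue
        m = match_known(seq, catalog, config.max_mismatches_known) \
            if catalog else None
        if m is not None:
            known_counts.setdefault(m.catalog_id, Counter()).update(counts)
        elif (cat == "Intergenic" and lo <= len(seq) <= hi
              and sum(counts.values()) >= config.min_candidate_expression):
            novel_candidates.append(seq)

    # ---------------- discovery ----------------
    observed = set(tags)
    calls = []
    for seq in sorted(novel_candidates):
        hit = best_hits.get(seq)
        if hit is None:
            continue
        call = discovery.evaluate_candidate(
            seq, hit, genome, observed_tags=observed,
            mfei_threshold=config.mfei_threshold,
            strict_star=config.strict_star)
        calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.precursor_start))
    novel_rows = []
    novel_counts: dict[str, Counter] = {}
    n_pass = 0
    for call in calls:
        if call.verdict:
            n_pass += 1
            name = f"novel_mir{n_pass:03d}"
        else:
            name = ""
        novel_rows.append(dict(
            novel_id=name, sequence=call.tag_sequence, chrom=call.chrom,
            start=call.precursor_start, end=call.precursor_end,
            strand=call.strand, length=len(call.precursor_seq),
            arm=(call.duplex.mature_arm if call.duplex else ""),
            mfe=(call.structure.mfe if call.structure else np.nan),
            mfei=(call.structure.mfei if call.structure else np.nan),
            star_observed=call.star_observed,
            verdict="pass" if call.verdict else "fail",
            reasons=";".join(call.reasons),
            dot_bracket=(call.structure.dot_bracket if call.structure else ""),
            precursor=call.precursor_seq))
        if call.verdict:
            novel_counts[name] = Counter(tags[call.tag_sequence])
    bundle["novel_calls"] = pd.DataFrame(novel_rows, columns=[
        "novel_id", "sequence", "chrom", "start", "end", "strand", "length",
        "arm", "mfe", "mfei", "star_observed", "verdict", "reasons",
        "dot_bracket", "precursor"])

    # ---------------- differential expression ----------------
    sequences = {}
    all_counts = {}
    for cid, counts in sorted(known_counts.items()):
        all_counts[cid] = counts
        sequences[cid] = catalog[cid].upper().replace("U", "T")
    for nid, counts in sorted(novel_counts.items()):
        all_counts[nid] = counts
    for row in novel_rows:
        if row["novel_id"]:
            sequences[row["novel_id"]] = row["sequence"]
    count_matrix = pd.DataFrame(
        {lib: {m: all_counts[m].get(lib, 0) for m in all_counts}
         for lib in lib_ids}).fillna(0).astype(int)
    count_matrix.index.name = "mirna_id"
    bundle["counts"] = count_matrix
    # the low-expression rule looks across every library, not per contrast
    tpm_all = count_matrix.apply(lambda col: col / totals[col.name] * 1e6)
    tested = count_matrix.loc[diffexpr.low_expression_filter(tpm_all).index]
    de_tables = []
    for control, treated in _contrasts(lib_ids):
        df = diffexpr.run_contrast(tested, totals, control, treated,
                                   alpha=config.alpha,
                                   lfc_threshold=config.lfc_threshold,
                                   prefiltered=True)
        df.insert(2, "sequence", df["mirna_id"].map(sequences))
        de_tables.append(df)
    de = pd.concat(de_tables, ignore_index=True) if de_tables \
        else pd.DataFrame()
    bundle["de"] = de
    if len(de):
        ht = de[de["contrast"].str.startswith("HT")]
        hs = de[de["contrast"].str.startswith("HS")]
        member = diffexpr.membership(ht, hs)
        bundle["membership"] = member.rename_axis("mirna_id").reset_index()
    else:
        bundle["membership"] = pd.DataFrame(columns=["mirna_id", "membership"])

    # ---------------- downstream ----------------
    de_mirnas = sorted(set(de.loc[de["direction"] != "ns", "mirna_id"])) \
        if len(de) else []
    if config.transcriptome and de_mirnas:
        transcriptome = mio.read_fasta(config.transcriptome)
        hits_a_all, hits_b_all = [], []
        for mid in de_mirnas:
            a, b = downstream.scan_targets(
                mid, sequences[mid], transcriptome,
                cutoff=config.target_cutoff,
                energy_cutoff=config.energy_ratio_cutoff)
            hits_a_all += a
            hits_b_all += b
        consensus = downstream.consensus_targets(hits_a_all, hits_b_all)
        bundle["targets"] = pd.DataFrame([
            dict(mirna=h.mirna_id, transcript=h.transcript_id, start=h.start,
                 end=h.end, penalty=h.penalty_score,
                 energy_ratio=h.energy_ratio,
                 scorers="".join(sorted(h.scorers)))
            for h in consensus])
        if config.term_map and len(consensus):
            term_map = mio.read_tsv(config.term_map)
            study = sorted({h.transcript_id for h in consensus})
            bundle["enrichment"] = downstream.enrich_terms(
                study, term_map, alpha=config.enrichment_alpha)
    if config.qpcr:
        ct = mio.read_tsv(config.qpcr)
        qp = downstream.qpcr_table(ct)
        qp = _join_seq_lfc(qp, ct, de)
        bundle["qpcr"] = qp
        ok = qp.dropna(subset=["seq_log2fc"])
        if len(ok) >= 3:
            r, r2 = downstream.corr_validation(ok["qpcr_log2fc"],
                                               ok["seq_log2fc"])
            bundle["qpcr_correlation"] = pd.DataFrame(
                [dict(n=len(ok), r=r, r_squared=r2)])

    _write_bundle(bundle, outdir)
    _write_manifest(config, outdir)
    return bundle


def _join_seq_lfc(qp: pd.DataFrame, ct: pd.DataFrame,
                  de: pd.DataFrame) -> pd.DataFrame:
    """Attach the sequencing log2FC matching each qPCR assay's contrast
    (derived from the sample ids), joining known miRNAs by name and novel
    assays by mature sequence."""
    seq_lfc = []
    for _, row in qp.iterrows():
        mirna = row["mirna"]
        sub = ct[(ct["mirna"] == mirna) & (ct["gene"] == mirna)]
        treat_sample = sub.loc[sub["group"] == "treatment", "sample"].iloc[0]
        ctrl_sample = sub.loc[sub["group"] == "control", "sample"].iloc[0]
        contrast = f"{treat_sample}_vs_{ctrl_sample}"
        assay_seq = str(sub["sequence"].iloc[0]) if "sequence" in sub else ""
        val = np.nan
        if len(de):
            sel = de[(de["contrast"] == contrast)
                     & ((de["mirna_id"] == mirna)
                        | (de["sequence"] == assay_seq))]
            if len(sel):
                val = float(sel["log2fc"].iloc[0])
        seq_lfc.append(val)
    qp = qp.copy()
    qp["seq_log2fc"] = seq_lfc
    return qp


def format_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Human-readable per-contrast table: counts, 2-decimal log2 ratio and
    3-significant-figure p-value."""
    if not len(de):
        return pd.DataFrame(columns=["miRNA Name", "Sequence (5>3)",
                                     "Count 1", "Count 2", "log2 Ratio",
                                     "p-Value", "Contrast"])
    out = pd.DataFrame({
        "miRNA Name": de["mirna_id"],
        "Sequence (5>3)": de["sequence"],
        "Count 1": de["count1"],
        "Count 2": de["count2"],
        "log2 Ratio": de["log2fc"].map(lambda v: f"{v:.2f}"),
        "p-Value": de["p"].map(lambda v: f"{v:.3g}"),
        "Contrast": de["contrast"],
    })
    return out


def _write_bundle(bundle: dict, outdir: Path) -> None:
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            mio.write_tsv(obj.reset_index() if obj.index.name else obj,
                          outdir / f"{name}.tsv")
    if "category_table" in bundle:
        tab = bundle["category_table"]
        cells = tab[["category"] + [c for c in tab.columns
                                    if c.endswith("_cell")]]
        mio.write_tsv(cells, outdir / "category_table_formatted.tsv")
    if "de" in bundle:
        mio.write_tsv(format_de_table(bundle["de"]),
                      outdir / "de_formatted.tsv")


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    manifest = {"package": "mirpipe", "version": __version__,
                "parameters": asdict(config)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
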