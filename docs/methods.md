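# Methods

`mirpipe` re-implements, as a tested library plus CLI, the computational
workflow of a two-genotype plant small-RNA sequencing study: heat-tolerant
(HT) and heat-sensitive (HS) flowering Chinese cabbage genotypes sampled at
0, 6 and 12 h of heat treatment, one pooled library per condition.  Every
stage is exercised end to end on synthetic data with a planted answer key.

## Read cleaning (`preprocess`)

Raw single-end reads are insert + 3′ adapter.  Discard rules apply in a
fixed order: no detectable adapter → empty insert → poly-A artifact →
length outside [15, 30] nt.  The order only affects the reason ledger, not
which reads survive; the ledger always balances
(`total_raw = total_clean + Σ discarded`).  Choices made where the source
workflow is silent:

* adapter location: semi-global suffix–prefix alignment, ≥ 6 nt overlap,
  ≤ 10 % mismatches, leftmost acceptable match; reads without a detectable
  adapter are discarded, not kept untrimmed;
* poly-A: insert with ≥ 90 % A over its full length (applied before the
  length rules, so an A-homopolymer short insert counts as poly-A);
* no base-quality filtering by default (a mean-quality floor exists but is
  off); U is normalized to T on input.

## Mapping and classification (`classify`)

Tags are aligned ungapped to both genome strands by pigeonhole seeding over
an exact k-mer index (k = 5): a tag split into `m+1` segments must contain
one exact segment in any hit with ≤ m Hamming mismatches, so seeding plus
full verification is provably exhaustive (and is tested against a
brute-force scan).  Reads are partitioned into the standard accounting
categories; multi-feature overlaps resolve by specificity:
Mature > Precursor > rRNA > tRNA > snRNA > snoRNA > other structural RNA >
Exon > Intron > Intergenic, with Unmapped for hitless tags.  Multi-mapping
tags are assigned once, by their best hit (fewest mismatches, then leftmost).
Percentages display as `count(pct%)` with two decimals, trailing zeros
stripped.

Known miRNAs are same-length catalog entries within Hamming distance 3
(ties broken lexicographically by catalog id); genome-mapped intergenic
tags of 19–25 nt absent from the catalog and with ≥ 5 reads across
libraries are novel-miRNA candidates.

## Folding (`rnafold`)

A simplified Zuker dynamic program over a nearest-neighbour model:
stacking energies for the six canonical pairs (Watson–Crick + G:U wobble,
Turner-like constants in one auditable table), length-indexed hairpin /
bulge / internal-loop penalties with logarithmic extrapolation, an affine
multiloop term, minimum hairpin loop 3 nt, no dangles, 37 °C only.  The
energy of a structure decomposes over the loops closed by each pair;
`structure_energy` evaluates that decomposition for any nested pair set,
which makes exhaustive enumeration an independent oracle for the DP — the
suite verifies global optimality on hundreds of short random sequences and
the reduction to Nussinov base-pair maximisation when loop penalties are
zeroed and each pair is worth −1.  Only qualitative agreement with Mfold
(MFE sign, hairpin topology) is claimed, never its exact energies.

MFEI follows the standard plant-miRNA definition
`|MFE| / length × 100 / GC%`; the acceptance threshold defaults to 0.85.

## Novel-miRNA discovery (`discovery`)

For each candidate tag both orientations (tag as 5′ or 3′ arm) of a ladder
of excision windows — (0, 55), (5, 60), (20, 70), (20, 180) nt beyond the
tag — are folded.  Each fold is trimmed to the stem-loop that actually
contains the tag: from the hairpin loop the stem is walked outward while
the connecting interior loop stays ≤ 8 unpaired bases, because flanking
genomic sequence routinely forms spurious enclosing stems joined to a real
hairpin by large loops.  The trimmed precursor is refolded and must pass
the community annotation gate for plant miRNAs: single stem-loop, MFE < 0,
MFEI ≥ 0.85, and a miRNA/miRNA* duplex with < 3 mismatches and at most one
bulge of ≤ 2 nt.  A G:U pair counts as paired; between paired anchors with
`a` and `b` unpaired bases on the two strands, `min(a, b)` count as
mismatches and an asymmetric remainder as one bulge of size `|a−b|`.  The
star interval uses the canonical 2-nt 3′ overhang
(`[partner(m2−3), partner(m1)+3)`), which inverts exactly on a clean
duplex.  Windows are tried shortest first and the first passing window is
kept (the most parsimonious precursor).  Star observation among sequenced
tags is reported; it is only required in the optional strict mode, since
requiring a sequenced star at these depths would veto genuine precursors.

## Differential expression (`diffexpr`)

Expression is reads per million clean reads; exact zeros become 0.01 so
fold changes `log2(N2/N1)` stay finite, and miRNAs below 1 TPM in every
library are dropped.  Significance uses the exact two-library count test:
conditional on count `x` in library 1, the count in library 2 follows
`p(y|x) = r^y (x+y)!/(x!y!) (1+r)^−(x+y+1)` with `r = N2/N1` — a negative
binomial with `x+1` successes at probability `1/(1+r)`, the identity used
as an independent oracle.  Both tails are accumulated in log space (the
naive `D = 1 − C + p` closure loses all precision on small upper tails);
the two-sided p-value is `min(1, 2·min(C, D))` and FDR control is
Benjamini–Hochberg.  Note the two-sided value is exactly symmetric in the
libraries only up to tail discreteness (bounded by the shared point mass),
a property of the tail construction itself.

p-values come from raw counts with clean-read totals; fold changes from
floored TPM.  Defaults, configurable: FDR ≤ 0.01 and |log2FC| ≥ 1.
Contrasts are heat versus control within genotype (6 h vs 0 h, 12 h vs
0 h); a miRNA significant in at least one contrast of a genotype counts
once toward the HT-only / HS-only / both membership labels.

## Targets, enrichment, qPCR (`downstream`)

Target sites use the plant penalty scheme shared by the TargetFinder/TAPIR
tool lineage: mismatch 1, G:U 0.5, gap 2, doubled at miRNA positions 2–13,
cutoff 4.0 (scorer A); scorer B additionally requires duplex stacking
energy ≥ 70 % of the perfect-complement duplex under the folding model's
stack table.  Ungapped windows are pre-screened vectorized; gapped
alignment (≤ 1 target bulge) runs near the cutoff.  Only sites called by
both scorers with ≥ 50 % overlap survive.  Term enrichment is the
upper-tail hypergeometric test in log space with BH correction, against a
universe defaulting to all genes of the supplied term map.  qPCR relative
expression is 2^−ΔΔCt with U6 as reference and amplification efficiency
assumed exactly 2; concordance with sequencing is Pearson r².

## Synthetic study (`simdata`)

The generator's defaults are the stated world of the emulated design: a
100 kb genome; 30 catalog miRNAs and 12 novel precursors, hairpins built
by explicit reverse-complement arm design (mature 21 nt, all-A loop flanked
by G/C-only stem ends so the loop cannot extend the stem and the designed
pairing is also the thermodynamic one; knowns carry ≤ 2 designed mismatches
and ≤ 1 bulge of ≤ 2 nt, novels one mismatch); structural-RNA loci (rRNA
2 %, tRNA 2 %, snRNA 0.5 %, snoRNA 0.5 %, other 1 % of reads) plus exon /
intron / precursor-fragment and unmapped read classes; six libraries of
10⁵ reads.  Planted effects are ±2 log2 units at both heat timepoints with
HT-only / HS-only / both / none membership blocks; two catalog miRNAs are
silenced to zero counts under treatment to exercise the TPM floor.  Counts
are negative binomial with `var = m + 0.01·m²`: one pooled library per
condition means technical, near-Poisson sampling with mild overdispersion
(the design pools biological replicates before sequencing, so no replicate
variance component is modelled).  Reads are drawn from fixed fragment pools
with Zipf-like weights (bounding the unique-tag universe, as repeated
degradation products do in real libraries); background fragment lengths
follow the 21/24-dominant profile of plant sRNA libraries.  Artifact
classes (poly-A, no-insert, oversized, short, adapter-less) default to 2 %
each.  The qPCR table is constructed so −ΔΔCt equals the planted log2FC
plus Gaussian noise (default SD 0.2 Ct).

What a green run does establish: the pipeline recovers planted classes,
effects, hairpins and targets from raw reads at realistic depths.  What it
does not: sequencing-error or quality-score realism, replicate variance,
isomiR heterogeneity, genome-scale repeat structure, or agreement with any
specific external folding/alignment tool.

## Numerical and degenerate-input choices

* Folding ties break by a fixed traceback case order (hairpin, interior by
  increasing loop size, multiloop), making outputs deterministic.
* Interior loops in the DP are capped at 30 unpaired bases (configurable;
  the cap is lifted for the Nussinov reduction).
* All randomness flows from explicit seeds (`numpy` Generators); reruns
  with the same configuration are byte-identical.
* Zero-depth libraries, empty catalogs, empty DE sets and header-only
  tables are all legal and covered by tests.

## Known limitations

* The energy model is a compact approximation: no terminal-mismatch,
  dangle or special-hairpin terms, so absolute MFEs differ from Mfold /
  ViennaRNA by several kcal/mol on long precursors.
* The aligner is ungapped by design; spliced or indel alignment is out of
  scope.
* The exact test inherits the discreteness of its tail construction (see
  above); at pooled-library depths this is negligible.
* Target scanning rescues gapped sites only near the ungapped pre-screen
  margin; deeply gapped sites below the cutoff are not guaranteed to be
  enumerated.
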