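# Methods

## Model and assumptions

The central object is the fragment: one sequenced DNA molecule, observed as
a read pair. Because both reads of a pair come from the same molecule,
co-observation of two alt alleles on one fragment implies they lie on the
same physical chromosome; consistent observation of them on *different*
fragments only, never together, implies the opposite. This direct-evidence
model deliberately uses no population or statistical phasing — linkage
exists only between SNVs close enough (within the library insert size) to
be spanned by one fragment, which is exactly the regime where codon-level
mis-annotation arises. In a normal diploid genome at most two haplotypes
are expected per locus; tumor samples may show more (heterogeneity,
aneuploidy), so haplotypes are enumerated empirically with their
supporting-fragment counts rather than fitted to a ploidy model.

Three status values per fragment and site are distinguished: mutant (the
aligned base equals the alt allele), non-mutant (reference *or a third
allele* — both contradict the variant being present on that molecule), and
unknown (no aligned base under the CIGAR, or base quality below threshold).
Unknown is strictly uninformative: it never creates graph edges and is
rendered `-` in haplotype strings.

## Pipeline stages and numerical choices

1. **Alignment gate.** Unmapped, secondary, supplementary and QC-fail
   records are dropped; duplicate-flagged reads are dropped by default
   (they would inflate haplotype counts; `--keep-duplicates` restores
   them). Mapping quality below `--min-mapq` (default 20) drops the record.
   Pairs whose mates map to different chromosomes are dropped at collect
   time, which makes interchromosomal BMs impossible by construction.
2. **Status classification.** The queried column is located by walking the
   aligned pairs, so insertions and soft clips cannot shift it; deletions
   and reference skips give unknown. Base quality below `--min-base-qual`
   (default 20, Phred) gives unknown. Both thresholds are deliberate,
   conventional defaults; they are exposed on the CLI.
3. **Pair merging.** Per SNV, (X, unknown) → X and (X, X) → X; mates
   asserting mutant and non-mutant at the same site mark the whole fragment
   as discordant and it is excluded from *all* downstream analysis (a
   one-site sequencing error invalidates the molecule's evidence). Each
   fragment contributes at most once per site, so all reported read counts
   are unique-fragment counts; overlapping agreeing mates count once.
4. **BM detection.** Edges require known status at both endpoints. BMs are
   connected components of size ≥ 2, extracted by an iterative depth-first
   search; vertices are visited in genomic order and neighbor sets are
   sorted, making output content and order deterministic regardless of
   fragment iteration order (a hand-written union-find oracle cross-checks
   the partition on random instances in the test suite). Singletons are not
   BMs: a block requires evidence shared with at least one other mutation.
5. **Codon assignment and BMCs.** Each SNV maps to (transcript, codon
   index, position-in-codon) via the CDS model; codon genomic positions are
   stored in transcript orientation, so they decrease with genomic
   coordinate on the minus strand and may be non-contiguous across splice
   junctions. Second-layer edges join BM members sharing a codon in *any*
   common transcript. A BMC is jointly annotated only under transcripts
   where **all** members share one codon; a transcript that links only a
   subset is recorded on the BMC but produces no joint row — reporting a
   joint change under a transcript that does not cover every member would
   fabricate phase-codon agreement that does not exist.
6. **Haplotypes and block substitution.** Fragments touching a BMC are
   grouped by combined status string; all-`-` patterns are dropped.
   Ordering is by descending count, ties broken all-mutant-first — a
   readability choice; indices restart at 1 per block. Each fully known
   haplotype becomes one block substitution spanning first to last SNV with
   intervening bases kept reference; the all-`0` haplotype yields the
   identity substitution and is annotated as silent. No minimum read count
   is imposed by default (`--min-hap-reads 1`): raw counts are the
   relative-abundance information.
7. **Annotation.** The codon is rebuilt from the reference at its three
   genomic positions, substituted from the block's alt sequence where those
   positions fall in the span, complemented base-wise on the minus strand,
   and translated with the standard genetic code. Stop is rendered `*`;
   consequence is silent iff ref and alt amino acids match, nonsense iff
   the alt is a stop gained. Codon positions are CDS positions by
   construction, so for a block spanning an intron/exon border the
   non-coding part never reaches the codon and is thereby excluded from
   prediction. Haplotypes containing `-` bypass annotation and are
   suppressed unless `--report-unknown` emits them count-only. The
   annotator is a seam: any function mapping a block substitution to an
   annotation result can replace the internal one.
8. **No-annotation mode** exports status strings and counts for *all* BMs
   (not only BMCs), including `-`-containing haplotypes — there is no
   annotation step to bypass, and BMs wider than one insert size would
   otherwise produce no output at all.

## Synthetic worlds

The fixture generator emulates the ideal evidence structure of paired-end
data: a declarative spec states the reference, CDS layout, SNVs and a
haplotype configuration (status string → fragment count), and the
generator lays out read pairs whose mates jointly cover exactly the sites
each status constrains, writing alt alleles at `1` sites and reference
elsewhere. `-` sites are left uncovered where geometry allows and otherwise
masked below the base-quality threshold. Base qualities are uniform
(default Phred 35); there is no error model, indels, soft-clipping or GC
bias, so passing round-trip tests demonstrates correctness of the evidence
→ haplotype → annotation chain, not robustness to messy real alignments.
The two noise knobs target the pipeline's exclusion rules specifically:
`add_noise` injects mate-discordant fragments (which must all be excluded,
leaving counts untouched) and quality-masks chosen SNV columns.

The `table1` preset rebuilds four published dinucleotide-variant codon
contexts — HIVEP1 P433 (`CCT`, SNVs at codon positions 1–2), TP53 E285
(`GAG` on the minus strand, genomic `TC` → `AG`), CDC5L A316 (`GCG`,
positions 2–3) and ZNF407 L1973 (`TTA`, positions 1–2) — each context
uniquely determined by its reference amino acid and the two per-SNV
predictions, and asserted against the genetic code in the test suite.
Contigs are small (≤ 10 kb, fixture depths 16–30 fragments per haplotype)
with codon *indices* preserved, so change strings are exact while
coordinates are synthetic stand-ins. BAMs are written pre-sorted rather
than piped through `samtools sort`, whose `@PG` line would embed temp paths
and break byte-level reproducibility; identical spec and seed give
byte-identical FASTA and BAM.

## Degenerate inputs and limitations

Empty SNV lists are an input-stage error; indel records in SNV lists are
skipped with a count, malformed rows are errors naming the line. Transcripts
with partial CDS (nonzero first phase) or length not divisible by 3 are
rejected with warnings rather than guessed; internal stops in the translated
reference CDS warn only. Two SNVs at one position (multi-allelic) need no
special case: one aligned base is mutant for at most one of them.

Known limitations: no realignment or indel-aware assembly around the SNVs;
phasing reach is bounded by insert size; annotation is one codon at a time,
so compensating changes in neighboring codons of the same haplotype are
reported separately; consequence classes are codon-level only (no splice,
UTR or protein-impact scoring).
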