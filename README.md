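# mnvfix

Somatic variant callers report multi-nucleotide variants (MNVs) — tandem
substitutions hitting two or three bases of the same protein codon — as
independent SNVs. Annotating those SNVs one at a time then predicts the
wrong amino acid: each per-SNV prediction mutates one base of the codon
while silently assuming the other stays reference. Whether neighboring SNVs
really form an MNV is a haplotype-phasing question: do the two alt alleles
sit on the same chromosome? `mnvfix` answers it directly from the raw
sequencing fragments and re-annotates the joint consequence, for anyone
running an SNV-based calling pipeline on tumor (or other) sequencing data.

## Method

Every SNV is a vertex of a multigraph. For each SNV, reads are extracted
from the BAM and classified as mutant (`1`, aligned base equals the alt
allele), non-mutant (`0`, reference or third allele) or unknown (`-`, no
aligned base or base quality below threshold). Mate pairs are merged into
fragments — extending the phasing reach from read length to insert size —
and any pair whose mates contradict each other at a site is excluded as a
likely sequencing error. An edge joins two SNVs whenever one fragment holds
a known status at both; the connected components of size ≥ 2 (found by
depth-first search) are **Blocks of Mutations (BM)**: groups of SNVs whose
mutual phase is physically determined.

Inside each BM, a second layer of edges joins SNVs that share a codon of
some transcript; those components are **Blocks of Mutations within Codon
(BMC)** — the units whose annotation can be wrong. Fragments touching a BMC
are grouped into haplotypes by their combined status string with
unique-fragment counts (a true MNV shows `11`; the same two alts on
opposite chromosomes show `10`/`01`). Each fully known haplotype is
collapsed into a single block substitution over the span from first to last
SNV and the affected codon is rebuilt and translated with the standard
genetic code, giving the joint change, e.g. `E285L` where per-SNV
annotation claimed `E285V` and `E285Q`. A `no-annotation` mode exports the
raw phase strings and counts for all BMs so any external annotator can
consume them.

## Worked example

The `table1` preset generates a synthetic world (reference FASTA, CDS
table, SNV list, phased BAM) containing four dinucleotide variants, each a
pair of SNVs inside one codon with both alts carried by the same fragments:

```sh
mnvfix make-fixture --preset table1 --outdir demo --seed 1
mnvfix run --snvs demo/snvs.tsv --bam demo/reads.bam --ref demo/reference.fa \
           --transcripts demo/cds_model.tsv --mode annotate --out demo/report.tsv
```

```
bmc_id	haplotype_index	status	read_count	gene	transcript	amino_acid_change
chr6.1397.C>G;chr6.1398.C>G	1	11	21	HIVEP1	NM_002114	P433G
chr6.1397.C>G;chr6.1398.C>G	2	00	19	HIVEP1	NM_002114	P433P
chr6.2447.C>G;chr6.2448.G>C	1	00	22	CDC5L	NM_001253	A316A
chr6.2447.C>G;chr6.2448.G>C	2	11	17	CDC5L	NM_001253	A316G
chr17.208.T>A;chr17.209.C>G	1	11	30	TP53	NM_000546	E285L
chr17.208.T>A;chr17.209.C>G	2	00	28	TP53	NM_000546	E285E
chr18.6017.T>A;chr18.6018.T>A	1	00	20	ZNF407	NM_017757	L1973L
chr18.6017.T>A;chr18.6018.T>A	2	11	16	ZNF407	NM_017757	L1973K
```

Each row is one haplotype of one BMC. The TP53 block reads: 30 fragments
carry both alts (`11`) — a dinucleotide substitution whose joint effect is
`E285L`, not the `E285V`/`E285Q` that per-SNV annotation of the two calls
would report — while 28 fragments carry the wild-type codon (`00`,
annotated as the identity change `E285E`). The ZNF407 block shows an MNV
whose joint effect `L1973K` is missense although its second SNV alone would
be called a nonsense change (`L1973*`). Run counts (SNVs, fragments, BMs,
BMCs, haplotypes) are logged to stderr.

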