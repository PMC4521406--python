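"""Haplotype enumeration, block substitution, and joint codon re-annotation.

Within each BMC, fragments are grouped by their combined status string over
the member SNVs ('1' mutant, '0' non-mutant, '-' unknown) with unique-
fragment counts. Each fully known haplotype is collapsed into one block
substitution — a single replacement of the genomic span from the first to
the last SNV — and its joint amino-acid consequence is predicted by
rebuilding the affected codon and translating it with the standard genetic
code. A dinucleotide mutation on one chromosome appears as "11"; the same
two alts on opposite chromosomes appear as "10"/"01" and correctly keep
their per-SNV annotations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .block_detection import BlockOfMutations, build_graph, find_blocks
from .codon_bmc import BMC, CodonAssignment, assign_codons, find_bmcs
from .io_models import COMPLEMENT, SNV, ReportRow, fetch_ref, snv_from_uid
from .read_evidence import FragmentEvidence, SiteStatus, collect_fragment_evidence

logger = logging.getLogger("mnvfix")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class BlockSubstitution:
    """One contiguous replacement encoding all mutant alleles of a haplotype.

    Spans first to last SNV of the BMC (1-based inclusive); alt_seq differs
    from ref_seq exactly at the status-'1' SNV positions, intervening bases
    stay reference.
    """

    chrom: str
    start: int
    end: int
    ref_seq: str
    alt_seq: str

    def __post_init__(self) -> None:
        if len(self.ref_seq) != self.end - self.start + 1:
            raise ValueError("ref_seq length does not match span")
        if len(self.alt_seq) != len(self.ref_seq):
            raise ValueError("alt_seq and ref_seq must have equal length")


@dataclass(frozen=True)
class AnnotationResult:
    """Joint amino-acid consequence of one haplotype under one transcript."""

    gene: str
    transcript_id: str
    ref_aa: str
    codon_index: int
    alt_aa: str
    consequence: str  # missense | silent | nonsense

    @property
    def change_string(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass
class Haplotype:
    """One observed status pattern over a BMC's SNVs with its fragment count."""

    bmc_id: str
    status_string: str
    read_count: int
    block_sub: BlockSubstitution | None = None
    annotations: list[AnnotationResult] = field(default_factory=list)


def enumerate_haplotypes(block, fragments: Sequence[FragmentEvidence]) -> list[Haplotype]:
    """Group fragments by combined status over the block's SNVs.

    ``block`` is a BMC or BM (anything with ``snvs`` in genomic order). Each
    fragment touching at least one member SNV maps to exactly one status
    string (UNKNOWN -> '-'); all-'-' fragments are dropped. Output is sorted
    by descending read count, ties broken by status string descending so the
    all-mutant haplotype comes first.
    """
    members: list[str] = block.snvs
    block_id = getattr(block, "bmc_id", None) or block.bm_id
    counts: dict[str, int] = {}
    for frag in fragments:
        status = "".join(frag.status_at(uid).value for uid in members)
        if set(status) == {"-"}:
            continue
        counts[status] = counts.get(status, 0) + 1
    haps = [Haplotype(block_id, s, n) for s, n in counts.items()]
    haps.sort(key=lambda h: (-h.read_count, tuple(-ord(c) for c in h.status_string)))
    return haps


def build_block_substitution(haplotype: Haplotype, bmc, reference,
                             snv_by_uid: dict[str, SNV] | None = None) -> BlockSubstitution:
    """Collapse a fully known haplotype into one block substitution.

    Requires a '-'-free status string. Reference bases are taken over the
    span from the first to the last member SNV; the alt allele is substituted
    wherever the haplotype carries a '1'.
    """
    if "-" in haplotype.status_string:
        raise ValueError("cannot build a block substitution from an unknown status")
    snvs = [(snv_by_uid or {}).get(uid) or snv_from_uid(uid) for uid in bmc.snvs]
    chrom = snvs[0].chrom
    start, end = snvs[0].pos, snvs[-1].pos
    ref_seq = fetch_ref(reference, chrom, start, end)
    alt = list(ref_seq)
    for snv, status in zip(snvs, haplotype.status_string):
        if ref_seq[snv.pos - start] != snv.ref:
            raise ValueError(f"reference mismatch at {snv.uid}: found {ref_seq[snv.pos - start]}")
        if status == "1":
            alt[snv.pos - start] = snv.alt
    return BlockSubstitution(chrom, start, end, ref_seq, "".join(alt))


def annotate_haplotype(block_sub: BlockSubstitution,
                       assignments: Sequence[CodonAssignment],
                       reference) -> AnnotationResult:
    """Predict the joint amino-acid change of a block substitution on the one
    codon the assignments share.

    The codon's three bases are read from the reference at its genomic
    positions and substituted from the block's alt sequence where they fall
    inside the span (codon positions are CDS by construction, so a variant
    position outside the CDS never reaches the codon — the non-coding part of
    a border-spanning block is excluded from prediction). Minus-strand codons
    are complemented base-by-base since the positions are already stored in
    transcript orientation. Translation uses the standard genetic code; stop
    is rendered '*'.
    """
    if not assignments:
        raise ValueError("no codon assignments given")
    first = assignments[0]
    if any(a.transcript_id != first.transcript_id or a.codon_index != first.codon_index
           for a in assignments):
        raise ValueError("assignments must share one transcript and codon")
    ref_codon = []
    alt_codon = []
    for g in first.codon_positions:
        try:
            base = fetch_ref(reference, block_sub.chrom, g, g)
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"cannot read codon {first.codon_index} of {first.transcript_id}: {exc}"
            ) from exc
        alt_base = base
        if block_sub.start <= g <= block_sub.end:
            alt_base = block_sub.alt_seq[g - block_sub.start]
        if first.strand == "-":
            base = base.translate(COMPLEMENT)
            alt_base = alt_base.translate(COMPLEMENT)
        ref_codon.append(base)
        alt_codon.append(alt_base)
    ref_aa = str(Seq("".join(ref_codon)).translate())
    alt_aa = str(Seq("".join(alt_codon)).translate())
    if ref_aa == alt_aa:
        consequence = "silent"
    elif alt_aa == "*":
        consequence = "nonsense"
    else:
        consequence = "missense"
    return AnnotationResult(first.gene, first.transcript_id, ref_aa,
                            first.codon_index, alt_aa, consequence)


def annotate_snv(snv: SNV, assignment: CodonAssignment, reference) -> AnnotationResult:
    """Classical single-SNV annotation: a length-1 block substitution."""
    bs = BlockSubstitution(snv.chrom, snv.pos, snv.pos, snv.ref, snv.alt)
    return annotate_haplotype(bs, [assignment], reference)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineOptions:
    mode: str = "annotate"  # annotate | no_annotation
    min_base_quality: int = 20
    min_mapq: int = 20
    keep_duplicates: bool = False
    report_unknown: bool = False
    min_hap_reads: int = 1


@dataclass
class PipelineResult:
    rows: list[ReportRow]
    fragments: list[FragmentEvidence]
    bms: list[BlockOfMutations]
    bmcs: list[BMC]
    assignments: list[CodonAssignment]
    haplotypes: dict[str, list[Haplotype]]  # block id -> haplotypes


def run_analysis(snvs: Sequence[SNV], bam, reference, transcripts,
                 options: PipelineOptions | None = None) -> PipelineResult:
    """Full workflow: fragment evidence -> BM detection -> codon assignment ->
    BMC extraction -> haplotype enumeration -> annotation (or phase export).

    Under no_annotation mode, BM-level haplotype phase and read counts are
    exported for ALL BMs, not only BMCs, so any external annotator can take
    over; unknown-containing haplotypes are kept there since there is no
    annotation step to bypass.
    """
    opts = options or PipelineOptions()
    if not snvs:
        raise PipelineError("input", "empty SNV list")
    snvs = sorted(snvs, key=lambda s: s.sort_key)
    snv_by_uid = {s.uid: s for s in snvs}

    try:
        fragments = collect_fragment_evidence(
            bam, snvs, opts.min_base_quality, opts.min_mapq, opts.keep_duplicates)
    except (OSError, ValueError) as exc:
        raise PipelineError("read-evidence", str(exc)) from exc

    graph = build_graph(snvs, fragments)
    bms = find_blocks(graph)

    assignments = [a for snv in snvs for a in assign_codons(snv, transcripts)]

    rows: list[ReportRow] = []
    bmcs: list[BMC] = []
    hap_map: dict[str, list[Haplotype]] = {}

    if opts.mode == "no_annotation":
        for bm in bms:
            haps = [h for h in enumerate_haplotypes(bm, fragments)
                    if h.read_count >= opts.min_hap_reads]
            hap_map[bm.bm_id] = haps
            for i, hap in enumerate(haps, 1):
                rows.append(ReportRow(bm.bm_id, i, hap.status_string, hap.read_count))
    elif opts.mode == "annotate":
        for bm in bms:
            for bmc in find_bmcs(bm, assignments):
                bmcs.append(bmc)
                haps = [h for h in enumerate_haplotypes(bmc, fragments)
                        if h.read_count >= opts.min_hap_reads]
                hap_map[bmc.bmc_id] = haps
                index = 0
                for hap in haps:
                    if "-" in hap.status_string:
                        if not opts.report_unknown:
                            continue
                        index += 1
                        rows.append(ReportRow(bmc.bmc_id, index,
                                              hap.status_string, hap.read_count))
                        continue
                    index += 1
                    try:
                        hap.block_sub = build_block_substitution(
                            hap, bmc, reference, snv_by_uid)
                    except ValueError as exc:
                        raise PipelineError("block-substitution", str(exc)) from exc
                    if not bmc.shared_codon:
                        logger.debug("BMC %s has no transcript covering all members; "
                                     "emitting phase only", bmc.bmc_id)
                        rows.append(ReportRow(bmc.bmc_id, index,
                                              hap.status_string, hap.read_count))
                        continue
                    for tid in sorted(bmc.shared_codon):
                        subset = [a for a in assignments
                                  if a.transcript_id == tid and a.snv_uid in bmc.snvs]
                        try:
                            res = annotate_haplotype(hap.block_sub, subset, reference)
                        except ValueError as exc:
                            raise PipelineError("annotation", str(exc)) from exc
                        hap.annotations.append(res)
                        rows.append(ReportRow(bmc.bmc_id, index, hap.status_string,
                                              hap.read_count, res.gene,
                                              res.transcript_id, res.change_string))
    else:
        raise PipelineError("options", f"unknown mode {opts.mode!r}")

    logger.info("%d SNVs, %d fragments, %d BMs, %d BMCs, %d haplotypes",
                len(snvs), len(fragments), len(bms), len(bmcs),
                sum(len(v) for v in hap_map.values()))
    return PipelineResult(rows, fragments, bms, bmcs, assignments, hap_map)


def run_pipeline(snvs: Sequence[SNV], bam, reference, transcripts,
                 options: PipelineOptions | None = None) -> list[ReportRow]:
    """Convenience wrapper returning only the report rows."""
    return run_analysis(snvs, bam, reference, transcripts, options).rows
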