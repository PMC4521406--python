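"""Per-fragment mutation-status evidence extracted from aligned reads.

Each sequenced DNA fragment (a read pair, or a single read) is reduced to a
status vector over the SNVs its reads overlap: at every site the fragment is
MUTANT (the aligned base is the alt allele), NON_MUTANT (wild-type or a third
allele) or UNKNOWN (no aligned base, or base quality below threshold). Mates
are merged: a known status beats UNKNOWN, agreement is kept once, and a pair
whose mates contradict each other at any SNV is excluded entirely as a likely
sequencing error. Co-observation of two alt alleles on one fragment is the
physical evidence that they lie on the same chromosome.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pysam

from .io_models import SNV

logger = logging.getLogger("mnvfix")


class SiteStatus(enum.Enum):
    """Mutation status of one fragment at one SNV site.

    Enum values double as the haplotype-string encoding.
    """

    MUTANT = "1"
    NON_MUTANT = "0"
    UNKNOWN = "-"


@dataclass
class FragmentEvidence:
    """Status vector of one fragment (keyed by read name) over the SNVs it
    touches. Only known statuses are stored; absence means UNKNOWN."""

    fragment_id: str
    statuses: dict[str, SiteStatus] = field(default_factory=dict)

    def status_at(self, uid: str) -> SiteStatus:
        return self.statuses.get(uid, SiteStatus.UNKNOWN)


def filter_alignment(aln: pysam.AlignedSegment, min_mapq: int = 20,
                     keep_duplicates: bool = False) -> bool:
    """Alignment-level gate: True to keep, False to drop.

    Drops unmapped, secondary, supplementary, QC-fail and (by default)
    duplicate-flagged records, and anything below the mapping-quality floor.
    """
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_qcfail:
        return False
    if aln.is_duplicate and not keep_duplicates:
        return False
    if aln.mapping_quality < min_mapq:
        return False
    return True


def classify_read_at_snv(aln: pysam.AlignedSegment, snv: SNV,
                         min_base_quality: int = 20) -> SiteStatus:
    """Classify one aligned read at one SNV site.

    The CIGAR is walked via the aligned pairs so insertions and soft clips do
    not shift the queried column; a deletion or reference skip spanning the
    site, or a base below the quality threshold, yields UNKNOWN. A base equal
    to the alt allele is MUTANT; any other aligned base (reference or third
    allele) is NON_MUTANT.
    """
    target = snv.pos - 1  # pysam is 0-based
    qpos = None
    for q, r in aln.get_aligned_pairs(matches_only=False):
        if r == target:
            qpos = q
            break
    if qpos is None:
        return SiteStatus.UNKNOWN
    quals = aln.query_qualities
    if quals is None or quals[qpos] < min_base_quality:
        return SiteStatus.UNKNOWN
    base = aln.query_sequence[qpos].upper()
    return SiteStatus.MUTANT if base == snv.alt else SiteStatus.NON_MUTANT


def collect_fragment_evidence(bam, snvs: Sequence[SNV],
                              min_base_quality: int = 20, min_mapq: int = 20,
                              keep_duplicates: bool = False) -> list[FragmentEvidence]:
    """Extract per-fragment status vectors over all SNV sites.

    Mate statuses are merged per SNV: (X, UNKNOWN) -> X and (X, X) -> X, while
    (MUTANT, NON_MUTANT) in either order marks the whole fragment discordant
    and removes it from all downstream analysis. Fragments whose merged vector
    is all-UNKNOWN are dropped, and each fragment contributes at most once per
    SNV, so downstream "read" counts are unique-fragment counts. Fragments
    whose mates map to different chromosomes are dropped at collect time.
    """
    own = False
    if not isinstance(bam, pysam.AlignmentFile):
        bam = pysam.AlignmentFile(str(bam), "rb")
        own = True
    try:
        if not bam.has_index():
            raise ValueError(f"BAM file {bam.filename!r} has no index")
        known = set(bam.references)
        frags: dict[str, dict[str, SiteStatus]] = {}
        discordant: set[str] = set()
        for snv in snvs:
            if snv.chrom not in known:
                raise ValueError(
                    f"chromosome {snv.chrom!r} (SNV {snv.uid}) absent from BAM header"
                )
            for aln in bam.fetch(snv.chrom, snv.pos - 1, snv.pos):
                if not filter_alignment(aln, min_mapq, keep_duplicates):
                    continue
                if (aln.is_paired and not aln.mate_is_unmapped
                        and aln.next_reference_id != aln.reference_id):
                    continue  # interchromosomal pair: cannot phase
                status = classify_read_at_snv(aln, snv, min_base_quality)
                if status is SiteStatus.UNKNOWN:
                    continue
                statuses = frags.setdefault(aln.query_name, {})
                prev = statuses.get(snv.uid)
                if prev is not None and prev is not status:
                    discordant.add(aln.query_name)
                else:
                    statuses[snv.uid] = status
        if discordant:
            logger.info("excluded %d fragment(s) with discordant mate statuses",
                        len(discordant))
        return [
            FragmentEvidence(name, statuses)
            for name, statuses in sorted(frags.items())
            if name not in discordant and statuses
        ]
    finally:
        if own:
            bam.close()
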