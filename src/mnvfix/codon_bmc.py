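"""Codon assignment and Blocks of Mutations within Codon (BMC).

Per-SNV annotation goes wrong exactly when two phased SNVs hit the same
protein codon, so within each BM a second layer of edges joins SNVs that
share a (transcript, codon) pair; the connected components of that layer are
the BMCs — the units of joint re-annotation. Annotation is deliberately
limited to one codon at a time: cross-codon joint effects are out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .block_detection import BlockOfMutations
from .io_models import SNV, TranscriptModel


@dataclass(frozen=True)
class CodonAssignment:
    """Placement of one SNV inside one codon of one transcript.

    ``codon_positions`` are the three genomic coordinates of the codon in
    transcript orientation (position-in-codon 1..3); they may be
    non-contiguous when the codon spans a splice junction. On the minus
    strand, position-in-codon decreases as the genomic coordinate increases.
    """

    snv_uid: str
    transcript_id: str
    gene: str
    strand: str
    codon_index: int  # 1-based amino-acid position
    codon_positions: tuple[int, int, int]
    position_in_codon: int  # 1..3, transcript orientation

    def __post_init__(self) -> None:
        if len(self.codon_positions) != 3:
            raise ValueError("a codon has exactly 3 genomic positions")


@dataclass
class BMC:
    """SNVs of one BM that share a codon under at least one transcript.

    ``transcripts`` lists every transcript supporting at least one internal
    codon-overlap edge; ``shared_codon`` maps the subset of transcripts under
    which ALL members sit in one codon to that codon index — only those can
    carry a joint annotation.
    """

    bm_id: str
    snvs: list[str]  # genomic order
    transcripts: list[str]
    shared_codon: dict[str, int]

    @property
    def bmc_id(self) -> str:
        return ";".join(self.snvs)


def assign_codons(snv: SNV, transcripts: Iterable[TranscriptModel]) -> list[CodonAssignment]:
    """One CodonAssignment per transcript whose CDS contains the SNV.

    SNVs outside every CDS return an empty list; they can still be BM members
    but never BMC members.
    """
    out: list[CodonAssignment] = []
    for t in transcripts:
        if t.chrom != snv.chrom:
            continue
        offset = t.cds_offset(snv.pos)
        if offset is None:
            continue
        codon_index = offset // 3 + 1
        out.append(CodonAssignment(
            snv_uid=snv.uid,
            transcript_id=t.transcript_id,
            gene=t.gene,
            strand=t.strand,
            codon_index=codon_index,
            codon_positions=t.codon_genomic_positions(codon_index),
            position_in_codon=offset % 3 + 1,
        ))
    return out


def find_bmcs(bm: BlockOfMutations, assignments: Sequence[CodonAssignment]) -> list[BMC]:
    """Connected components of size >= 2 under codon-overlap edges inside a BM.

    A second-layer edge joins two BM members iff some transcript places both
    in the same codon. Each BMC records every transcript supporting at least
    one of its internal edges, and separately the transcripts under which all
    its members share one codon.
    """
    keys: dict[str, set[tuple[str, int]]] = {uid: set() for uid in bm.snvs}
    for a in assignments:
        if a.snv_uid in keys:
            keys[a.snv_uid].add((a.transcript_id, a.codon_index))

    index = {uid: i for i, uid in enumerate(bm.snvs)}
    adjacency: dict[str, set[str]] = {uid: set() for uid in bm.snvs}
    edge_transcripts: dict[str, set[str]] = {uid: set() for uid in bm.snvs}
    for a, b in combinations(bm.snvs, 2):
        shared = keys[a] & keys[b]
        if shared:
            adjacency[a].add(b)
            adjacency[b].add(a)
            tids = {tid for tid, _ in shared}
            edge_transcripts[a] |= tids
            edge_transcripts[b] |= tids

    seen: set[str] = set()
    bmcs: list[BMC] = []
    for start in bm.snvs:
        if start in seen or not adjacency[start]:
            continue
        stack = [start]
        component: set[str] = set()
        while stack:
            uid = stack.pop()
            if uid in seen:
                continue
            seen.add(uid)
            component.add(uid)
            stack.extend(adjacency[uid] - seen)
        members = sorted(component, key=index.__getitem__)
        transcripts = sorted(set().union(*(edge_transcripts[u] for u in members)))
        shared_codon: dict[str, int] = {}
        common = set.intersection(*(keys[u] for u in members))
        for tid, ci in sorted(common):
            shared_codon[tid] = ci
        bmcs.append(BMC(bm.bm_id, members, transcripts, shared_codon))
    return bmcs
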