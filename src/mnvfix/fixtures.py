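"""Synthetic, self-consistent test worlds: reference FASTA, CDS model, SNV
list and phased paired-end BAM, generated deterministically from a seed.

A FixtureSpec states the study conditions directly: which SNVs exist, which
codons they hit, and how many fragments exhibit each haplotype status string.
The generator lays out read pairs so that each configured fragment's mates
jointly cover exactly the SNVs its status string constrains; '-' positions
are either left uncovered or, when they unavoidably fall inside a mate's
span, masked below the base-quality threshold, so the pipeline sees UNKNOWN
either way. Reads reproduce the configured alleles exactly and reference
elsewhere — no sequencing-error model beyond the two knobs of add_noise.

The ``table1`` preset rebuilds the four dinucleotide-variant codon contexts
(HIVEP1 P433 / CCT, TP53 E285 / GAG on the minus strand, CDC5L A316 / GCG,
ZNF407 L1973 / TTA) at small coordinates, preserving the codon indices so
the amino-acid change strings are the published ones.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import pysam
from Bio.Seq import Seq

from .io_models import SNV, TranscriptModel, chrom_sort_key

STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_LOW_QUAL = 2  # below any sensible threshold: reads as UNKNOWN


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic test world.

    ``haplotype_config`` maps a status string over ``snvs`` (genomic order;
    '1' mutant / '0' non-mutant / '-' not asserted) to the number of
    fragments carrying that pattern.
    """

    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    snvs: list[SNV]
    haplotype_config: dict[str, int]
    read_length: int = 100
    insert_size: int = 250
    base_quality: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        self.snvs = sorted(self.snvs, key=lambda s: s.sort_key)
        for snv in self.snvs:
            contig = self.reference.get(snv.chrom)
            if contig is None or snv.pos > len(contig):
                raise FixtureError(f"SNV {snv.uid} outside the reference")
            if contig[snv.pos - 1].upper() != snv.ref:
                raise FixtureError(
                    f"SNV {snv.uid}: reference carries {contig[snv.pos - 1]!r}")
        for status, count in self.haplotype_config.items():
            if len(status) != len(self.snvs):
                raise FixtureError(
                    f"status {status!r} has length {len(status)}, "
                    f"but there are {len(self.snvs)} SNVs")
            known = {self.snvs[i].chrom for i, c in enumerate(status) if c != "-"}
            if len(known) != 1:
                raise FixtureError(
                    f"status {status!r} must constrain SNVs on exactly one contig")
            if count < 1:
                raise FixtureError(f"status {status!r}: count must be >= 1")


@dataclass
class Fixture:
    """Paths of one generated test world plus the spec that produced it."""

    reference_fasta: Path
    cds_table: Path
    snv_table: Path
    bam: Path
    spec: FixtureSpec


def generate_fixture(spec: FixtureSpec, outdir) -> Fixture:
    """Materialize a FixtureSpec as FASTA(+.fai), CDS table, SNV TSV and a
    coordinate-sorted indexed BAM. Deterministic given the spec's seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = sorted(spec.reference, key=chrom_sort_key)

    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = spec.reference[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(ref_path))

    cds_path = outdir / "cds_model.tsv"
    with open(cds_path, "w") as fh:
        for t in spec.transcripts:
            for s, e in t.cds_intervals:
                fh.write(f"{t.chrom}\t{s}\t{e}\t{t.strand}\t{t.transcript_id}\t{t.gene}\n")

    snv_path = outdir / "snvs.tsv"
    with open(snv_path, "w") as fh:
        for snv in spec.snvs:
            fh.write(f"{snv.chrom}\t{snv.pos}\t{snv.ref}\t{snv.alt}\n")

    rng = random.Random(spec.seed)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(spec.reference[name])} for name in contigs],
    }
    segments = []
    counter = 0
    for status in sorted(spec.haplotype_config):
        for _ in range(spec.haplotype_config[status]):
            segments.extend(_fragment_pair(spec, status, f"frag{counter:05d}", rng, header))
            counter += 1
    bam_path = outdir / "reads.bam"
    _write_sorted_bam(bam_path, header, segments)
    return Fixture(ref_path, cds_path, snv_path, bam_path, spec)


def add_noise(fixture: Fixture, discordant_pair_fraction: float = 0.0,
              low_quality_fraction: float = 0.0, seed: int = 0,
              outdir=None, at_snvs: Sequence[SNV] | None = None) -> Fixture:
    """Perturb a fixture's BAM to exercise the pipeline's exclusion rules.

    ``discordant_pair_fraction`` injects that fraction (of the existing
    fragment count, rounded) of NEW fragments whose mates contradict each
    other at an SNV — each must be excluded downstream, leaving the original
    haplotype counts untouched. ``low_quality_fraction`` drops the base
    quality below threshold at SNV columns (restricted to ``at_snvs`` if
    given) for that fraction of existing fragments, turning their statuses
    there into '-'. Both fractions 0 reproduce the BAM byte-identically.
    """
    if not 0 <= discordant_pair_fraction <= 1 or not 0 <= low_quality_fraction <= 1:
        raise FixtureError("noise fractions must lie in [0, 1]")
    spec = fixture.spec
    outdir = Path(outdir) if outdir is not None else fixture.bam.parent / "noisy"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    with pysam.AlignmentFile(str(fixture.bam), "rb") as bam:
        header = bam.header.to_dict()
        segments = list(bam)
    qnames = sorted({s.query_name for s in segments})

    n_low = round(low_quality_fraction * len(qnames))
    chosen = set(rng.sample(qnames, n_low)) if n_low else set()
    targets = list(at_snvs) if at_snvs is not None else list(spec.snvs)
    if chosen:
        by_chrom: dict[str, list[SNV]] = {}
        for snv in targets:
            by_chrom.setdefault(snv.chrom, []).append(snv)
        for seg in segments:
            if seg.query_name not in chosen:
                continue
            quals = list(seg.query_qualities)
            touched = False
            for snv in by_chrom.get(seg.reference_name, ()):
                for q, r in seg.get_aligned_pairs(matches_only=True):
                    if r == snv.pos - 1:
                        quals[q] = _LOW_QUAL
                        touched = True
            if touched:
                seg.query_qualities = quals

    n_disc = round(discordant_pair_fraction * len(qnames))
    head = pysam.AlignmentHeader.from_dict(header)
    for i in range(n_disc):
        snv = spec.snvs[i % len(spec.snvs)]
        segments.extend(_discordant_pair(spec, snv, f"disc{i:05d}", head))

    bam_path = outdir / "reads.bam"
    _write_sorted_bam(bam_path, header, segments)
    return replace_bam(fixture, bam_path)


def replace_bam(fixture: Fixture, bam_path: Path) -> Fixture:
    return Fixture(fixture.reference_fasta, fixture.cds_table,
                   fixture.snv_table, bam_path, fixture.spec)


# ---------------------------------------------------------------------------
# read layout


def _fragment_pair(spec: FixtureSpec, status: str, name: str,
                   rng: random.Random, header: dict) -> list[pysam.AlignedSegment]:
    known = [spec.snvs[i] for i, c in enumerate(status) if c != "-"]
    chrom = known[0].chrom
    contig_len = len(spec.reference[chrom])
    L = spec.read_length
    first, last = known[0].pos, known[-1].pos
    a = max(1, min(first - 15 - rng.randint(0, 10), contig_len - L + 1))
    b_end = min(contig_len, last + 15 + rng.randint(0, 10))
    b = max(a, b_end - L + 1)
    covered = set(range(a, a + L)) | set(range(b, b + L))
    missing = [s.uid for s in known if s.pos not in covered]
    if missing:
        raise FixtureError(
            f"status {status!r}: SNVs {missing} not coverable by one read pair "
            f"(read_length={L}); widen the layout or split the status")
    head = pysam.AlignmentHeader.from_dict(header)
    tlen = b + L - a
    r1 = _mate(spec, status, chrom, a, name, 99, b, tlen, head)
    r2 = _mate(spec, status, chrom, b, name, 147, a, -tlen, head)
    return [r1, r2]


def _mate(spec: FixtureSpec, status: str, chrom: str, start: int, name: str,
          flag: int, mate_start: int, tlen: int,
          head: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    L = spec.read_length
    seq = list(spec.reference[chrom][start - 1 : start - 1 + L].upper())
    quals = [spec.base_quality] * L
    for snv, st in zip(spec.snvs, status):
        if snv.chrom != chrom or not start <= snv.pos < start + L:
            continue
        i = snv.pos - start
        if st == "1":
            seq[i] = snv.alt
        elif st == "-":
            quals[i] = _LOW_QUAL
    seg = pysam.AlignedSegment(head)
    seg.query_name = name
    seg.flag = flag
    seg.reference_id = head.get_tid(chrom)
    seg.reference_start = start - 1
    seg.mapping_quality = 60
    seg.cigartuples = [(0, L)]
    seg.next_reference_id = seg.reference_id
    seg.next_reference_start = mate_start - 1
    seg.template_length = tlen
    seg.query_sequence = "".join(seq)
    seg.query_qualities = quals
    return seg


def _discordant_pair(spec: FixtureSpec, snv: SNV, name: str,
                     head: pysam.AlignmentHeader) -> list[pysam.AlignedSegment]:
    """A read pair whose mates disagree at ``snv``: mate 1 carries the alt,
    mate 2 the reference base. The merge step must drop it entirely."""
    L = spec.read_length
    contig_len = len(spec.reference[snv.chrom])
    a = max(1, min(snv.pos - 60, contig_len - L + 1))
    b = max(1, min(snv.pos - 40, contig_len - L + 1))
    tlen = b + L - a
    out = []
    for start, flag, mate_start, t, mutant in (
        (a, 99, b, tlen, True),
        (b, 147, a, -tlen, False),
    ):
        seq = list(spec.reference[snv.chrom][start - 1 : start - 1 + L].upper())
        if mutant:
            seq[snv.pos - start] = snv.alt
        seg = pysam.AlignedSegment(head)
        seg.query_name = name
        seg.flag = flag
        seg.reference_id = head.get_tid(snv.chrom)
        seg.reference_start = start - 1
        seg.mapping_quality = 60
        seg.cigartuples = [(0, L)]
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = mate_start - 1
        seg.template_length = t
        seg.query_sequence = "".join(seq)
        seg.query_qualities = [spec.base_quality] * L
        out.append(seg)
    return out


def _write_sorted_bam(path: Path, header: dict, segments) -> None:
    # sorted here rather than via samtools sort: the latter's @PG line embeds
    # temp paths and would break byte-level reproducibility
    ordered = sorted(segments, key=lambda s: (s.reference_id, s.reference_start,
                                              s.query_name, s.flag))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for seg in ordered:
            out.write(seg)
    pysam.index(str(path))


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_seq(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _stop_free_cds(n_codons: int, rng: random.Random,
                   fixed: dict[int, str] | None = None) -> str:
    """A CDS of n_codons ending in TAA with no internal stop; ``fixed`` pins
    specific codons by 1-based index."""
    codons = [rng.choice(_SAFE_CODONS) for _ in range(n_codons)]
    codons[-1] = "TAA"
    for ci, codon in (fixed or {}).items():
        if not 1 <= ci < n_codons:
            raise FixtureError(f"fixed codon index {ci} out of range")
        if codon in STOP_CODONS:
            raise FixtureError(f"fixed codon {codon} is a stop codon")
        codons[ci - 1] = codon
    return "".join(codons)


def _place(length: int, rng: random.Random, pieces: dict[int, str]) -> str:
    """Random contig of ``length`` with ``pieces`` written at 1-based starts."""
    arr = list(_random_seq(length, rng))
    for start, seq in pieces.items():
        if start < 1 or start + len(seq) - 1 > length:
            raise FixtureError("piece outside contig")
        arr[start - 1 : start - 1 + len(seq)] = seq
    return "".join(arr)


# ---------------------------------------------------------------------------
# presets


def table1_spec(seed: int = 0) -> FixtureSpec:
    """Four dinucleotide-variant loci with the published codon contexts.

    Codon indices (433, 285, 316, 1973) are preserved so change strings come
    out as published; coordinates are small synthetic stand-ins, so uids
    differ from the original genomic positions.
    """
    rng = random.Random(seed)
    hivep1 = _stop_free_cds(435, rng, {433: "CCT"})
    cdc5l = _stop_free_cds(318, rng, {316: "GCG"})
    tp53 = _stop_free_cds(287, rng, {285: "GAG"})
    znf407 = _stop_free_cds(1975, rng, {1973: "TTA"})
    reference = {
        "chr6": _place(2600, rng, {101: hivep1, 1501: cdc5l}),
        "chr17": _place(1200, rng, {201: str(Seq(tp53).reverse_complement())}),
        "chr18": _place(6200, rng, {101: znf407}),
    }
    transcripts = [
        TranscriptModel("NM_002114", "HIVEP1", "chr6", "+", [(101, 1405)]),
        TranscriptModel("NM_001253", "CDC5L", "chr6", "+", [(1501, 2454)]),
        TranscriptModel("NM_000546", "TP53", "chr17", "-", [(201, 1061)]),
        TranscriptModel("NM_017757", "ZNF407", "chr18", "+", [(101, 6025)]),
    ]
    snvs = [
        SNV("chr6", 1397, "C", "G"),   # HIVEP1 codon 433 pos 1
        SNV("chr6", 1398, "C", "G"),   # HIVEP1 codon 433 pos 2
        SNV("chr6", 2447, "C", "G"),   # CDC5L codon 316 pos 2
        SNV("chr6", 2448, "G", "C"),   # CDC5L codon 316 pos 3
        SNV("chr17", 208, "T", "A"),   # TP53 codon 285 pos 2 (minus strand)
        SNV("chr17", 209, "C", "G"),   # TP53 codon 285 pos 1
        SNV("chr18", 6017, "T", "A"),  # ZNF407 codon 1973 pos 1
        SNV("chr18", 6018, "T", "A"),  # ZNF407 codon 1973 pos 2
    ]
    haplotype_config = {
        "11------": 21, "00------": 19,  # HIVEP1
        "--11----": 17, "--00----": 22,  # CDC5L
        "----11--": 30, "----00--": 28,  # TP53
        "------11": 16, "------00": 20,  # ZNF407
    }
    return FixtureSpec(reference, transcripts, snvs, haplotype_config, seed=seed)


def fig1_spec(phased: bool, seed: int = 0) -> FixtureSpec:
    """Two SNVs inside one codon (OR6Y1-style codon 252, GTA) at codon
    positions 1 and 3: on shared fragments when ``phased`` (a true MNV, joint
    codon ATG), on disjoint fragments otherwise (two chromosomes, per-SNV
    annotations V252I and V252V stand)."""
    rng = random.Random(seed)
    cds = _stop_free_cds(254, rng, {252: "GTA"})
    reference = {"chr1": _place(1000, rng, {101: cds})}
    transcripts = [TranscriptModel("NM_001005189", "OR6Y1", "chr1", "+", [(101, 862)])]
    snvs = [SNV("chr1", 854, "G", "A"), SNV("chr1", 856, "A", "G")]
    config = {"11": 25, "00": 25} if phased else {"10": 15, "01": 15}
    return FixtureSpec(reference, transcripts, snvs, config, seed=seed)


def kataegis_like_spec(seed: int = 0) -> FixtureSpec:
    """One 6-SNV chain (spacing 40 bp, fragments linking adjacent pairs):
    a single large BM with zero BMCs, for BM-size testing only."""
    rng = random.Random(seed)
    cds = _stop_free_cds(20, rng)
    reference = {"chr2": _place(1200, rng, {701: cds})}
    transcripts = [TranscriptModel("NM_900001", "KTG1", "chr2", "+", [(701, 760)])]
    positions = [301, 341, 381, 421, 461, 501]
    snvs = []
    for pos in positions:
        ref = reference["chr2"][pos - 1].upper()
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        snvs.append(SNV("chr2", pos, ref, alt))
    config = {}
    for i in range(5):
        status = "-" * i + "11" + "-" * (4 - i)
        config[status] = 10
    return FixtureSpec(reference, transcripts, snvs, config, seed=seed)


PRESETS: dict[str, Callable[[int], FixtureSpec]] = {
    "table1": table1_spec,
    "fig1a": lambda seed=0: fig1_spec(True, seed),
    "fig1b": lambda seed=0: fig1_spec(False, seed),
    "kataegis-like": kataegis_like_spec,
}
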