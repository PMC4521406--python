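"""Boundary I/O: SNV lists, reference access, transcript/CDS models, reports.

All genomic coordinates at this boundary are 1-based inclusive. Internal
0-based arithmetic (e.g. when talking to pysam) is a private detail of the
individual functions.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pysam
from Bio.Seq import Seq

logger = logging.getLogger("mnvfix")

BASES = frozenset("ACGT")
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_UID_RE = re.compile(r"^(?P<chrom>.+)\.(?P<pos>\d+)\.(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_CHROM_NUM_RE = re.compile(r"^(\D*?)(\d+)$")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering for chromosome names: chr2 < chr10 < chrX."""
    m = _CHROM_NUM_RE.match(chrom)
    if m:
        return (m.group(1).lower(), 0, int(m.group(2)), chrom)
    return (chrom.lower(), 1, 0, chrom)


@dataclass(frozen=True)
class SNV:
    """One called single-nucleotide variant; the vertex of the mutation graph.

    Only substitutions of a single base are representable: this tool corrects
    SNV calls, so indels are rejected at parse time, not here.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"alleles must be single bases in ACGT: {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def uid(self) -> str:
        return f"{self.chrom}.{self.pos}.{self.ref}>{self.alt}"

    @property
    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


def snv_from_uid(uid: str) -> SNV:
    m = _UID_RE.match(uid)
    if m is None:
        raise ValueError(f"not a valid SNV uid: {uid!r}")
    return SNV(m.group("chrom"), int(m.group("pos")), m.group("ref"), m.group("alt"))


def fetch_ref(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference bases over a 1-based inclusive interval.

    ``reference`` may be a pysam.FastaFile (or anything with a 0-based
    ``fetch``) or a plain mapping of contig name to sequence string.
    """
    if hasattr(reference, "fetch"):
        seq = reference.fetch(chrom, start - 1, end)
    else:
        seq = reference[chrom][start - 1 : end]
    seq = seq.upper()
    if len(seq) != end - start + 1:
        raise ValueError(f"reference {chrom}:{start}-{end} out of bounds")
    return seq


# ---------------------------------------------------------------------------
# SNV lists


class SNVParseResult(NamedTuple):
    snvs: list[SNV]
    n_skipped: int


def parse_snv_list(path, dialect: str = "tsv") -> SNVParseResult:
    """Parse an SNV list, returning the SNVs plus the count of skipped records.

    Non-SNV records (indels, multi-base ref/alt) are skipped with a warning;
    malformed coordinates or alleles raise :class:`ParseError` naming the line.
    Duplicate (chrom, pos, alt) rows collapse to one vertex. Output is sorted
    by genomic position.
    """
    path = Path(path)
    if dialect == "tsv":
        raw, skipped = _parse_tsv(path)
    elif dialect == "vcf":
        raw, skipped = _parse_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not raw:
        raise ParseError(f"{path}: no SNV records found")
    seen: dict[tuple, SNV] = {}
    for snv in raw:
        seen.setdefault((snv.chrom, snv.pos, snv.alt), snv)
    snvs = sorted(seen.values(), key=lambda s: s.sort_key)
    if skipped:
        logger.warning("%s: skipped %d non-SNV record(s)", path.name, skipped)
    return SNVParseResult(snvs, skipped)


def read_snv_list(path, dialect: str = "tsv") -> list[SNV]:
    return parse_snv_list(path, dialect).snvs


def _parse_tsv(path: Path) -> tuple[list[SNV], int]:
    snvs: list[SNV] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            chrom, pos_s, ref, alt = fields[0], fields[1], fields[2].upper(), fields[3].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed coordinate {pos_s!r}") from None
            if len(ref) > 1 or len(alt) > 1:
                skipped += 1  # indel / multi-base substitution: not an SNV
                continue
            try:
                snvs.append(SNV(chrom, pos, ref, alt))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return snvs, skipped


def _parse_vcf(path: Path) -> tuple[list[SNV], int]:
    snvs: list[SNV] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if (
                    alt is None
                    or len(rec.ref or "") != 1
                    or len(alt) != 1
                    or rec.ref.upper() not in BASES
                    or alt.upper() not in BASES
                ):
                    skipped += 1
                    continue
                snvs.append(SNV(rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
    return snvs, skipped


# ---------------------------------------------------------------------------
# Transcript / CDS models


@dataclass
class TranscriptModel:
    """A coding transcript as an ordered set of genomic CDS intervals.

    ``cds_intervals`` are 1-based closed intervals in genomic order; their
    concatenation, read 5'->3' in transcript orientation (reverse-complemented
    on the minus strand), is the CDS. Total length must be divisible by 3.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    _positions: list[int] | None = field(default=None, repr=False, compare=False)
    _offsets: dict[int, int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        ivals = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping CDS intervals")
        self.cds_intervals = ivals
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def _build(self) -> None:
        positions: list[int] = []
        if self.strand == "+":
            for s, e in self.cds_intervals:
                positions.extend(range(s, e + 1))
        else:
            for s, e in reversed(self.cds_intervals):
                positions.extend(range(e, s - 1, -1))
        self._positions = positions
        self._offsets = {g: i for i, g in enumerate(positions)}

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the CDS (transcript
        orientation), or None if the position is non-coding."""
        if self._offsets is None:
            self._build()
        return self._offsets.get(pos)

    def codon_genomic_positions(self, codon_index: int) -> tuple[int, int, int]:
        """The three genomic coordinates of a codon, in transcript orientation
        (position-in-codon 1, 2, 3). Non-contiguous across splice junctions."""
        if self._positions is None:
            self._build()
        lo = (codon_index - 1) * 3
        trio = self._positions[lo : lo + 3]
        if len(trio) != 3:
            raise ValueError(f"{self.transcript_id}: codon {codon_index} out of range")
        return tuple(trio)

    def cds_sequence(self, reference) -> str:
        chunks = [fetch_ref(reference, self.chrom, s, e) for s, e in self.cds_intervals]
        seq = "".join(chunks)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def read_transcripts(path, reference=None) -> list[TranscriptModel]:
    """Load transcript CDS models from GFF3/GTF (CDS features) or from a
    simplified 6-column table (chrom, start, end, strand, transcript_id, gene).

    Transcripts whose CDS length is not divisible by 3, or whose first CDS
    feature has nonzero phase (partial CDS), are rejected with a warning.
    Strand mixing within one transcript is an error. If a reference accessor
    is given, each accepted CDS is translated and internal stop codons are
    reported as warnings only.
    """
    path = Path(path)
    fmt = _sniff_transcript_format(path)
    if fmt == "table":
        groups = _cds_groups_from_table(path)
    else:
        groups = _cds_groups_from_gff(path, fmt)

    models: list[TranscriptModel] = []
    for tid in sorted(groups):
        g = groups[tid]
        strands = {strand for _, _, strand, _ in g["feats"]}
        if len(strands) > 1:
            raise ParseError(f"{path}: transcript {tid} mixes strands {sorted(strands)}")
        strand = strands.pop()
        feats = sorted(g["feats"])
        first = feats[0] if strand == "+" else feats[-1]  # 5'-most in transcript orientation
        phase = first[3]
        if phase not in (None, ".", "0", 0):
            logger.warning("rejecting %s: first CDS phase %r (partial CDS)", tid, phase)
            continue
        intervals = [(s, e) for s, e, _, _ in feats]
        try:
            model = TranscriptModel(tid, g["gene"], g["chrom"], strand, intervals)
        except ValueError as exc:
            logger.warning("rejecting %s: %s", tid, exc)
            continue
        if reference is not None:
            peptide = str(Seq(model.cds_sequence(reference)).translate())
            if "*" in peptide[:-1]:
                logger.warning("%s: internal stop codon in translated CDS", tid)
        models.append(model)
    return models


def _sniff_transcript_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9:
                return "gtf" if 'transcript_id "' in fields[8] else "gff3"
            if len(fields) == 6:
                return "table"
            raise ParseError(f"{path}: unrecognized transcript model format")
    raise ParseError(f"{path}: empty transcript model file")


def _cds_groups_from_table(path: Path) -> dict[str, dict]:
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, strand, tid, gene = fields
            g = groups.setdefault(tid, {"gene": gene, "chrom": chrom, "feats": []})
            g["feats"].append((int(start), int(end), strand, "0"))
    return groups


def _cds_groups_from_gff(path: Path, fmt: str) -> dict[str, dict]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    groups: dict[str, dict] = {}
    for f in db.features_of_type("CDS", order_by="start"):
        attrs = f.attributes
        tid = _first_attr(attrs, "transcript_id", "Parent")
        if tid is None:
            raise ParseError(f"{path}: CDS feature at {f.seqid}:{f.start} lacks a transcript attribute")
        tid = tid.split(":")[-1]  # strip GFF3 "transcript:" prefixes
        gene = _first_attr(attrs, "gene", "gene_name", "gene_id", "Name") or tid
        g = groups.setdefault(tid, {"gene": gene, "chrom": f.seqid, "feats": []})
        if f.seqid != g["chrom"]:
            raise ParseError(f"{path}: transcript {tid} spans multiple contigs")
        g["feats"].append((f.start, f.end, f.strand, f.frame))
    return groups


def _first_attr(attrs, *names: str) -> str | None:
    for name in names:
        vals = attrs.get(name)
        if vals:
            return vals[0]
    return None


# ---------------------------------------------------------------------------
# Report


@dataclass
class ReportRow:
    """One haplotype of one BMC (or, in no-annotation mode, of one BM)."""

    bmc_id: str
    haplotype_index: int
    status_string: str
    read_count: int
    gene: str = ""
    transcript: str = ""
    amino_acid_change: str = ""


ANNOTATED_COLUMNS = ["bmc_id", "haplotype_index", "status", "read_count",
                     "gene", "transcript", "amino_acid_change"]
PHASE_COLUMNS = ANNOTATED_COLUMNS[:4]


def write_report(rows: Sequence[ReportRow], path, mode: str = "annotated") -> None:
    """Write the tab-separated report; one row per haplotype.

    Under ``no_annotation`` mode the three annotation columns are omitted so
    any external annotator can consume the phasing output directly.
    """
    if mode not in ("annotated", "no_annotation"):
        raise ValueError(f"unknown report mode {mode!r}")
    cols = ANNOTATED_COLUMNS if mode == "annotated" else PHASE_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fields = [row.bmc_id, str(row.haplotype_index), row.status_string,
                      str(row.read_count)]
            if mode == "annotated":
                fields += [row.gene, row.transcript, row.amino_acid_change]
            fh.write("\t".join(fields) + "\n")
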