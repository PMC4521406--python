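import pysam
import pytest

from mnvfix import (
    PipelineOptions,
    generate_fixture,
    read_snv_list,
    read_transcripts,
    run_analysis,
)
from mnvfix.fixtures import fig1_spec, table1_spec


@pytest.fixture(scope="session")
def table1_world(tmp_path_factory):
    return generate_fixture(table1_spec(seed=1), tmp_path_factory.mktemp("table1"))


@pytest.fixture(scope="session")
def fig1a_world(tmp_path_factory):
    return generate_fixture(fig1_spec(True, seed=2), tmp_path_factory.mktemp("fig1a"))


@pytest.fixture(scope="session")
def fig1b_world(tmp_path_factory):
    return generate_fixture(fig1_spec(False, seed=3), tmp_path_factory.mktemp("fig1b"))


@pytest.fixture
def run_world():
    """Run the full pipeline on a generated fixture; returns
    (snvs, transcripts, PipelineResult)."""

    def _run(fixture, options=None):
        snvs = read_snv_list(fixture.snv_table)
        with pysam.FastaFile(str(fixture.reference_fasta)) as ref:
            transcripts = read_transcripts(fixture.cds_table, ref)
            result = run_analysis(snvs, fixture.bam, ref, transcripts,
                                  options or PipelineOptions())
        return snvs, transcripts, result

    return _run


SMALL_HEADER = pysam.AlignmentHeader.from_dict({
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [{"SN": "chr1", "LN": 10000}, {"SN": "chr2", "LN": 10000}],
})


def make_segment(name="r1", chrom="chr1", start=101, seq=None, quals=None,
                 flag=0, mapq=60, cigar=None, length=50, header=SMALL_HEADER):
    """In-memory aligned read; ``start`` is 1-based."""
    if seq is None:
        seq = "A" * length
    if cigar is None:
        cigar = [(0, len(seq))]
    if quals is None:
        quals = [35] * len(seq)
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = flag
    seg.reference_id = header.get_tid(chrom)
    seg.reference_start = start - 1
    seg.mapping_quality = mapq
    seg.cigartuples = cigar
    seg.query_sequence = seq
    seg.query_qualities = quals
    if flag & 0x1 and not flag & 0x8:  # paired with mapped mate: same contig
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = seg.reference_start
    return seg
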