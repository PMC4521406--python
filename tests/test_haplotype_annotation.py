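import pytest

from mnvfix import (
    SNV,
    BlockSubstitution,
    FragmentEvidence,
    Haplotype,
    PipelineError,
    PipelineOptions,
    SiteStatus,
    TranscriptModel,
    annotate_haplotype,
    annotate_snv,
    assign_codons,
    build_block_substitution,
    enumerate_haplotypes,
    generate_fixture,
    run_analysis,
    write_report,
)
from mnvfix.codon_bmc import BMC
from mnvfix.fixtures import kataegis_like_spec

M, N, U = SiteStatus.MUTANT, SiteStatus.NON_MUTANT, SiteStatus.UNKNOWN

# plus-strand world: codon 2 of TX+ is GAG (E) at 104-106
PLUS_REF = {"chr1": "N" * 100 + "ATGGAGTAA" + "N" * 20}
TX_PLUS = TranscriptModel("TX+", "GENE", "chr1", "+", [(101, 109)])
P1 = SNV("chr1", 104, "G", "C")  # alone: CAG -> Q
P2 = SNV("chr1", 105, "A", "T")  # alone: GTG -> V

# the same locus mirrored onto the minus strand
MINUS_REF = {"chr1": "N" * 100 + "TTACTCCAT" + "N" * 20}
TX_MINUS = TranscriptModel("TX-", "GENE", "chr1", "-", [(101, 109)])
M1 = SNV("chr1", 105, "T", "A")
M2 = SNV("chr1", 106, "C", "G")


def bmc_for(snvs, transcript):
    assignments = [a for s in snvs for a in assign_codons(s, [transcript])]
    ci = assignments[0].codon_index
    return (
        BMC(";".join(s.uid for s in snvs), [s.uid for s in snvs],
            [transcript.transcript_id], {transcript.transcript_id: ci}),
        assignments,
    )


class TestEnumerate:
    BLOCK, _ = bmc_for([P1, P2], TX_PLUS)

    def frags(self):
        out = []
        for i in range(30):
            out.append(FragmentEvidence(f"a{i}", {P1.uid: M, P2.uid: M}))
        for i in range(28):
            out.append(FragmentEvidence(f"b{i}", {P1.uid: N, P2.uid: N}))
        out.append(FragmentEvidence("c0", {P1.uid: M}))
        out.append(FragmentEvidence("d0", {SNV("chr1", 999, "A", "C").uid: M}))
        return out

    def test_grouping_counts_and_order(self):
        haps = enumerate_haplotypes(self.BLOCK, self.frags())
        assert [(h.status_string, h.read_count) for h in haps] == [
            ("11", 30), ("00", 28), ("1-", 1)]

    def test_all_unknown_fragments_dropped(self):
        haps = enumerate_haplotypes(self.BLOCK, [
            FragmentEvidence("x", {SNV("chr1", 999, "A", "C").uid: M})])
        assert haps == []

    def test_tie_broken_all_mutant_first(self):
        frags = [FragmentEvidence("a", {P1.uid: M, P2.uid: M}),
                 FragmentEvidence("b", {P1.uid: N, P2.uid: N})]
        haps = enumerate_haplotypes(self.BLOCK, frags)
        assert [h.status_string for h in haps] == ["11", "00"]

    def test_read_count_conservation(self):
        frags = self.frags()
        haps = enumerate_haplotypes(self.BLOCK, frags)
        touching = sum(
            1 for f in frags
            if any(f.status_at(u) is not U for u in self.BLOCK.snvs))
        assert sum(h.read_count for h in haps) == touching


class TestBlockSubstitution:
    def test_adjacent_pair(self):
        bmc, _ = bmc_for([P1, P2], TX_PLUS)
        hap = Haplotype(bmc.bmc_id, "11", 5)
        bs = build_block_substitution(hap, bmc, PLUS_REF)
        assert (bs.start, bs.end, bs.ref_seq, bs.alt_seq) == (104, 105, "GA", "CT")

    def test_gap_base_stays_reference(self):
        s1, s3 = SNV("chr1", 104, "G", "C"), SNV("chr1", 106, "G", "T")
        bmc, _ = bmc_for([s1, s3], TX_PLUS)
        bs = build_block_substitution(Haplotype(bmc.bmc_id, "10", 1), bmc, PLUS_REF)
        assert (bs.ref_seq, bs.alt_seq) == ("GAG", "CAG")

    def test_identity_substitution(self):
        bmc, _ = bmc_for([P1, P2], TX_PLUS)
        bs = build_block_substitution(Haplotype(bmc.bmc_id, "00", 1), bmc, PLUS_REF)
        assert bs.ref_seq == bs.alt_seq

    def test_unknown_status_rejected(self):
        bmc, _ = bmc_for([P1, P2], TX_PLUS)
        with pytest.raises(ValueError):
            build_block_substitution(Haplotype(bmc.bmc_id, "1-", 1), bmc, PLUS_REF)

    def test_reference_mismatch_detected(self):
        bad = {"chr1": "N" * 100 + "ATGCAGTAA" + "N" * 20}  # 104 is C, not G
        bmc, _ = bmc_for([P1, P2], TX_PLUS)
        with pytest.raises(ValueError, match="mismatch"):
            build_block_substitution(Haplotype(bmc.bmc_id, "11", 1), bmc, bad)


class TestAnnotate:
    def test_joint_differs_from_both_marginals(self):
        bmc, assignments = bmc_for([P1, P2], TX_PLUS)
        bs = build_block_substitution(Haplotype(bmc.bmc_id, "11", 1), bmc, PLUS_REF)
        joint = annotate_haplotype(bs, assignments, PLUS_REF)
        assert joint.change_string == "E2L"
        assert joint.consequence == "missense"
        singles = {annotate_snv(s, a, PLUS_REF).change_string
                   for s, a in zip([P1, P2], assignments)}
        assert singles == {"E2Q", "E2V"}

    def test_identity_substitution_is_silent(self):
        bmc, assignments = bmc_for([P1, P2], TX_PLUS)
        bs = build_block_substitution(Haplotype(bmc.bmc_id, "00", 1), bmc, PLUS_REF)
        res = annotate_haplotype(bs, assignments, PLUS_REF)
        assert res.ref_aa == res.alt_aa == "E"
        assert res.consequence == "silent"

    def test_nonsense_rendered_with_star(self):
        # TTA codon: second-position T>A alone gives TAA = stop
        ref = {"chr1": "N" * 100 + "ATGTTATAA" + "N" * 20}
        s = SNV("chr1", 105, "T", "A")
        (a,) = assign_codons(s, [TX_PLUS])
        res = annotate_snv(s, a, ref)
        assert res.change_string == "L2*"
        assert res.consequence == "nonsense"

    def test_strand_symmetry(self):
        bmc_p, asg_p = bmc_for([P1, P2], TX_PLUS)
        bs_p = build_block_substitution(Haplotype(bmc_p.bmc_id, "11", 1), bmc_p, PLUS_REF)
        plus = annotate_haplotype(bs_p, asg_p, PLUS_REF)

        bmc_m, asg_m = bmc_for([M1, M2], TX_MINUS)
        bs_m = build_block_substitution(Haplotype(bmc_m.bmc_id, "11", 1), bmc_m, MINUS_REF)
        minus = annotate_haplotype(bs_m, asg_m, MINUS_REF)

        assert plus.change_string == minus.change_string == "E2L"
        assert plus.consequence == minus.consequence

    def test_single_mutant_haplotype_equals_per_snv_annotation(self):
        bmc, assignments = bmc_for([P1, P2], TX_PLUS)
        for status, snv, a in (("10", P1, assignments[0]), ("01", P2, assignments[1])):
            bs = build_block_substitution(Haplotype(bmc.bmc_id, status, 1), bmc, PLUS_REF)
            joint = annotate_haplotype(bs, assignments, PLUS_REF)
            single = annotate_snv(snv, a, PLUS_REF)
            assert joint.change_string == single.change_string

    def test_mismatched_assignments_rejected(self):
        _, assignments = bmc_for([P1, P2], TX_PLUS)
        other = assign_codons(SNV("chr1", 108, "A", "C"), [TX_PLUS])
        bs = BlockSubstitution("chr1", 104, 105, "GA", "CT")
        with pytest.raises(ValueError):
            annotate_haplotype(bs, assignments + other, PLUS_REF)


class TestPipeline:
    def test_empty_snv_list_errors_at_input_stage(self):
        with pytest.raises(PipelineError, match=r"\[input\]"):
            run_analysis([], None, PLUS_REF, [])

    def test_no_annotation_mode_exports_all_bms(self, tmp_path, run_world):
        fx = generate_fixture(kataegis_like_spec(seed=9), tmp_path)
        _, _, result = run_world(fx, PipelineOptions(mode="no_annotation"))
        assert len(result.bms) == 1
        assert len(result.bms[0].snvs) == 6
        assert result.bmcs == []
        assert result.rows  # phase rows exist even without any BMC
        assert all(r.amino_acid_change == "" for r in result.rows)
        assert all(len(r.status_string) == 6 for r in result.rows)

    def test_kataegis_chain_annotate_mode_has_no_bmc_rows(self, tmp_path, run_world):
        fx = generate_fixture(kataegis_like_spec(seed=9), tmp_path)
        _, _, result = run_world(fx)
        assert result.rows == []

    def test_conservation_over_bmcs(self, table1_world, run_world):
        _, _, result = run_world(table1_world)
        for bmc in result.bmcs:
            haps = result.haplotypes[bmc.bmc_id]
            touching = sum(
                1 for f in result.fragments
                if any(f.status_at(u) is not U for u in bmc.snvs))
            assert sum(h.read_count for h in haps) == touching

    def test_min_hap_reads_filters_rows(self, fig1a_world, run_world):
        _, _, result = run_world(fig1a_world, PipelineOptions(min_hap_reads=26))
        assert all(r.read_count >= 26 for r in result.rows)
        assert result.rows == []  # both haplotypes have 25 fragments

    def test_report_is_byte_identical_across_reruns(self, table1_world, run_world, tmp_path):
        outputs = []
        for i in range(2):
            _, _, result = run_world(table1_world)
            p = tmp_path / f"report{i}.tsv"
            write_report(result.rows, p, "annotated")
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]
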