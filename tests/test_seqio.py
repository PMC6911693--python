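"""FASTA I/O, global alignment (with exhaustive oracle) and region transfer."""

import numpy as np
import pytest

from pseudits.errors import AlignmentError, AnnotationError, FastaFormatError
from pseudits.seqio import (ItsRegions, Scoring, SequenceRecord,
                            annotate_regions, global_align, progressive_msa,
                            read_fasta, write_fasta)


def _score_alignment(ra, rb, sc: Scoring) -> float:
    """Score a gapped pair by direct scanning (independent of the DP)."""
    total = 0.0
    run = None  # which row the open gap is in
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            row = 0 if x == "-" else 1
            total += sc.gap_extend if run == row else sc.gap_open
            run = row
        else:
            run = None
            total += sc.match if x == y else sc.mismatch
    return total


def _all_alignments(a, b):
    """Enumerate every global alignment of two strings."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in _all_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in _all_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in _all_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.id == "x" and rec.residues == "ACGT"

    def test_multiline_and_case(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a\nac\ngt\n>b\nGGGG\n")
        recs = read_fasta(p)
        assert [r.residues for r in recs] == ["ACGT", "GGGG"]

    def test_bad_character_names_offender(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nAC!T\n")
        with pytest.raises(FastaFormatError, match="'a'"):
            read_fasta(p)

    def test_ambiguity_codes_rejected(self, tmp_path):
        p = tmp_path / "amb.fasta"
        p.write_text(">r\nACRT\n")
        with pytest.raises(FastaFormatError, match="'r'"):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FastaFormatError):
            read_fasta(p)

    def test_u_mapped_to_t(self, tmp_path):
        p = tmp_path / "rna.fasta"
        p.write_text(">r\nACGU\n")
        assert read_fasta(p)[0].residues == "ACGT"

    def test_round_trip(self, tmp_path):
        recs = [SequenceRecord(id="a", residues="ACGTACGT" * 20),
                SequenceRecord(id="b", residues="GGGGCCCC")]
        p = tmp_path / "rt.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == \
            [(r.id, r.residues) for r in recs]


class TestGlobalAlign:
    def test_identity(self):
        a = SequenceRecord(id="a", residues="ACGT")
        aln = global_align(a, SequenceRecord(id="b", residues="ACGT"))
        assert aln.records[0].residues == "ACGT"
        assert aln.records[1].residues == "ACGT"
        assert aln.score == 4.0

    def test_single_gap_opposite_c(self):
        aln = global_align(SequenceRecord(id="a", residues="ACGT"),
                           SequenceRecord(id="b", residues="AGT"),
                           Scoring(1, -1, -2, -1))
        assert aln.records[0].residues == "ACGT"
        assert aln.records[1].residues == "A-GT"
        assert aln.score == 1.0

    def test_all_mismatch_no_gaps(self):
        aln = global_align(SequenceRecord(id="a", residues="AAAA"),
                           SequenceRecord(id="b", residues="TTTT"))
        assert "-" not in aln.records[0].residues
        assert "-" not in aln.records[1].residues
        assert aln.score == -4.0

    def test_gap_removal_recovers_inputs(self, rng):
        for _ in range(20):
            sa = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            sb = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            aln = global_align(SequenceRecord(id="a", residues=sa),
                               SequenceRecord(id="b", residues=sb))
            assert aln.records[0].residues.replace("-", "") == sa
            assert aln.records[1].residues.replace("-", "") == sb

    def test_score_equals_bruteforce_max(self, rng):
        """DP optimum equals exhaustive enumeration for short sequences."""
        sc = Scoring(1, -1, -4, -1)
        for _ in range(15):
            sa = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            sb = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            aln = global_align(SequenceRecord(id="a", residues=sa),
                               SequenceRecord(id="b", residues=sb), sc)
            brute = max(_score_alignment(ra, rb, sc)
                        for ra, rb in _all_alignments(sa, sb))
            assert aln.score == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(FastaFormatError):
            SequenceRecord(id="e", residues="")


class TestProgressiveMsa:
    def test_identical_records_no_gaps(self):
        recs = [SequenceRecord(id=f"s{i}", residues="ACGTACGT")
                for i in range(3)]
        aln = progressive_msa(recs)
        assert all(r.residues == "ACGTACGT" for r in aln.records)

    def test_shared_deletion_column(self):
        recs = [SequenceRecord(id="a", residues="ACGT"),
                SequenceRecord(id="b", residues="ACGT"),
                SequenceRecord(id="c", residues="ACT")]
        aln = progressive_msa(recs)
        assert aln.length == 4
        assert aln.row("c").residues.count("-") == 1
        assert aln.row("a").residues == "ACGT"

    def test_order_invariance(self, rng):
        recs = [SequenceRecord(id=f"s{i}",
                               residues="".join(rng.choice(list("ACGT"),
                                                           size=30)))
                for i in range(5)]
        aln1 = progressive_msa(recs)
        aln2 = progressive_msa(recs[::-1])
        for r in recs:
            assert aln1.row(r.id).residues == aln2.row(r.id).residues

    def test_needs_two_records(self):
        with pytest.raises(AlignmentError):
            progressive_msa([SequenceRecord(id="a", residues="ACGT")])

    def test_column_count_at_least_longest(self, rng):
        recs = [SequenceRecord(id=f"s{i}",
                               residues="".join(rng.choice(list("ACGT"),
                                                           size=n)))
                for i, n in enumerate([25, 30, 28])]
        aln = progressive_msa(recs)
        assert aln.length >= 30


class TestAnnotateRegions:
    def test_identity(self, ancestors):
        short_ref, _, regions = ancestors
        assert annotate_regions(short_ref, short_ref, regions) == regions

    def test_insertion_inside_its1(self, ancestors):
        short_ref, _, regions = ancestors
        pos = 50  # inside ITS1
        mutant = SequenceRecord(
            id="ins", residues=short_ref.residues[:pos] + "CGTATACAATGCG"
            + short_ref.residues[pos:])
        got = annotate_regions(mutant, short_ref, regions)
        assert got.its1[1] - got.its1[0] == regions.its1[1] - regions.its1[0] + 13
        assert got.r58s[1] - got.r58s[0] == regions.r58s[1] - regions.r58s[0]
        assert got.its2[1] - got.its2[0] == regions.its2[1] - regions.its2[0]

    def test_truncation_fails(self, ancestors):
        short_ref, _, regions = ancestors
        stump = SequenceRecord(id="t",
                               residues=short_ref.residues[regions.r58s[0]:])
        with pytest.raises(AnnotationError, match="annotation failed"):
            annotate_regions(stump, short_ref, regions)

    def test_idempotent(self, ancestors):
        short_ref, long_ref, regions = ancestors
        first = annotate_regions(long_ref, short_ref, regions)
        again = annotate_regions(long_ref, long_ref, first)
        assert again == first


def test_regions_ordering_enforced():
    with pytest.raises(ValueError):
        ItsRegions(its1=(0, 100), r58s=(90, 200), its2=(200, 300))
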