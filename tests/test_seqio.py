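"""Adapter trimming, exact mapping, anchoring, and file round-trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirnasort.seqio import (
    DEFAULT_ADAPTER,
    AnchoredHit,
    ParseError,
    ReferenceSet,
    SmallRNARead,
    anchored_filter,
    map_reads_bulk,
    map_to_references,
    read_cluster_references,
    read_small_rnas,
    to_rna,
    trim_adapter,
    write_small_rnas_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestNormalization:
    def test_u_and_t_are_interchangeable(self):
        assert SmallRNARead("r", "ACGU").sequence == "ACGT"
        assert SmallRNARead("r", "acgt").sequence == "ACGT"
        assert to_rna("ACGT") == "ACGU"

    @pytest.mark.parametrize("bad", ["", "ACGN", "ACG-T", "1234"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ParseError):
            SmallRNARead("r", bad)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ParseError):
            SmallRNARead("r", "ACGT", count=0)


class TestTrimAdapter:
    def test_exact_adapter_suffix_removed(self):
        read = SmallRNARead("r", "ACGTACGTACGTACGT" + "TGGAATTCTCGG")
        res = trim_adapter(read, DEFAULT_ADAPTER)
        assert res.trimmed and res.read.sequence == "ACGTACGTACGTACGT"

    def test_no_adapter_unchanged(self):
        read = SmallRNARead("r", "ACGTACGTACGTACGT")
        res = trim_adapter(read, DEFAULT_ADAPTER)
        assert not res.trimmed and res.read.sequence == read.sequence

    def test_overlap_below_threshold_unchanged(self):
        read = SmallRNARead("r", "ACGTACGTACGTACGT" + DEFAULT_ADAPTER[:5])
        res = trim_adapter(read, DEFAULT_ADAPTER, min_overlap=8)
        assert not res.trimmed and res.read.sequence == read.sequence

    def test_internal_adapter_removes_everything_three_prime(self):
        read = SmallRNARead("r", "ACGTACGTACGTACGT" + DEFAULT_ADAPTER + "AAAACCCC")
        res = trim_adapter(read, DEFAULT_ADAPTER)
        assert res.trimmed and res.read.sequence == "ACGTACGTACGTACGT"

    def test_short_trimmed_read_discarded(self):
        read = SmallRNARead("r", "ACGTACG" + DEFAULT_ADAPTER[:10])
        res = trim_adapter(read, DEFAULT_ADAPTER, min_length=15)
        assert res.trimmed and res.read is None

    @settings(max_examples=200, derandomize=True)
    @given(body=st.text(alphabet="ACGT", min_size=15, max_size=40),
           tail=st.integers(min_value=0, max_value=21))
    def test_idempotent(self, body, tail):
        read = SmallRNARead("r", body + DEFAULT_ADAPTER[:tail])
        once = trim_adapter(read, DEFAULT_ADAPTER)
        if once.read is None:
            return
        twice = trim_adapter(once.read, DEFAULT_ADAPTER)
        assert not twice.trimmed
        assert twice.read.sequence == once.read.sequence


def naive_scan(read: SmallRNARead, refs: ReferenceSet):
    """Independent all-window scan oracle for exact sense-strand mapping."""
    hits = []
    for rid in sorted(refs.entries):
        ref = refs.entries[rid]
        for off in range(len(ref) - len(read.sequence) + 1):
            if ref[off : off + len(read.sequence)] == read.sequence:
                hits.append((rid, off))
    return hits


class TestMapping:
    def test_multiple_occurrences_enumerated(self):
        hits = map_to_references(SmallRNARead("r", "ACGT"), ReferenceSet({"R1": "ACGTACGT"}))
        assert [(h.reference_id, h.offset) for h in hits] == [("R1", 0), ("R1", 4)]

    def test_read_longer_than_references(self):
        hits = map_to_references(SmallRNARead("r", "A" * 50), ReferenceSet({"R1": "AAAA"}))
        assert hits == []

    def test_order_by_reference_then_offset(self):
        hits = map_to_references(
            SmallRNARead("r", "ACGT"), ReferenceSet({"R1": "TTACGTT", "R2": "ACGTTT"})
        )
        assert [(h.reference_id, h.offset) for h in hits] == [("R1", 2), ("R2", 0)]

    def test_agrees_with_naive_scan_oracle(self):
        rng = random.Random(7)
        refs = ReferenceSet(
            {f"R{i:02d}": "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 100)))
             for i in range(100)}
        )
        for _ in range(100):
            read = SmallRNARead("r", "".join(rng.choice("ACG") for _ in range(rng.randint(2, 6))))
            got = [(h.reference_id, h.offset) for h in map_to_references(read, refs)]
            assert got == naive_scan(read, refs)

    def test_bulk_mapper_agrees_with_per_read_op(self):
        rng = random.Random(11)
        refs = ReferenceSet(
            {f"R{i}": "".join(rng.choice("ACGT") for _ in range(60)) for i in range(30)}
        )
        reads = [
            SmallRNARead(f"r{j}", "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 8))))
            for j in range(50)
        ]
        bulk = map_reads_bulk(reads, refs)
        expected = [(r, h) for r in reads for h in map_to_references(r, refs)]
        assert [(r.id, h.reference_id, h.offset) for r, h in bulk] == [
            (r.id, h.reference_id, h.offset) for r, h in expected
        ]


class TestAnchoredFilter:
    def test_keeps_only_offset_zero(self):
        hits = [AnchoredHit("r", "R1", 0), AnchoredHit("r", "R1", 4)]
        out = anchored_filter(hits)
        assert out == [hits[0]] and out[0].anchored

    def test_no_anchored_hit(self):
        assert anchored_filter([AnchoredHit("r", "R1", 3)]) == []

    def test_all_anchored_identity(self):
        hits = [AnchoredHit("a", "R1", 0), AnchoredHit("b", "R2", 0)]
        assert anchored_filter(hits) == hits

    @settings(max_examples=100, derandomize=True)
    @given(offs=st.lists(st.integers(min_value=0, max_value=5), max_size=20))
    def test_subset_property(self, offs):
        hits = [AnchoredHit("r", "R", o) for o in offs]
        out = anchored_filter(hits)
        assert all(h in hits and h.offset == 0 for h in out)


class TestFiles:
    def test_fasta_roundtrip_with_collapsed_counts(self, tmp_path):
        reads = [SmallRNARead("a", "ACGTACGTACGTACG", 7), SmallRNARead("b", "TTTTGGGGCCCCAAA", 1)]
        p = tmp_path / "reads.fasta"
        write_small_rnas_fasta(reads, p)
        back = read_small_rnas(p)
        assert [(r.sequence, r.count) for r in back] == [(r.sequence, r.count) for r in reads]

    def test_plain_fasta_header_gets_count_one(self, tmp_path):
        p = tmp_path / "r.fasta"
        p.write_text(">plain\nACGU\n>tagged_x12\nGGGG\n")
        reads = read_small_rnas(p)
        assert [(r.count, r.sequence) for r in reads] == [(1, "ACGT"), (12, "GGGG")]

    def test_fastq_reader(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n")
        reads = read_small_rnas(p)
        assert reads[0].sequence == "ACGTACGT" and reads[0].count == 1

    def test_bed_cluster_extraction_half_open(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">chr1\nAACCGGTTAACC\n")
        (tmp_path / "c.bed").write_text("chr1\t2\t8\tclu1\n")
        refs = read_cluster_references(tmp_path / "c.bed", tmp_path / "g.fasta")
        assert refs.entries == {"clu1": "CCGGTT"}
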