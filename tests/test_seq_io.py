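import pytest
from hypothesis import given, settings, strategies as st

from mirslice.seq_io import (
    CollapsedRead,
    SequenceRecord,
    clip_adapter,
    collapse_reads,
    drop_n_reads,
    filter_by_length,
    normalize_seq,
    read_fasta,
    read_tag_counts,
    rp10m,
    attach_rp10m,
    write_fasta,
    write_tag_counts,
    revcomp,
)

ADAPTER = "TCGTATGCCG"

seqs = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestClipAdapter:
    @pytest.mark.parametrize(
        "read, min_ov, expected",
        [
            ("ACGTACGTACGT" + ADAPTER, 6, "ACGTACGTACGT"),  # full adapter at 3' end
            ("ACGTACGT" + "TCG", 3, "ACGTACGT"),  # 3-nt adapter prefix at read end
            ("ACGTACGTACGT", 6, None),  # no adapter evidence
            ("AC" + ADAPTER + "GG" + ADAPTER, 6, "AC"),  # leftmost occurrence wins
        ],
    )
    def test_examples(self, read, min_ov, expected):
        assert clip_adapter(read, ADAPTER, min_ov) == expected

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            clip_adapter("ACGTXZ", ADAPTER, 6)
        with pytest.raises(ValueError):
            clip_adapter("ACGT", "", 6)

    @given(insert=st.text(alphabet="AC", min_size=8, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_when_insert_lacks_adapter(self, insert):
        # adapter starts with T, so an A/C insert cannot contain it
        clipped = clip_adapter(insert + ADAPTER, ADAPTER, 4)
        assert clipped == insert
        assert clip_adapter(clipped, ADAPTER, 4) is None


class TestFilterAndCollapse:
    def test_length_window_is_inclusive(self):
        reads = [CollapsedRead("A" * n, 1) for n in (17, 18, 25, 26)]
        kept = filter_by_length(reads, 18, 25)
        assert [len(r.seq) for r in kept] == [18, 25]

    def test_identity_when_all_inside(self):
        reads = [CollapsedRead("A" * 20, 2), CollapsedRead("C" * 21, 1)]
        assert filter_by_length(reads, 20, 21) == reads
        assert filter_by_length([], 18, 25) == []

    def test_collapse_example(self):
        out = collapse_reads(["ACG", "ACG", "TTT"])
        assert [(r.seq, r.count) for r in out] == [("ACG", 2), ("TTT", 1)]
        assert collapse_reads([]) == []

    @given(st.lists(seqs, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_collapse_conserves_total_and_sorts(self, raw):
        out = collapse_reads(raw)
        assert sum(r.count for r in out) == len(raw)
        keys = [(-r.count, r.seq) for r in out]
        assert keys == sorted(keys)
        assert len({r.seq for r in out}) == len(out)

    @given(st.lists(seqs, min_size=1, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_filter_idempotent(self, raw):
        reads = collapse_reads(raw)
        once = filter_by_length(reads, 2, 10)
        assert filter_by_length(once, 2, 10) == once

    def test_drop_n_reads(self):
        kept, dropped = drop_n_reads(["ACGT", "ACNT", "NNNN"])
        assert kept == ["ACGT"] and dropped == 2


class TestNormalization:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(100, 5_000_000, 200.0), (0, 10, 0.0), (10_000_000, 10_000_000, 1e7)],
    )
    def test_rp10m_examples(self, count, total, expected):
        assert rp10m(count, total) == pytest.approx(expected)

    def test_rp10m_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            rp10m(1, 0)
        with pytest.raises(ValueError):
            rp10m(5, 3)

    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_library_rp10m_sums_to_ten_million(self, counts):
        reads = [CollapsedRead(f"{'ACGT'[i % 4]}" * 20 + "ACGT"[i % 4] * (i % 3), c) for i, c in enumerate(counts)]
        # sequences need not be unique here; only the normalization sum matters
        attach_rp10m(reads)
        assert sum(r.rp10m for r in reads) == pytest.approx(1e7, rel=1e-6)

    def test_u_normalized_to_t(self):
        assert normalize_seq("acgu") == "ACGT"

    def test_revcomp(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AAGC") == "GCTT"


class TestFiles:
    def test_fasta_round_trip_with_wrapping(self, tmp_path):
        recs = [SequenceRecord("a", "ACGT" * 40), SequenceRecord("b", "GGGTTT")]
        p = tmp_path / "x.fa"
        write_fasta(recs, p)
        text = p.read_text()
        assert max(len(l) for l in text.splitlines()) <= 60
        assert read_fasta(p) == recs

    def test_fasta_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_tag_counts_round_trip(self, tmp_path):
        reads = [CollapsedRead("ACGTACGT", 5), CollapsedRead("TTTTAAAA", 1)]
        p = tmp_path / "tags.tsv"
        write_tag_counts(reads, p)
        back = read_tag_counts(p)
        assert [(r.seq, r.count) for r in back] == [(r.seq, r.count) for r in reads]

    def test_tag_counts_rejects_duplicates_and_bad_counts(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("ACGT\t2\nACGT\t1\n")
        with pytest.raises(ValueError):
            read_tag_counts(p)
        p.write_text("ACGT\t0\n")
        with pytest.raises(ValueError):
            read_tag_counts(p)
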