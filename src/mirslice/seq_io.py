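"""Sequence I/O and small-RNA read preprocessing.

Readers/writers for FASTA/FASTQ, two-column tag-count tables, CDS coordinate
tables and GFF3-lite annotation intervals, plus the read-level preprocessing
steps every small-RNA library goes through before analysis: 3' adapter
clipping, length filtering and collapsing of identical reads into unique
sequences with counts.

All sequences are held internally in the DNA alphabet; U is normalized to T
on ingest and converted back only for display of folded hairpins.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDES = frozenset("ACGTN")

__all__ = [
    "SequenceRecord",
    "CollapsedRead",
    "TranscriptRecord",
    "AnnotationInterval",
    "normalize_seq",
    "clip_adapter",
    "filter_by_length",
    "collapse_reads",
    "drop_n_reads",
    "rp10m",
    "attach_rp10m",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_tag_counts",
    "write_tag_counts",
    "read_cds_table",
    "write_cds_table",
    "read_intervals",
    "write_tsv_report",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (genome contig, transcript, miRNA, ...)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValueError(f"non-nucleotide characters {sorted(bad)} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with its raw library count.

    ``rp10m`` (reads per ten million) is filled in once the library total is
    known; it is the normalization used throughout degradome reporting, where
    it is conventionally printed as TP10M (tags per ten million).
    """

    seq: str
    count: int
    rp10m: float = 0.0

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptRecord:
    """A sense-strand cDNA with optional 1-based inclusive CDS coordinates.

    Region labels derive from the CDS bounds: 5'UTR = [1, cds_start-1],
    CDS = [cds_start, cds_end], 3'UTR = [cds_end+1, len].
    """

    id: str
    seq: str
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.id!r}: cds_start and cds_end must be given together")
        if self.cds_start is not None:
            if not (1 <= self.cds_start <= self.cds_end <= len(self.seq)):
                raise ValueError(
                    f"{self.id!r}: CDS [{self.cds_start},{self.cds_end}] outside "
                    f"1..{len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AnnotationInterval:
    """GFF3-lite interval: seqid, 1-based inclusive start/end, strand, type."""

    seqid: str
    start: int
    end: int
    strand: str
    feature_type: str


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T; raise on anything outside {A,C,G,T,N}."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


# ---------------------------------------------------------------------------
# preprocessing


def clip_adapter(read_seq: str, adapter3: str, min_overlap: int = 6) -> Optional[str]:
    """Clip a 3' adapter from a raw read.

    Returns the insert preceding the leftmost exact occurrence of the full
    adapter, or of an adapter prefix of at least ``min_overlap`` nt flush with
    the read's 3' end. Returns None when the read carries no adapter evidence;
    callers discard such reads (an insert shorter than the sequencing cycle
    count must expose adapter, so untrimmed reads are adapter-negative
    artifacts or inserts running past the read end).
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read_seq = normalize_seq(read_seq)
    adapter3 = normalize_seq(adapter3)

    idx = read_seq.find(adapter3)
    if idx >= 0:
        return read_seq[:idx]
    # partial adapter prefix at the extreme 3' end
    max_part = min(len(adapter3) - 1, len(read_seq))
    for k in range(max_part, min_overlap - 1, -1):
        if read_seq.endswith(adapter3[:k]):
            return read_seq[:-k]
    return None


def filter_by_length(
    reads: Sequence[CollapsedRead], min_len: int, max_len: int
) -> list[CollapsedRead]:
    """Keep reads with min_len <= len <= max_len, preserving order."""
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    return [r for r in reads if min_len <= len(r.seq) <= max_len]


def drop_n_reads(raw_seqs: Iterable[str]) -> tuple[list[str], int]:
    """Remove reads containing N (exact-match mapping cannot place them).

    Returns (kept, n_dropped).
    """
    kept, dropped = [], 0
    for s in raw_seqs:
        if "N" in s:
            dropped += 1
        else:
            kept.append(s)
    return kept, dropped


def collapse_reads(raw_seqs: Iterable[str]) -> list[CollapsedRead]:
    """Collapse raw reads to unique sequences with counts.

    Output is sorted by descending count, then lexicographically, so the
    most abundant species (the putative mature miRNA in a hairpin window)
    is always first and ties break deterministically.
    """
    counts = Counter(normalize_seq(s) for s in raw_seqs)
    return [
        CollapsedRead(seq=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def rp10m(count: int, library_total: int) -> float:
    """Reads per ten million: count / library_total * 1e7."""
    if library_total < 1:
        raise ValueError("library_total must be >= 1")
    if not (0 <= count <= library_total):
        raise ValueError("require 0 <= count <= library_total")
    return count / library_total * 1e7


def attach_rp10m(reads: Sequence[CollapsedRead], library_total: Optional[int] = None) -> int:
    """Fill in rp10m for every read in place; returns the library total used."""
    total = library_total if library_total is not None else sum(r.count for r in reads)
    for r in reads:
        r.rp10m = rp10m(r.count, total)
    return total


# ---------------------------------------------------------------------------
# file formats


def _open_text(path: Union[str, Path], mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file; U is normalized to T."""
    with _open_text(path) as fh:
        records = [
            SequenceRecord(id=r.id, seq=normalize_seq(str(r.seq))) for r in SeqIO.parse(fh, "fasta")
        ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record ids in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], wrap: int = 60) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def read_fastq(path: Union[str, Path], min_mean_q: float = 0.0) -> Iterator[str]:
    """Yield read sequences from a Phred+33 FASTQ, dropping reads whose mean
    quality falls below ``min_mean_q``."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            if quals and sum(quals) / len(quals) < min_mean_q:
                continue
            yield normalize_seq(str(rec.seq))


def read_tag_counts(path: Union[str, Path]) -> list[CollapsedRead]:
    """Read a two-column (sequence, count) TSV — the de facto small-RNA
    interchange format."""
    reads: list[CollapsedRead] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            seq = normalize_seq(parts[0])
            if seq in seen:
                raise ValueError(f"{path}:{ln}: duplicate sequence {seq}")
            seen.add(seq)
            count = int(parts[1])
            if count < 1:
                raise ValueError(f"{path}:{ln}: count must be >= 1")
            reads.append(CollapsedRead(seq=seq, count=count))
    return reads


def write_tag_counts(reads: Iterable[CollapsedRead], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"{r.seq}\t{r.count}\n")


def read_cds_table(path: Union[str, Path]) -> dict[str, tuple[int, int]]:
    """Read a transcript CDS table: id, cds_start, cds_end (1-based inclusive)."""
    out: dict[str, tuple[int, int]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            out[parts[0]] = (int(parts[1]), int(parts[2]))
    return out


def write_cds_table(cds: dict[str, tuple[int, int]], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for tid, (s, e) in cds.items():
            fh.write(f"{tid}\t{s}\t{e}\n")


def read_intervals(path: Union[str, Path]) -> list[AnnotationInterval]:
    """Read GFF3-lite intervals: seqid, start, end, strand, type."""
    out: list[AnnotationInterval] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 tab-separated columns")
            seqid, start, end, strand, ftype = parts
            if strand not in "+-":
                raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
            out.append(AnnotationInterval(seqid, int(start), int(end), strand, ftype))
    return out


def write_tsv_report(
    rows: Iterable[Sequence], header: Sequence[str], path: Union[str, Path]
) -> None:
    """Write a plain TSV report with a header line."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (N self-complements)."""
    return str(Seq(seq).reverse_complement())
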