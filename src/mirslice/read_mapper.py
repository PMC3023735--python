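"""Exact-match multi-hit mapping of short reads to a reference set.

Small-RNA analysis only needs full-length, zero-mismatch placements, so the
mapper is a k-mer seed index with full verification rather than a BWT/FM
aligner. Genome mode indexes both strands; transcriptome mode indexes the
sense strand only, because degradome tags are 5' ends of mRNA 3' fragments
and can only map sense.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seq_io import CollapsedRead, SequenceRecord, revcomp

__all__ = [
    "MappedHit",
    "ReferenceIndex",
    "build_index",
    "map_exact",
    "map_library",
    "hit_multiplicity_summary",
    "write_hits_tsv",
    "write_hits_sam",
]

DEFAULT_SEED_K = 18  # minimum retained small-RNA read length
HYPER_REPETITIVE_CAP = 20  # loci; beyond this a read is excluded from hairpin candidacy


@dataclass(frozen=True, order=True)
class MappedHit:
    """One full-length exact placement of a read.

    ``pos`` is the 1-based start on the forward strand of the reference; for
    strand '-', the reverse complement of the read matches the forward
    reference at that interval.
    """

    read_seq: str
    ref_id: str
    pos: int
    strand: str


@dataclass
class ReferenceIndex:
    k: int
    both_strands: bool
    refs: dict[str, str]
    # k-mer -> list of (ref_id, 0-based forward offset, strand)
    seeds: dict[str, list[tuple[str, int, str]]] = field(repr=False, default_factory=dict)


def build_index(
    refs: Sequence[SequenceRecord], k: int = DEFAULT_SEED_K, both_strands: bool = True
) -> ReferenceIndex:
    """Index every k-mer occurrence of the references.

    Reverse-strand seeds are stored as the k-mer observed on the minus strand
    together with the forward offset of its footprint, so lookups need no
    second pass over the reference.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if not refs:
        raise ValueError("empty reference list")
    for r in refs:
        if len(r.seq) < k:
            raise ValueError(f"reference {r.id!r} shorter than seed length {k}")

    seeds: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for r in refs:
        s = r.seq
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            seeds[kmer].append((r.id, i, "+"))
            if both_strands:
                seeds[revcomp(kmer)].append((r.id, i, "-"))
    return ReferenceIndex(
        k=k, both_strands=both_strands, refs={r.id: r.seq for r in refs}, seeds=dict(seeds)
    )


def map_exact(read: CollapsedRead | str, index: ReferenceIndex) -> list[MappedHit]:
    """All full-length zero-mismatch placements of a read, sorted by
    (ref_id, pos, strand). Returns [] for an absent read."""
    seq = read.seq if isinstance(read, CollapsedRead) else read
    if len(seq) < index.k:
        raise ValueError(f"read shorter than seed length {index.k}")

    hits: set[MappedHit] = set()
    seed = seq[: index.k]
    for ref_id, off, strand in index.seeds.get(seed, ()):
        ref = index.refs[ref_id]
        if strand == "+":
            start = off
            if ref.startswith(seq, start):
                hits.add(MappedHit(seq, ref_id, start + 1, "+"))
        else:
            # seed came from the read's 5' end, which on '-' sits at the
            # 3' end of the forward-strand footprint
            start = off + index.k - len(seq)
            if start >= 0 and ref.startswith(revcomp(seq), start):
                hits.add(MappedHit(seq, ref_id, start + 1, "-"))
    return sorted(hits, key=lambda h: (h.ref_id, h.pos, h.strand))


def map_library(
    reads: Iterable[CollapsedRead], index: ReferenceIndex
) -> dict[str, list[MappedHit]]:
    """Map every read; returns {read_seq: hits} (possibly empty lists)."""
    return {r.seq: map_exact(r, index) for r in reads}


def hit_multiplicity_summary(hits_by_read: Mapping[str, int]) -> dict[str, int]:
    """Partition reads by genome hit count into the {0, 1, 2, >=3} classes."""
    table = {"0": 0, "1": 0, "2": 0, ">=3": 0}
    for n in hits_by_read.values():
        if n <= 2:
            table[str(n)] += 1
        else:
            table[">=3"] += 1
    return table


def write_hits_tsv(hits_by_read: Mapping[str, list[MappedHit]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tref\tpos\tstrand\tn_hits\n")
        for read_seq in sorted(hits_by_read):
            hits = hits_by_read[read_seq]
            for h in hits:
                fh.write(f"{h.read_seq}\t{h.ref_id}\t{h.pos}\t{h.strand}\t{len(hits)}\n")


def write_hits_sam(hits_by_read: Mapping[str, list[MappedHit]], index: ReferenceIndex, path) -> None:
    """Optional SAM emission for interoperability (flags 0/16, ungapped)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref_id, seq in index.refs.items():
            fh.write(f"@SQ\tSN:{ref_id}\tLN:{len(seq)}\n")
        for read_seq in sorted(hits_by_read):
            for h in hits_by_read[read_seq]:
                flag = 0 if h.strand == "+" else 16
                out_seq = h.read_seq if h.strand == "+" else revcomp(h.read_seq)
                fh.write(
                    f"{h.read_seq}\t{flag}\t{h.ref_id}\t{h.pos}\t255\t"
                    f"{len(h.read_seq)}M\t*\t0\t0\t{out_seq}\t*\n"
                )
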