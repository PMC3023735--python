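"""Categorization of genome-mapped small-RNA reads and isomiR tabulation.

Genome-matched unique reads are partitioned into three disjoint primary
categories with fixed precedence — known miRNA (exact identity with a known
mature sequence) > ncRNA (full-length containment in an rRNA/tRNA/snRNA/
snoRNA reference) > unannotated — so the category tallies always sum back to
the genome-matched totals. Exon overlap is tracked as a sub-flag of the
unannotated class: it bars a read from novel-miRNA candidacy (likely mRNA
degradation) without changing the category arithmetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .read_mapper import MappedHit
from .seq_io import CollapsedRead, SequenceRecord

__all__ = [
    "CategoryTable",
    "IsomirVariant",
    "IsomirTable",
    "length_distribution",
    "categorize_reads",
    "tabulate_isomirs",
]

CATEGORIES = ("known_miRNA", "ncRNA_Rfam", "unannotated")


@dataclass
class CategoryTable:
    """Unique/total read tallies per category, plus the exon-overlap sub-flag
    and the set of reads eligible for novel-miRNA prediction."""

    unique: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    total: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    exon_flagged_unique: int = 0
    category_of: dict[str, str] = field(default_factory=dict)
    prediction_eligible: set[str] = field(default_factory=set)

    def genome_matched_unique(self) -> int:
        return sum(self.unique.values())

    def genome_matched_total(self) -> int:
        return sum(self.total.values())


@dataclass(frozen=True)
class IsomirVariant:
    seq: str
    count: int
    off5: Optional[int]  # 5'-end shift vs the reference mature (+ = downstream)
    off3: Optional[int]  # 3'-end shift vs the reference mature
    arm: str  # "mature" or "star"


@dataclass
class IsomirTable:
    precursor_id: str
    mature_ref: str
    variants: list[IsomirVariant]


def length_distribution(reads: Iterable[CollapsedRead]) -> dict[int, int]:
    """Total read count per length (weighted by the collapsed counts)."""
    dist: Counter[int] = Counter()
    for r in reads:
        dist[len(r.seq)] += r.count
    return dict(dist)


def _overlaps_exon(
    hits: Sequence[MappedHit], exon_intervals: Mapping[str, list[tuple[int, int]]]
) -> bool:
    for h in hits:
        end = h.pos + len(h.read_seq) - 1
        for s, e in exon_intervals.get(h.ref_id, ()):
            if h.pos <= e and end >= s:
                return True
    return False


def categorize_reads(
    mapped_reads: Sequence[CollapsedRead],
    known_mirnas: Sequence[SequenceRecord],
    ncrna_refs: Sequence[SequenceRecord],
    exon_intervals: Optional[Mapping[str, list[tuple[int, int]]]] = None,
    hits_by_read: Optional[Mapping[str, Sequence[MappedHit]]] = None,
) -> CategoryTable:
    """Assign each genome-mapped read to exactly one primary category.

    ``mapped_reads`` must already be restricted to genome-matched reads.
    ncRNA matching is exact full-length containment of the read within a
    reference sequence, which keeps the assignment deterministic. Exon
    intervals (forward-strand, 1-based inclusive per reference) only flag
    unannotated reads; flagged reads are excluded from
    ``prediction_eligible``.
    """
    known_set = {m.seq for m in known_mirnas}
    ncrna_seqs = [n.seq for n in ncrna_refs]
    table = CategoryTable()

    for read in sorted(mapped_reads, key=lambda r: r.seq):
        if read.seq in known_set:
            cat = "known_miRNA"
        elif any(read.seq in n for n in ncrna_seqs):
            cat = "ncRNA_Rfam"
        else:
            cat = "unannotated"
        table.category_of[read.seq] = cat
        table.unique[cat] += 1
        table.total[cat] += read.count
        if cat == "unannotated":
            flagged = False
            if exon_intervals and hits_by_read is not None:
                flagged = _overlaps_exon(hits_by_read.get(read.seq, ()), exon_intervals)
            if flagged:
                table.exon_flagged_unique += 1
            else:
                table.prediction_eligible.add(read.seq)
    return table


def tabulate_isomirs(
    precursor: SequenceRecord,
    reads: Sequence[CollapsedRead],
    mature_ref: str,
) -> IsomirTable:
    """Tabulate mature-miRNA processing variants within one precursor.

    Offsets are the shifts of a variant's 5'/3' ends relative to the
    reference mature's ends in precursor coordinates (positive = toward the
    precursor 3' end). Reads landing outside the mature footprint with no
    overlap are flagged as star-arm variants and carry no offsets. Variants
    are sorted by descending count, ties lexicographic.
    """
    m_start = precursor.seq.find(mature_ref)
    if m_start < 0:
        raise ValueError(f"mature reference not found in precursor {precursor.id!r}")
    m_end = m_start + len(mature_ref) - 1  # 0-based inclusive

    variants = []
    for read in reads:
        pos = precursor.seq.find(read.seq)
        if pos < 0:
            raise ValueError(
                f"read {read.seq} does not map within precursor {precursor.id!r}"
            )
        end = pos + len(read.seq) - 1
        if end < m_start or pos > m_end:
            variants.append(IsomirVariant(read.seq, read.count, None, None, "star"))
        else:
            variants.append(
                IsomirVariant(read.seq, read.count, pos - m_start, end - m_end, "mature")
            )
    variants.sort(key=lambda v: (-v.count, v.seq))
    return IsomirTable(precursor_id=precursor.id, mature_ref=mature_ref, variants=variants)


def write_category_report(table: CategoryTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tunique_reads\ttotal_reads\n")
        for cat in CATEGORIES:
            fh.write(f"{cat}\t{table.unique[cat]}\t{table.total[cat]}\n")
        fh.write(
            f"# genome_matched\t{table.genome_matched_unique()}\t{table.genome_matched_total()}\n"
        )
        fh.write(f"# exon_flagged_unique\t{table.exon_flagged_unique}\n")


def write_isomir_report(tables: Sequence[IsomirTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("precursor\tvariant\tcount\toff5\toff3\tarm\n")
        for t in tables:
            for v in t.variants:
                o5 = "" if v.off5 is None else v.off5
                o3 = "" if v.off3 is None else v.off3
                fh.write(f"{t.precursor_id}\t{v.seq}\t{v.count}\t{o5}\t{o3}\t{v.arm}\n")
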