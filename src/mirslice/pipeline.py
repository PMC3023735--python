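"""End-to-end orchestration: preprocess -> map -> categorize -> discover ->
degradome signatures -> target calls -> classify -> report.

Every stage logs its input/output row counts to ``run.log`` in the output
directory; reruns with an identical configuration are byte-identical apart
from that log's timestamp line. Inputs are the plain-text formats of the
field: FASTA references, two-column tag-count TSVs, a CDS coordinate TSV,
and FASTA miRNA sets.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import degradome_targeting as deg
from . import hairpin_miner as hm
from . import read_mapper as rm
from . import seq_io
from . import smallrna_annotator as ann
from .seq_io import CollapsedRead, SequenceRecord, TranscriptRecord

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run.

    Thresholds default to the standard plant small-RNA/degradome settings:
    18-25-nt small RNAs, 20-21-nt degradome tags, 150-nt hairpin flanks,
    duplex acceptance at >=16 matched pairs and <=4 nt size difference,
    alignment scores up to 7 with a doubled-penalty core at miRNA positions
    2-13, and 15-nt t-signature half-windows.
    """

    out_dir: str = "mirslice_run"
    # inputs (any may be omitted; stages lacking inputs are skipped)
    genome_fasta: Optional[str] = None
    smallrna_tags: Optional[str] = None
    smallrna_fastq: Optional[str] = None
    adapter3: Optional[str] = None
    known_mirna_fasta: Optional[str] = None
    known_precursor_fasta: Optional[str] = None
    ncrna_fasta: Optional[str] = None
    exon_gff: Optional[str] = None
    transcript_fasta: Optional[str] = None
    cds_table: Optional[str] = None
    degradome_tags: Optional[str] = None
    extra_mirna_fasta: Optional[str] = None  # e.g. newly discovered matures
    # thresholds
    min_read_len: int = 18
    max_read_len: int = 25
    deg_min_len: int = 20
    deg_max_len: int = 21
    flank: int = hm.DEFAULT_FLANK
    matched_pairs_min: int = hm.MIN_MATCHED_PAIRS
    size_diff_max: int = hm.MAX_SIZE_DIFF
    score_max: float = deg.SCORE_MAX
    allow_gap: bool = False
    min_candidate_count: int = 10  # read abundance needed to seed a hairpin window
    max_hits_for_candidacy: int = rm.HYPER_REPETITIVE_CAP
    seed_k: int = rm.DEFAULT_SEED_K
    seed: int = 0
    # stage switches
    do_smallrna: bool = True
    do_discovery: bool = True
    do_degradome: bool = True


@dataclass
class PipelineResult:
    out_dir: Path
    length_dist: dict = field(default_factory=dict)
    multiplicity: dict = field(default_factory=dict)
    category_table: Optional[ann.CategoryTable] = None
    candidates: list = field(default_factory=list)
    accepted_candidates: list = field(default_factory=list)
    signatures: list = field(default_factory=list)
    calls: list = field(default_factory=list)
    table_rows: list = field(default_factory=list)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a YAML (or flat key: value) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = [f"# run started {time.strftime('%Y-%m-%dT%H:%M:%S')}"]

    def stage(self, name: str, **counts) -> None:
        self.lines.append(name + "\t" + "\t".join(f"{k}={v}" for k, v in counts.items()))

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _load_reads(cfg: PipelineConfig, log: _Log) -> list[CollapsedRead]:
    if cfg.smallrna_tags:
        reads = seq_io.read_tag_counts(cfg.smallrna_tags)
        log.stage("load_smallrna", unique=len(reads), total=sum(r.count for r in reads))
        return reads
    if cfg.smallrna_fastq:
        if not cfg.adapter3:
            raise ValueError("raw FASTQ input requires adapter3")
        raw = list(seq_io.read_fastq(cfg.smallrna_fastq))
        clipped = [seq_io.clip_adapter(s, cfg.adapter3) for s in raw]
        kept = [c for c in clipped if c]
        kept, n_dropped = seq_io.drop_n_reads(kept)
        reads = seq_io.collapse_reads(kept)
        log.stage(
            "preprocess",
            raw=len(raw),
            adapter_clipped=len(kept),
            n_dropped=n_dropped,
            unique=len(reads),
        )
        return reads
    raise ValueError("no small-RNA input configured")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    for k, v in asdict(cfg).items():
        log.lines.append(f"# config {k}={v}")
    res = PipelineResult(out_dir=out)

    genome = seq_io.read_fasta(cfg.genome_fasta) if cfg.genome_fasta else []
    known_mirnas = (
        seq_io.read_fasta(cfg.known_mirna_fasta) if cfg.known_mirna_fasta else []
    )
    ncrnas = seq_io.read_fasta(cfg.ncrna_fasta) if cfg.ncrna_fasta else []

    accepted_matures: dict[str, str] = {}

    if cfg.do_smallrna and (cfg.smallrna_tags or cfg.smallrna_fastq):
        reads = _load_reads(cfg, log)
        reads = seq_io.filter_by_length(reads, cfg.min_read_len, cfg.max_read_len)
        seq_io.attach_rp10m(reads)
        log.stage("length_filter", unique=len(reads), total=sum(r.count for r in reads))

        res.length_dist = ann.length_distribution(reads)
        seq_io.write_tsv_report(
            sorted(res.length_dist.items()), ("length", "total_reads"), out / "length_distribution.tsv"
        )

        if genome:
            index = rm.build_index(genome, k=cfg.seed_k, both_strands=True)
            hits_by_read = rm.map_library(reads, index)
            n_hits = {s: len(h) for s, h in hits_by_read.items()}
            res.multiplicity = rm.hit_multiplicity_summary(n_hits)
            seq_io.write_tsv_report(
                sorted(res.multiplicity.items()), ("hit_class", "reads"), out / "hit_multiplicity.tsv"
            )
            mapped = [r for r in reads if n_hits[r.seq] > 0]
            log.stage("map_genome", mapped_unique=len(mapped), classes=str(res.multiplicity))

            exon_iv: dict[str, list[tuple[int, int]]] = {}
            if cfg.exon_gff:
                for iv in seq_io.read_intervals(cfg.exon_gff):
                    if iv.feature_type == "exon":
                        exon_iv.setdefault(iv.seqid, []).append((iv.start, iv.end))
            table = ann.categorize_reads(mapped, known_mirnas, ncrnas, exon_iv, hits_by_read)
            res.category_table = table
            ann.write_category_report(table, out / "category_report.tsv")
            log.stage(
                "categorize",
                known=table.unique["known_miRNA"],
                ncrna=table.unique["ncRNA_Rfam"],
                unannotated=table.unique["unannotated"],
            )

            if cfg.do_discovery:
                res.candidates = _discover(cfg, genome, index, reads, table, hits_by_read, log)
                res.accepted_candidates = [c for c in res.candidates if c.accepted]
                hm.write_candidate_report(res.candidates, out / "hairpin_candidates.tsv")
                hm.write_vienna(res.accepted_candidates, out / "accepted_precursors.vienna")
                for i, c in enumerate(res.accepted_candidates, 1):
                    accepted_matures[f"novel_mir_{i}"] = c.mature_seq
                log.stage(
                    "discover",
                    windows=len(res.candidates),
                    accepted=len(res.accepted_candidates),
                )

    if cfg.do_degradome and cfg.degradome_tags and cfg.transcript_fasta:
        _degradome(cfg, res, accepted_matures, known_mirnas, log, out)

    log.flush()
    return res


def _discover(cfg, genome, index, reads, table, hits_by_read, log) -> list[hm.HairpinCandidate]:
    eligible = {
        s
        for s in table.prediction_eligible
        if 1 <= len(hits_by_read[s]) <= cfg.max_hits_for_candidacy
    }
    by_seq = {r.seq: r for r in reads}
    windows = []
    for s in sorted(eligible):
        if by_seq[s].count < cfg.min_candidate_count:
            continue
        for hit in hits_by_read[s]:
            windows.extend(hm.extract_flanks(genome, hit, flank=cfg.flank))
    refs = {r.id: r.seq for r in genome}
    merged = hm.merge_windows(windows, refs)
    log.stage("candidate_windows", raw=len(windows), merged=len(merged))

    # Candidates are seeded abundance-first within each merged locus: the
    # folded precursor window is re-derived from the most abundant unclaimed
    # read (flanks are anchored on the small RNA itself), and every read
    # falling inside that window is claimed by the candidate, so one locus
    # can host several well-separated candidates but never duplicates.
    window_reads = [r for r in reads if r.seq in table.prediction_eligible]
    out = []
    for locus in merged:
        present = [r for r in window_reads if r.seq in locus.seq]
        claimed: set[str] = set()
        while True:
            seeds = [
                r for r in present
                if r.seq not in claimed and r.count >= cfg.min_candidate_count
            ]
            if not seeds:
                break
            top = min(seeds, key=lambda r: (-r.count, r.seq))
            hit = next(
                (
                    h for h in hits_by_read[top.seq]
                    if h.ref_id == locus.ref_id
                    and h.strand == locus.strand
                    and locus.start <= h.pos <= locus.end
                ),
                None,
            )
            if hit is None:
                claimed.add(top.seq)
                continue
            fold_window = hm.merge_windows(
                hm.extract_flanks(genome, hit, flank=cfg.flank), refs
            )[0]
            out.append(
                hm.evaluate_candidate(
                    fold_window,
                    window_reads,
                    min_matched_pairs=cfg.matched_pairs_min,
                    max_size_diff=cfg.size_diff_max,
                )
            )
            claimed.add(top.seq)
            for r in present:
                if r.seq in fold_window.seq:
                    claimed.add(r.seq)
    return out


def _degradome(cfg, res, accepted_matures, known_mirnas, log, out: Path) -> None:
    transcripts = _load_transcripts(cfg)
    tags = seq_io.read_tag_counts(cfg.degradome_tags)
    library_total = sum(t.count for t in tags)
    tags_lf = seq_io.filter_by_length(tags, cfg.deg_min_len, cfg.deg_max_len)
    log.stage("degradome_load", unique=len(tags), kept=len(tags_lf), total=library_total)

    t_index = rm.build_index(
        [SequenceRecord(t.id, t.seq) for t in transcripts], k=cfg.seed_k, both_strands=False
    )
    tag_hits = []
    n_mapped = 0
    for t in tags_lf:
        hits = rm.map_exact(t, t_index)
        if hits:
            n_mapped += 1
        for h in hits:
            tag_hits.append((h, t.count))
    log.stage("degradome_map", mapped_unique=n_mapped)

    res.signatures = deg.build_signatures(transcripts, tag_hits, library_total)
    log.stage("signatures", n=len(res.signatures))

    mirnas: dict[str, str] = {m.id: m.seq for m in known_mirnas}
    if cfg.extra_mirna_fasta:
        for m in seq_io.read_fasta(cfg.extra_mirna_fasta):
            mirnas[m.id] = m.seq
    mirnas.update(accepted_matures)
    mirnas = {k: v for k, v in mirnas.items() if 18 <= len(v) <= 25}
    if not mirnas:
        log.stage("call_targets", skipped="no miRNA set")
        return

    calls = deg.call_targets(
        mirnas, res.signatures, transcripts, allow_gap=cfg.allow_gap, score_max=cfg.score_max
    )
    calls = deg.classify_all(calls, res.signatures)
    t_by_id = {t.id: t for t in transcripts}
    for c in calls:
        c.site_region = deg.locate_site_region(t_by_id[c.alignment.transcript_id], c.cleave_pos)
    res.calls = calls
    log.stage("call_targets", calls=len(calls))

    res.table_rows = deg.emit_target_table(calls)
    seq_io.write_tsv_report(
        res.table_rows,
        ("mirna", "target_gene", "annotation", "class", "abundance_tp10m", "cleavage_site", "location"),
        out / "target_table.tsv",
    )
    tdir = out / "tplots"
    tdir.mkdir(exist_ok=True)
    cleav_by_tid: dict[str, set[int]] = {}
    for c in calls:
        cleav_by_tid.setdefault(c.alignment.transcript_id, set()).add(c.cleave_pos)
    for tid, positions in sorted(cleav_by_tid.items()):
        rows = deg.tplot_data(tid, res.signatures, positions)
        seq_io.write_tsv_report(rows, ("position", "tp10m", "is_cleavage_site"), tdir / f"{tid}.tsv")


def _load_transcripts(cfg: PipelineConfig) -> list[TranscriptRecord]:
    recs = seq_io.read_fasta(cfg.transcript_fasta)
    cds = seq_io.read_cds_table(cfg.cds_table) if cfg.cds_table else {}
    out = []
    for r in recs:
        if r.id in cds:
            s, e = cds[r.id]
            out.append(TranscriptRecord(id=r.id, seq=r.seq, cds_start=s, cds_end=e))
        else:
            out.append(TranscriptRecord(id=r.id, seq=r.seq))
    return out
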