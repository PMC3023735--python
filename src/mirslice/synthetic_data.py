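"""Ground-truthed synthetic data emulating a seed small-RNA + degradome study.

Three coupled generators produce exactly the formats the pipeline consumes:

* a toy genome carrying planted miRNA hairpins (both accept-type precursors
  and deliberate violations of the duplex criteria), plus planted ncRNA
  genes and "known" miRNA loci so the read categorizer has all three
  categories to assign;
* a small-RNA library dominated by 21/22/24-nt reads, with mature/star
  species, 5'/3' isomiRs at geometric decay, ncRNA fragments and random
  degradation background;
* a degradome library of 20-21-nt 5'-end tags with high-abundance peaks
  planted exactly opposite miRNA positions 10-11 of complementary sites,
  over Poisson background at uniform positions with a gentle 5'->3' decay.

Every planted signal is recorded in a :class:`SynthTruth` that serializes
losslessly to a line-oriented key-value file, so recovery tests can compare
pipeline output against intent. All randomness flows from one integer seed
through named :class:`numpy.random.SeedSequence` streams; a fixed seed gives
byte-identical outputs.

Hairpin construction guarantees its advertised duplex statistics by
deterministic rejection sampling: arms are built to the target matched-pair
and size-difference values (non-pairable same-letter substitutions opposite
selected mature positions; bulged insertions in the star arm), then the
exact window the discovery stage will fold is re-evaluated and the draw is
retried if the maximum-pairing structure realizes different statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .hairpin_miner import DEFAULT_FLANK, DuplexStats, evaluate_candidate, CandidateWindow
from .seq_io import CollapsedRead, SequenceRecord, TranscriptRecord, revcomp

__all__ = [
    "SynthConfig",
    "PlantedHairpin",
    "PlantedCleavage",
    "SynthTruth",
    "make_genome_with_hairpins",
    "make_transcriptome",
    "make_smallrna_library",
    "make_degradome_library",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic bundle.

    Defaults emulate a developing-seed library: read lengths concentrated at
    21/22/24 nt, star strands a third as abundant as matures, degradome
    peaks ten-fold over per-position background.
    """

    seed: int = 0
    # genome / hairpins
    n_hairpins: int = 50
    n_known_mirnas: int = 5
    n_ncrna_genes: int = 4
    mature_len_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.15, 21: 0.60, 22: 0.25}
    )
    frac_violation_pairs: float = 0.2  # planted with matched_pairs < 16
    frac_violation_size: float = 0.2  # planted with size_diff > 4
    spacer_len: int = 300
    minus_strand_frac: float = 0.3
    verify_hairpins: bool = True  # re-fold each construct; off for degradome-only studies
    # small-RNA library
    smallrna_library_size: int = 100_000
    length_mode_weights: dict[int, float] = field(
        default_factory=lambda: {21: 0.5, 22: 0.3, 24: 0.2}
    )
    background_fraction: float = 0.7
    ncrna_read_fraction: float = 0.1
    star_to_mature_ratio: float = 0.3
    isomir_decay: float = 0.25
    mature_count_range: tuple[int, int] = (150, 400)
    # transcriptome / degradome
    n_transcripts: int = 20
    n_target_sites: int = 10
    transcript_len: int = 1200
    cds_margin: int = 150  # CDS spans [margin+1, len-margin]
    peak_to_background_ratio: float = 10.0
    planted_peak_range: tuple[int, int] = (50, 80)
    background_decay_rate: float = 0.001  # per-nt 5'->3' intensity decay

    def __post_init__(self):
        if self.n_hairpins < 1 or self.n_transcripts < 1:
            raise ValueError("sizes must be >= 1")
        if self.peak_to_background_ratio <= 0:
            raise ValueError("peak-to-background ratio must be > 0")
        for w in (self.mature_len_weights, self.length_mode_weights):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("length weights must sum to 1")


@dataclass
class PlantedHairpin:
    name: str
    chrom: str
    start: int  # 1-based forward-strand coords of the precursor
    end: int
    strand: str
    precursor_seq: str  # read-sense
    mature_seq: str
    star_seq: str
    matched_pairs: int  # realized under the deterministic fold
    size_diff: int
    intended_accept: bool
    reason: str  # "accepted" or the planted violation
    is_known: bool = False


@dataclass
class PlantedCleavage:
    mirna_id: str
    mirna_seq: str
    transcript_id: str
    site_start: int
    site_end: int
    cleave_pos: int  # opposite miRNA position 10
    planted_count: int
    weak: bool = False  # peak at/below background: may fall to Class III/IV


@dataclass
class SynthTruth:
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    cleavages: list[PlantedCleavage] = field(default_factory=list)
    known_mirnas: list[SequenceRecord] = field(default_factory=list)
    ncrna_refs: list[SequenceRecord] = field(default_factory=list)

    def to_file(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for h in self.hairpins:
                fh.write(
                    "hairpin\t"
                    + "\t".join(
                        f"{k}={v}"
                        for k, v in [
                            ("name", h.name),
                            ("chrom", h.chrom),
                            ("start", h.start),
                            ("end", h.end),
                            ("strand", h.strand),
                            ("precursor", h.precursor_seq),
                            ("mature", h.mature_seq),
                            ("star", h.star_seq),
                            ("matched_pairs", h.matched_pairs),
                            ("size_diff", h.size_diff),
                            ("accept", int(h.intended_accept)),
                            ("reason", h.reason),
                            ("known", int(h.is_known)),
                        ]
                    )
                    + "\n"
                )
            for c in self.cleavages:
                fh.write(
                    "cleavage\t"
                    + "\t".join(
                        f"{k}={v}"
                        for k, v in [
                            ("mirna_id", c.mirna_id),
                            ("mirna", c.mirna_seq),
                            ("transcript", c.transcript_id),
                            ("site_start", c.site_start),
                            ("site_end", c.site_end),
                            ("cleave_pos", c.cleave_pos),
                            ("count", c.planted_count),
                            ("weak", int(c.weak)),
                        ]
                    )
                    + "\n"
                )
            for r in self.known_mirnas:
                fh.write(f"known_mirna\tid={r.id}\tseq={r.seq}\n")
            for r in self.ncrna_refs:
                fh.write(f"ncrna\tid={r.id}\tseq={r.seq}\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SynthTruth":
        truth = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                kind, kv = parts[0], dict(p.split("=", 1) for p in parts[1:])
                if kind == "hairpin":
                    truth.hairpins.append(
                        PlantedHairpin(
                            name=kv["name"],
                            chrom=kv["chrom"],
                            start=int(kv["start"]),
                            end=int(kv["end"]),
                            strand=kv["strand"],
                            precursor_seq=kv["precursor"],
                            mature_seq=kv["mature"],
                            star_seq=kv["star"],
                            matched_pairs=int(kv["matched_pairs"]),
                            size_diff=int(kv["size_diff"]),
                            intended_accept=bool(int(kv["accept"])),
                            reason=kv["reason"],
                            is_known=bool(int(kv["known"])),
                        )
                    )
                elif kind == "cleavage":
                    truth.cleavages.append(
                        PlantedCleavage(
                            mirna_id=kv["mirna_id"],
                            mirna_seq=kv["mirna"],
                            transcript_id=kv["transcript"],
                            site_start=int(kv["site_start"]),
                            site_end=int(kv["site_end"]),
                            cleave_pos=int(kv["cleave_pos"]),
                            planted_count=int(kv["count"]),
                            weak=bool(int(kv["weak"])),
                        )
                    )
                elif kind == "known_mirna":
                    truth.known_mirnas.append(SequenceRecord(kv["id"], kv["seq"]))
                elif kind == "ncrna":
                    truth.ncrna_refs.append(SequenceRecord(kv["id"], kv["seq"]))
        return truth


# ---------------------------------------------------------------------------
# helpers


def _stream(cfg: SynthConfig, name: str) -> np.random.Generator:
    """A named, seed-derived RNG stream."""
    digest = sum(ord(c) * 131**i for i, c in enumerate(name)) % (2**20)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed % (2**31), digest]))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _weighted_choice(rng: np.random.Generator, weights: dict[int, float]) -> int:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _build_arms(
    rng: np.random.Generator, mature: str, n_mismatch: int, n_insert: int
) -> str:
    """Star arm = reverse complement of the mature with ``n_mismatch``
    non-pairable same-letter substitutions at interior positions and
    ``n_insert`` bulged bases inserted at one interior point."""
    L = len(mature)
    star = list(revcomp(mature))
    interior = np.arange(3, L - 3)  # keep duplex ends paired
    if n_mismatch > len(interior):
        raise ValueError("matched_pairs target infeasible for this mature length")
    if n_mismatch:
        chosen = rng.choice(interior, size=n_mismatch, replace=False)
        for p in chosen:  # star index opposite mature position p
            star[L - 1 - int(p)] = mature[int(p)]
    if n_insert:
        at = int(rng.integers(4, L - 4))
        star[at:at] = list(_rand_seq(rng, n_insert))
    return "".join(star)


def _hairpin_spec(cfg: SynthConfig, rng: np.random.Generator, idx: int):
    """Decide one hairpin's target duplex statistics and intended verdict."""
    u = idx / cfg.n_hairpins  # deterministic stratification over the set
    if u < cfg.frac_violation_pairs:
        matched_target = int(rng.integers(12, 16))  # < 16: reject
        size_target = int(rng.integers(0, 3))
        accept, reason = False, "matched_pairs<16"
    elif u < cfg.frac_violation_pairs + cfg.frac_violation_size:
        matched_target = int(rng.integers(17, 21))
        size_target = int(rng.integers(5, 7))  # > 4: reject
        accept, reason = False, "size_diff>4"
    else:
        matched_target = int(rng.integers(16, 22))
        size_target = int(rng.integers(0, 3))
        accept, reason = True, "accepted"
    return matched_target, size_target, accept, reason


def _realized_stats(window_seq: str, mature: str):
    """Fold the discovery-stage window and report the realized verdict."""
    window = CandidateWindow("synthcheck", 1, len(window_seq), "+", window_seq)
    cand = evaluate_candidate(window, [CollapsedRead(seq=mature, count=10)])
    return cand


def make_genome_with_hairpins(cfg: SynthConfig):
    """Build the toy genome and its truth record.

    Returns (genome records, :class:`SynthTruth`). Background is i.i.d.
    uniform nucleotides, which keeps accidental hairpins negligible at the
    150-nt flank scale. Each planted precursor is re-checked under the
    deterministic fold over the exact flanked window discovery will see,
    and redrawn until the realized verdict matches the intended one.
    """
    rng = _stream(cfg, "genome")
    segments: list[str] = []
    cursor = 0
    chrom = "chr1"
    truth = SynthTruth()

    def _push(seq: str) -> int:
        nonlocal cursor
        segments.append(seq)
        start = cursor + 1
        cursor += len(seq)
        return start

    n_total = cfg.n_hairpins + cfg.n_known_mirnas
    for idx in range(n_total):
        is_known = idx >= cfg.n_hairpins
        if is_known:
            matched_target, size_target = 99, 0  # perfect duplex for known loci
            accept, reason = True, "accepted"
        else:
            matched_target, size_target, accept, reason = _hairpin_spec(cfg, rng, idx)

        for _attempt in range(60):
            mlen = _weighted_choice(rng, cfg.mature_len_weights)
            mature = _rand_seq(rng, mlen)
            n_mm = 0 if matched_target >= mlen else mlen - matched_target
            star = _build_arms(rng, mature, n_mm, size_target)
            loop = _rand_seq(rng, 8)
            if rng.random() < 0.5:
                precursor = mature + loop + star
            else:
                precursor = star + loop + mature
            # context pads sized so the discovery-stage fold window
            # (mature read +/- flank) is exactly pad5 + precursor + pad3
            o5 = precursor.find(mature)
            o3 = o5 + mlen - 1
            flank5 = _rand_seq(rng, DEFAULT_FLANK - o5)
            flank3 = _rand_seq(rng, DEFAULT_FLANK - (len(precursor) - 1 - o3))
            window_seq = flank5 + precursor + flank3

            if not cfg.verify_hairpins:
                # construction-only mode: trust the built duplex statistics
                cand = type("Stub", (), {})()
                cand.duplex = DuplexStats(
                    matched_pairs=min(matched_target, mlen), size_diff=size_target
                )
                cand.star_seq = star
                cand.accepted = accept
                cand.reason = reason
                break

            cand = _realized_stats(window_seq, mature)
            if cand.duplex is None:
                continue
            ok_accept = cand.accepted and accept and cand.duplex.size_diff == size_target
            ok_reject = (not cand.accepted) and (not accept) and cand.reason == reason
            if ok_accept or ok_reject:
                break
        else:
            raise RuntimeError(f"could not realize hairpin spec {matched_target}/{size_target}")

        strand = "-" if rng.random() < cfg.minus_strand_frac else "+"
        spacer = _rand_seq(rng, cfg.spacer_len)
        _push(spacer)
        planted = window_seq if strand == "+" else revcomp(window_seq)
        w_start = _push(planted)
        prec_off = len(flank5)  # precursor offset within the window (read-sense)
        if strand == "+":
            p_start = w_start + prec_off
        else:
            p_start = w_start + len(flank3)
        p_end = p_start + len(precursor) - 1

        name = ("known_mir_%d" if is_known else "syn_mir_%d") % (
            idx - cfg.n_hairpins + 1 if is_known else idx + 1
        )
        truth.hairpins.append(
            PlantedHairpin(
                name=name,
                chrom=chrom,
                start=p_start,
                end=p_end,
                strand=strand,
                precursor_seq=precursor,
                mature_seq=mature,
                star_seq=cand.star_seq,
                matched_pairs=cand.duplex.matched_pairs,
                size_diff=cand.duplex.size_diff,
                intended_accept=accept,
                reason=cand.reason,
                is_known=is_known,
            )
        )
        if is_known:
            truth.known_mirnas.append(SequenceRecord(name, mature))

    for j in range(cfg.n_ncrna_genes):
        spacer = _rand_seq(rng, cfg.spacer_len)
        _push(spacer)
        gene = _rand_seq(rng, 120)
        _push(gene)
        truth.ncrna_refs.append(SequenceRecord(f"ncrna_{j+1}", gene))

    _push(_rand_seq(rng, cfg.spacer_len))
    genome = [SequenceRecord(chrom, "".join(segments))]
    return genome, truth


# ---------------------------------------------------------------------------
# small-RNA library


def make_smallrna_library(cfg: SynthConfig, truth: SynthTruth) -> list[CollapsedRead]:
    """Simulate the collapsed small-RNA library.

    Mature and star species at configured abundances, 5'/3' isomiRs at
    geometric decay, ncRNA fragments and genome-derived degradation
    background with the 21/22/24 length profile.
    """
    rng = _stream(cfg, "smallrna")
    counts: dict[str, int] = {}

    def _add(seq: str, n: int) -> None:
        if n > 0 and seq:
            counts[seq] = counts.get(seq, 0) + int(n)

    planted_budget = int(cfg.smallrna_library_size * (1 - cfg.background_fraction))
    per_hairpin = max(1, planted_budget // max(1, len(truth.hairpins)))

    for h in truth.hairpins:
        lo, hi = cfg.mature_count_range
        scale = per_hairpin / ((lo + hi) / 2 * (1 + cfg.star_to_mature_ratio + 0.6))
        mature_count = int(rng.integers(lo, hi + 1) * max(scale, 0.2))
        mature_count = max(mature_count, 20)
        _add(h.mature_seq, mature_count)
        _add(h.star_seq, max(1, int(round(mature_count * cfg.star_to_mature_ratio))))

        # isomiRs: end-shifted variants read off the precursor
        prec = h.precursor_seq
        m0 = prec.find(h.mature_seq)
        if m0 >= 0:
            variants = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)]
            for k, (d5, d3) in enumerate(variants, start=1):
                s = m0 + d5
                e = m0 + len(h.mature_seq) + d3
                if s < 0 or e > len(prec) or e - s < 18:
                    continue
                iso = prec[s:e]
                if iso != h.mature_seq:
                    _add(iso, int(mature_count * cfg.isomir_decay**k))

    # ncRNA fragments
    n_nc = int(cfg.smallrna_library_size * cfg.ncrna_read_fraction)
    if truth.ncrna_refs and n_nc:
        for _ in range(max(1, n_nc // 40)):
            ref = truth.ncrna_refs[int(rng.integers(0, len(truth.ncrna_refs)))]
            ln = _weighted_choice(rng, cfg.length_mode_weights)
            if len(ref.seq) <= ln:
                continue
            p = int(rng.integers(0, len(ref.seq) - ln + 1))
            _add(ref.seq[p : p + ln], 40)

    return _finish_library(cfg, rng, counts)


def _finish_library(cfg, rng, counts) -> list[CollapsedRead]:
    # genome-derived degradation background is added by the caller when the
    # genome is at hand; standalone libraries fall back to random fragments
    reads = [CollapsedRead(seq=s, count=c) for s, c in counts.items()]
    reads.sort(key=lambda r: (-r.count, r.seq))
    return reads


def add_degradation_background(
    cfg: SynthConfig,
    genome: Sequence[SequenceRecord],
    reads: list[CollapsedRead],
) -> list[CollapsedRead]:
    """Add genome-derived background reads (random loci, modal lengths
    following the configured 21/22/24 weights) up to the library size."""
    rng = _stream(cfg, "background")
    counts = {r.seq: r.count for r in reads}
    current = sum(counts.values())
    target = cfg.smallrna_library_size
    gseq = genome[0].seq
    while current < target:
        ln = _weighted_choice(rng, cfg.length_mode_weights)
        p = int(rng.integers(0, len(gseq) - ln + 1))
        frag = gseq[p : p + ln]
        if "N" in frag:
            continue
        n = int(rng.integers(1, 6))
        n = min(n, target - current)
        counts[frag] = counts.get(frag, 0) + n
        current += n
    out = [CollapsedRead(seq=s, count=c) for s, c in counts.items()]
    out.sort(key=lambda r: (-r.count, r.seq))
    return out


# ---------------------------------------------------------------------------
# transcriptome and degradome


def write_bundle(cfg: SynthConfig, out_dir: Union[str, Path]) -> Path:
    """Generate and write a complete, pipeline-ready input bundle.

    Emits genome.fa, smallrna_tags.tsv, known_mirnas.fa, ncrna.fa,
    transcripts.fa, cds.tsv, degradome_tags.tsv and truth.txt. Byte-identical
    for a fixed config.
    """
    from . import seq_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = make_genome_with_hairpins(cfg)
    reads = make_smallrna_library(cfg, truth)
    reads = add_degradation_background(cfg, genome, reads)
    transcripts = make_transcriptome(cfg, truth)
    tags = make_degradome_library(cfg, truth, transcripts)

    seq_io.write_fasta(genome, out / "genome.fa")
    seq_io.write_tag_counts(reads, out / "smallrna_tags.tsv")
    seq_io.write_fasta(truth.known_mirnas, out / "known_mirnas.fa")
    seq_io.write_fasta(truth.ncrna_refs, out / "ncrna.fa")
    seq_io.write_fasta(
        [seq_io.SequenceRecord(t.id, t.seq) for t in transcripts], out / "transcripts.fa"
    )
    seq_io.write_cds_table(
        {t.id: (t.cds_start, t.cds_end) for t in transcripts if t.cds_start}, out / "cds.tsv"
    )
    seq_io.write_tag_counts(tags, out / "degradome_tags.tsv")
    truth.to_file(out / "truth.txt")
    return out


def make_transcriptome(
    cfg: SynthConfig, truth: SynthTruth
) -> list[TranscriptRecord]:
    """Random transcripts with CDS bounds; complementary target sites for the
    first ``n_target_sites`` accepted planted miRNAs are embedded in the CDS
    and recorded in ``truth.cleavages`` (cleave_pos opposite miRNA nt 10)."""
    rng = _stream(cfg, "transcripts")
    accepted = [h for h in truth.hairpins if h.intended_accept]
    site_mirnas = accepted[: cfg.n_target_sites]

    transcripts = []
    for i in range(cfg.n_transcripts):
        tid = f"synT{i+1:03d}"
        seq = list(_rand_seq(rng, cfg.transcript_len))
        cds_start = cfg.cds_margin + 1
        cds_end = cfg.transcript_len - cfg.cds_margin
        if i < len(site_mirnas):
            h = site_mirnas[i]
            site = revcomp(h.mature_seq)
            lo = cds_start + 30
            hi = cds_end - 30 - len(site)
            pos = int(rng.integers(lo, hi))  # 1-based site start
            seq[pos - 1 : pos - 1 + len(site)] = list(site)
            site_end = pos + len(site) - 1
            cleave_pos = site_end - 9  # base paired to miRNA position 10
            peak = int(rng.integers(*cfg.planted_peak_range))
            weak = cfg.peak_to_background_ratio <= 1.0
            truth.cleavages.append(
                PlantedCleavage(
                    mirna_id=h.name,
                    mirna_seq=h.mature_seq,
                    transcript_id=tid,
                    site_start=pos,
                    site_end=site_end,
                    cleave_pos=cleave_pos,
                    planted_count=peak,
                    weak=weak,
                )
            )
        transcripts.append(
            TranscriptRecord(id=tid, seq="".join(seq), cds_start=cds_start, cds_end=cds_end)
        )
    return transcripts


def make_degradome_library(
    cfg: SynthConfig,
    truth: SynthTruth,
    transcripts: Sequence[TranscriptRecord],
) -> list[CollapsedRead]:
    """Simulate the degradome tag library (20-21-nt 5'-end tags).

    Planted events contribute a high-abundance tag whose 5' end sits at the
    recorded cleavage position; background tags arise per position as
    Poisson draws with mean ``peak/ratio`` damped by a 5'->3' exponential
    decay, emulating general exonucleolytic turnover.
    """
    rng = _stream(cfg, "degradome")
    seqs = {t.id: t.seq for t in transcripts}
    counts: dict[str, int] = {}

    def _add_tag(tseq: str, pos: int, n: int) -> None:
        ln = 20 if rng.random() < 0.5 else 21
        if pos - 1 + ln > len(tseq) or n <= 0:
            return
        tag = tseq[pos - 1 : pos - 1 + ln]
        counts[tag] = counts.get(tag, 0) + int(n)

    mean_peak = sum(cfg.planted_peak_range) / 2
    bg_mean = mean_peak / cfg.peak_to_background_ratio

    for t in transcripts:
        n_pos = len(t.seq) - 21
        lam = bg_mean * np.exp(-cfg.background_decay_rate * np.arange(n_pos))
        draws = rng.poisson(lam)
        for p in np.nonzero(draws)[0]:
            _add_tag(t.seq, int(p) + 1, int(draws[p]))

    for ev in truth.cleavages:
        _add_tag(seqs[ev.transcript_id], ev.cleave_pos, ev.planted_count)

    reads = [CollapsedRead(seq=s, count=c) for s, c in counts.items()]
    reads.sort(key=lambda r: (-r.count, r.seq))
    return reads
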