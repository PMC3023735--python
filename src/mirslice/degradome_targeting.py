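"""Degradome (PARE) target identification and classification.

Degradome tags are 20-21-nt 5' ends of uncapped mRNA 3' fragments; a tag's
5' position marks an endonucleolytic cleavage site. For every distinct
(transcript, 5'-end) position a 30-nt "t-signature" is extracted (15 nt of
context on each side). Candidate miRNAs are aligned anti-parallel to the
signature region; plant AGO slicing occurs between the target bases paired
to miRNA positions 10 and 11, so a validated call requires the tag's 5' end
to sit exactly opposite miRNA position 10 with a perfectly paired 10/11.

Alignment scoring follows the plant-standard degradome scheme: mismatch 1,
G:U wobble 0.5, single-nucleotide gap 1, every penalty doubled inside the
5' core (miRNA positions 2-13), with alignments rejected above a total of 7.

Validated targets are tiered by the cleavage signature's abundance relative
to all signatures on the transcript:

* Class I   — the only signatures on the transcript are miRNA-directed;
* Class II  — the cleavage signature ties the transcript maximum;
* Class III — above the (lower) median signature abundance;
* Class IV  — everything else.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .read_mapper import MappedHit
from .seq_io import CollapsedRead, TranscriptRecord, rp10m

__all__ = [
    "TSignature",
    "TargetAlignment",
    "TargetCall",
    "build_signatures",
    "score_alignment",
    "call_targets",
    "classify_target",
    "classify_all",
    "locate_site_region",
    "emit_target_table",
    "tplot_data",
]

SIGNATURE_HALF_WINDOW = 15
SCORE_MAX = 7.0
CORE_START, CORE_END = 2, 13  # miRNA positions with doubled penalties
CLEAVAGE_POSITIONS = (10, 11)  # must be perfectly paired
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 1.0

_COMPLEMENT = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA G : target U, miRNA U : target G


@dataclass(frozen=True)
class TSignature:
    """A degradome 5'-end position on a transcript with its 30-nt context."""

    transcript_id: str
    cleave_pos: int  # 1-based transcript coordinate of the tag 5' end
    tag30: str
    count: int
    tp10m: float

    def __post_init__(self):
        if len(self.tag30) != 2 * SIGNATURE_HALF_WINDOW:
            raise ValueError("t-signature must be 30 nt")


@dataclass(frozen=True)
class TargetAlignment:
    mirna_id: str
    mirna_seq: str  # 5'->3'
    transcript_id: str
    site_start: int  # 1-based transcript coords of the aligned site
    site_end: int
    score: float
    states: tuple[str, ...]  # per miRNA position: match / wobble / mismatch / gap
    pos10_target: int  # transcript coordinate paired with miRNA position 10


@dataclass
class TargetCall:
    alignment: TargetAlignment
    cleave_pos: int
    cleave_count: int
    cleave_abundance: float  # tp10m
    class_label: str = ""
    site_region: str = ""


# ---------------------------------------------------------------------------
# signature construction


def build_signatures(
    transcripts: Sequence[TranscriptRecord],
    tag_hits: Iterable[tuple[MappedHit, int]],
    library_total: int,
) -> list[TSignature]:
    """Aggregate sense-mapped degradome tags into per-position signatures.

    ``tag_hits`` yields (hit, raw count); counts of tags sharing a 5' end on
    a transcript are summed (a multi-hit tag contributes its full count at
    every position it maps to). Positions with fewer than 15 nt of context
    on either side are dropped; ``library_total`` must be the whole-library
    tag total so normalization is unaffected by the dropped positions.
    """
    seqs = {t.id: t.seq for t in transcripts}
    by_pos: dict[tuple[str, int], int] = defaultdict(int)
    for hit, count in tag_hits:
        if hit.strand != "+":
            raise ValueError("degradome tags must be sense-mapped")
        by_pos[(hit.ref_id, hit.pos)] += count

    out = []
    for (tid, pos), count in sorted(by_pos.items()):
        seq = seqs[tid]
        if pos - SIGNATURE_HALF_WINDOW < 1 or pos + SIGNATURE_HALF_WINDOW - 1 > len(seq):
            continue  # insufficient context; excluded from signatures, kept in total
        tag30 = seq[pos - SIGNATURE_HALF_WINDOW - 1 : pos + SIGNATURE_HALF_WINDOW - 1]
        out.append(
            TSignature(
                transcript_id=tid,
                cleave_pos=pos,
                tag30=tag30,
                count=count,
                tp10m=rp10m(count, library_total),
            )
        )
    return out


# ---------------------------------------------------------------------------
# alignment scoring


def _pair_state(mirna_base: str, target_base: str) -> str:
    key = (mirna_base, target_base)
    if key in _COMPLEMENT:
        return "match"
    if key in _WOBBLE:
        return "wobble"
    return "mismatch"


def _penalty(state: str, mirna_pos: float) -> float:
    if state == "match":
        p = 0.0
    elif state == "wobble":
        p = WOBBLE_PENALTY
    elif state == "mismatch":
        p = MISMATCH_PENALTY
    else:  # gap
        p = GAP_PENALTY
    if p and CORE_START <= mirna_pos <= CORE_END:
        p *= 2.0
    return p


def _score_ungapped(mirna: str, site: str) -> tuple[float, list[str], dict[int, int]]:
    """Anti-parallel ungapped comparison; site and miRNA same length.

    Returns (score, per-miRNA-position states, miRNA pos -> site index map,
    site index 1-based from the site 5' end).
    """
    n = len(mirna)
    states, score = [], 0.0
    posmap = {}
    for i in range(1, n + 1):
        t_idx = n - i + 1  # miRNA pos 1 pairs the site's 3'-most base
        st = _pair_state(mirna[i - 1], site[t_idx - 1])
        states.append(st)
        score += _penalty(st, i)
        posmap[i] = t_idx
    return score, states, posmap


def _gap_alignments(mirna: str, site: str):
    """Enumerate single-gap anti-parallel alignments.

    If the site is one base longer than the miRNA, one site base is bulged
    (gap in the miRNA strand); one base shorter, one miRNA base is bulged
    (gap in the target strand). Yields (score, states, posmap, gap_pos) per
    gap placement; ``gap_pos`` is the miRNA coordinate of the bulge (g + 0.5
    for a site bulge between miRNA positions g and g+1), which decides the
    doubled-core surcharge and the cleavage-site rejection.
    """
    n, m = len(mirna), len(site)
    if m == n + 1:
        # bulged site base between miRNA positions g and g+1 (g in 0..n)
        for g in range(0, n + 1):
            score, states, posmap = 0.0, [], {}
            # miRNA positions 1..g pair the site's 3' side; g+1..n shift by one
            for i in range(1, n + 1):
                t_idx = m - i + 1 if i <= g else m - i
                st = _pair_state(mirna[i - 1], site[t_idx - 1])
                states.append(st)
                score += _penalty(st, i)
                posmap[i] = t_idx
            gap_pos = g + 0.5
            score += _penalty("gap", gap_pos)
            yield score, states, posmap, gap_pos
    elif m == n - 1:
        # miRNA position g is bulged (pairs nothing)
        for g in range(1, n + 1):
            score, states, posmap = 0.0, [], {}
            for i in range(1, n + 1):
                if i == g:
                    states.append("gap")
                    score += _penalty("gap", i)
                    continue
                t_idx = m - i + 1 if i < g else m - i + 2
                st = _pair_state(mirna[i - 1], site[t_idx - 1])
                states.append(st)
                score += _penalty(st, i)
                posmap[i] = t_idx
            yield score, states, posmap, float(g)


def score_alignment(
    mirna: str,
    site: str,
    allow_gap: bool = False,
    score_max: float = SCORE_MAX,
) -> Optional[tuple[float, list[str], dict[int, int]]]:
    """Score one miRNA against one candidate target site (both 5'->3').

    Returns (score, states, posmap) for the best admissible alignment, or
    None if every alignment is rejected. ``posmap`` maps miRNA positions to
    1-based site indices. Rejection: total score above ``score_max``, or any
    non-match state (mismatch, wobble or gap) at miRNA positions 10 or 11 —
    the duplex flanking the scissile bond must be perfectly paired.
    """
    if not (18 <= len(mirna) <= 25):
        raise ValueError("miRNA length outside 18-25 nt")
    for s in (mirna, site):
        if set(s) - set("ACGT"):
            raise ValueError("sequences must be over {A,C,G,T}")

    candidates: list[tuple[float, list[str], dict[int, int], Optional[float]]] = []
    if len(site) == len(mirna):
        sc, st, pm = _score_ungapped(mirna, site)
        candidates.append((sc, st, pm, None))
    elif allow_gap and abs(len(site) - len(mirna)) == 1:
        candidates.extend(_gap_alignments(mirna, site))
    else:
        return None

    best = None
    lo, hi = CLEAVAGE_POSITIONS
    for score, states, posmap, gap_pos in candidates:
        if any(states[p - 1] != "match" for p in CLEAVAGE_POSITIONS):
            continue
        if gap_pos is not None and lo <= gap_pos <= hi:
            continue  # bulged site base between the cleavage-site pairs
        if score > score_max:
            continue
        if best is None or score < best[0]:
            best = (score, states, posmap)
    return best


# ---------------------------------------------------------------------------
# target calling


def call_targets(
    mirnas: Mapping[str, str] | Sequence[tuple[str, str]],
    signatures: Sequence[TSignature],
    transcripts: Sequence[TranscriptRecord],
    allow_gap: bool = False,
    score_max: float = SCORE_MAX,
) -> list[TargetCall]:
    """Call miRNA-directed cleavage events (unclassified).

    For each signature and each miRNA, the candidate site is the transcript
    window whose base at the signature's 5'-end position pairs miRNA
    position 10 (site 3' end = cleave_pos + 9); with gaps enabled, sites one
    base shorter/longer are also tried and the accepted alignment must still
    place the cleavage position opposite miRNA position 10.
    """
    if not mirnas:
        raise ValueError("miRNA set is empty")
    mirna_items = list(mirnas.items()) if isinstance(mirnas, Mapping) else list(mirnas)
    seqs = {t.id: t.seq for t in transcripts}

    calls: list[TargetCall] = []
    for sig in signatures:
        tseq = seqs[sig.transcript_id]
        if sig.cleave_pos < 2:
            continue
        # bases paired to miRNA positions 10 (the tag 5' end) and 11
        t10, t11 = tseq[sig.cleave_pos - 1], tseq[sig.cleave_pos - 2]
        for mid, mseq in mirna_items:
            # cheap rejection: positions 10/11 must be Watson-Crick paired
            if (mseq[9], t10) not in _COMPLEMENT or (mseq[10], t11) not in _COMPLEMENT:
                continue
            n = len(mseq)
            site_lens = [n] if not allow_gap else [n, n - 1, n + 1]
            best: Optional[TargetAlignment] = None
            for L in site_lens:
                end = sig.cleave_pos + 9  # pairs miRNA position 10 at cleave_pos
                start = end - L + 1
                if start < 1 or end > len(tseq):
                    continue
                site = tseq[start - 1 : end]
                res = score_alignment(mseq, site, allow_gap=(L != n), score_max=score_max)
                if res is None:
                    continue
                score, states, posmap = res
                # the base opposite miRNA position 10 must be the tag 5' end
                if start - 1 + posmap[10] != sig.cleave_pos:
                    continue
                if best is None or score < best.score:
                    best = TargetAlignment(
                        mirna_id=mid,
                        mirna_seq=mseq,
                        transcript_id=sig.transcript_id,
                        site_start=start,
                        site_end=end,
                        score=score,
                        states=tuple(states),
                        pos10_target=start - 1 + posmap[10],
                    )
            if best is not None:
                calls.append(
                    TargetCall(
                        alignment=best,
                        cleave_pos=sig.cleave_pos,
                        cleave_count=sig.count,
                        cleave_abundance=sig.tp10m,
                    )
                )
    calls.sort(key=lambda c: (c.alignment.mirna_id, c.alignment.transcript_id, c.cleave_pos))
    return calls


# ---------------------------------------------------------------------------
# classification


def _lower_median(values: Sequence[float]) -> float:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def classify_target(
    call: TargetCall,
    all_signatures_on_transcript: Sequence[TSignature],
    mirna_directed_positions: Optional[set[int]] = None,
) -> str:
    """Assign the confidence class of one validated cleavage event.

    Precedence I > II > III > IV. Class I requires every signature position
    on the transcript to be attributable to an accepted miRNA call
    (``mirna_directed_positions``; defaults to just this call's position).
    Class II: the cleavage abundance ties the transcript maximum. Class III:
    strictly above the lower median of all per-position abundances
    (cleavage position included). Class IV: the rest.
    """
    sigs = [s for s in all_signatures_on_transcript if s.transcript_id == call.alignment.transcript_id]
    positions = {s.cleave_pos: s.tp10m for s in sigs}
    if call.cleave_pos not in positions:
        raise ValueError("cleavage position absent from the transcript's signatures")

    directed = mirna_directed_positions or {call.cleave_pos}
    if set(positions) <= directed:
        return "I"
    abundances = list(positions.values())
    if call.cleave_abundance >= max(abundances):
        return "II"
    if call.cleave_abundance > _lower_median(abundances):
        return "III"
    return "IV"


def classify_all(
    calls: Sequence[TargetCall], signatures: Sequence[TSignature]
) -> list[TargetCall]:
    """Classify every call, pooling miRNA-directed positions per transcript."""
    sigs_by_tid: dict[str, list[TSignature]] = defaultdict(list)
    for s in signatures:
        sigs_by_tid[s.transcript_id].append(s)
    directed_by_tid: dict[str, set[int]] = defaultdict(set)
    for c in calls:
        directed_by_tid[c.alignment.transcript_id].add(c.cleave_pos)

    out = []
    for c in calls:
        tid = c.alignment.transcript_id
        c = replace(c)
        c.class_label = classify_target(c, sigs_by_tid[tid], directed_by_tid[tid])
        out.append(c)
    return out


def locate_site_region(transcript: TranscriptRecord, cleave_pos: int) -> str:
    """5'UTR / CDS / 3'UTR from the CDS bounds; "unknown" without them."""
    if not (1 <= cleave_pos <= len(transcript.seq)):
        raise ValueError("cleavage position outside the transcript")
    if transcript.cds_start is None:
        return "unknown"
    if cleave_pos < transcript.cds_start:
        return "5'UTR"
    if cleave_pos <= transcript.cds_end:
        return "CDS"
    return "3'UTR"


# ---------------------------------------------------------------------------
# reporting


def emit_target_table(
    calls: Sequence[TargetCall],
    annotations: Optional[Mapping[str, str]] = None,
) -> list[tuple]:
    """Rows (miRNA, target, annotation, class, abundance TP10M, site, region).

    Validated cleavage positions of one (miRNA, transcript) pair that are
    adjacent on the transcript — both ends of one scissile region — are
    merged into a single row with an "a/b" site, keeping the more abundant
    position's class and abundance.
    """
    annotations = annotations or {}
    groups: dict[tuple[str, str], list[TargetCall]] = defaultdict(list)
    for c in calls:
        groups[(c.alignment.mirna_id, c.alignment.transcript_id)].append(c)

    rows = []
    for (mid, tid) in sorted(groups):
        group = sorted(groups[(mid, tid)], key=lambda c: c.cleave_pos)
        i = 0
        while i < len(group):
            run = [group[i]]
            while i + 1 < len(group) and group[i + 1].cleave_pos == run[-1].cleave_pos + 1:
                run.append(group[i + 1])
                i += 1
            i += 1
            lead = max(run, key=lambda c: c.cleave_abundance)
            site = "/".join(str(c.cleave_pos) for c in run)
            rows.append(
                (
                    mid,
                    tid,
                    annotations.get(tid, ""),
                    lead.class_label,
                    round(lead.cleave_abundance, 1),
                    site,
                    lead.site_region,
                )
            )
    return rows


def tplot_data(
    transcript_id: str,
    signatures: Sequence[TSignature],
    cleavage_positions: set[int],
) -> list[tuple[int, float, int]]:
    """Per-position (position, tp10m, is_cleavage_site) rows for t-plots."""
    return [
        (s.cleave_pos, s.tp10m, int(s.cleave_pos in cleavage_positions))
        for s in sorted(signatures, key=lambda s: s.cleave_pos)
        if s.transcript_id == transcript_id
    ]
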