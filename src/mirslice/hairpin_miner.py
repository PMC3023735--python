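"""Novel miRNA discovery from hairpin-forming genomic windows.

The discovery logic mirrors the classic plant small-RNA workflow: extract
150-nt flanks around unannotated read loci, fold each window, locate the
miRNA* partner of the most abundant read, and accept the locus as a miRNA
candidate when the miRNA:miRNA* duplex has at least 16 matched nucleotide
pairs and the two strands differ in length by at most 4 nt.

The fold engine is a constrained base-pair maximization (Nussinov-style
dynamic program: canonical plus G:U pairs, minimum hairpin loop of 3, no
pseudoknots) with a deterministic traceback. The candidate filters are
structural counts, not free energies, so a maximum-pairing structure is the
appropriate backbone; an external thermodynamic folder can be plugged in as
a callable returning dot-bracket, and any structure it returns is consumed
through the same ``FoldResult`` interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .read_mapper import MappedHit
from .seq_io import CollapsedRead, SequenceRecord, revcomp

__all__ = [
    "FoldResult",
    "DuplexStats",
    "CandidateWindow",
    "HairpinCandidate",
    "extract_flanks",
    "merge_windows",
    "fold",
    "fold_from_dotbracket",
    "find_star",
    "evaluate_candidate",
    "detect_known_stars",
    "viennarna_engine",
]

MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 400
MIN_LOOP = 3
DEFAULT_FLANK = 150
MIN_MATCHED_PAIRS = 16
MAX_SIZE_DIFF = 4
STAR_END_TOLERANCE = 2  # nt slack at each end when matching observed star reads

# allowed duplex pairs in the DNA alphabet (G:T encodes the G:U wobble)
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass
class FoldResult:
    """A secondary structure: dot-bracket plus an explicit 1-based pair set."""

    seq: str
    structure: str
    pairs: frozenset[tuple[int, int]]

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DuplexStats:
    matched_pairs: int
    size_diff: int
    overhang3: int = 2


@dataclass(frozen=True)
class CandidateWindow:
    """A sense-normalized genomic window hosting a putative precursor.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates; for
    strand '-', ``seq`` is the reverse complement of the forward reference
    slice so that mapped reads appear verbatim.
    """

    ref_id: str
    start: int
    end: int
    strand: str
    seq: str


@dataclass
class HairpinCandidate:
    window: CandidateWindow
    fold: Optional[FoldResult]
    mature: Optional[tuple[int, int]]  # 1-based inclusive within window
    star: Optional[tuple[int, int]]
    duplex: Optional[DuplexStats]
    mature_seq: str = ""
    mature_count: int = 0
    star_seq: str = ""
    star_count: int = 0
    accepted: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# window extraction


def extract_flanks(
    genome: Sequence[SequenceRecord] | Mapping[str, str],
    hit: MappedHit,
    flank: int = DEFAULT_FLANK,
) -> list[CandidateWindow]:
    """Two candidate windows per hit: the read plus ``flank`` nt upstream, and
    the read plus ``flank`` nt downstream (each window always covers the
    read). Windows are truncated at reference ends; minus-strand windows are
    reverse-complemented so the read reads sense.

    Up/downstream are in read orientation: for a '-' hit the upstream flank
    lies at higher forward coordinates.
    """
    refs = genome if isinstance(genome, Mapping) else {r.id: r.seq for r in genome}
    ref = refs[hit.ref_id]
    read_len = len(hit.read_seq)
    r_start, r_end = hit.pos, hit.pos + read_len - 1

    if hit.strand == "+":
        spans = [(r_start - flank, r_end), (r_start, r_end + flank)]
    else:
        spans = [(r_start, r_end + flank), (r_start - flank, r_end)]

    windows = []
    for s, e in spans:
        s, e = max(1, s), min(len(ref), e)
        seq = ref[s - 1 : e]
        if hit.strand == "-":
            seq = revcomp(seq)
        windows.append(CandidateWindow(hit.ref_id, s, e, hit.strand, seq))
    return windows


def merge_windows(windows: Sequence[CandidateWindow], refs: Mapping[str, str]) -> list[CandidateWindow]:
    """Merge overlapping windows on the same reference and strand into one
    candidate locus (one candidate per merged locus per strand)."""
    merged: list[CandidateWindow] = []
    for w in sorted(windows, key=lambda w: (w.ref_id, w.strand, w.start, w.end)):
        if (
            merged
            and merged[-1].ref_id == w.ref_id
            and merged[-1].strand == w.strand
            and w.start <= merged[-1].end + 1
        ):
            prev = merged[-1]
            s, e = prev.start, max(prev.end, w.end)
            seq = refs[w.ref_id][s - 1 : e]
            if w.strand == "-":
                seq = revcomp(seq)
            merged[-1] = CandidateWindow(w.ref_id, s, e, w.strand, seq)
        else:
            merged.append(w)
    return merged


# ---------------------------------------------------------------------------
# fold engine


def _pair_matrix(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    a = codes[:, None]
    b = codes[None, :]
    A, C, G, T = (ord(x) for x in "ACGT")
    return (
        ((a == A) & (b == T))
        | ((a == T) & (b == A))
        | ((a == G) & (b == C))
        | ((a == C) & (b == G))
        | ((a == G) & (b == T))
        | ((a == T) & (b == G))
    )


def fold(
    seq: str,
    engine: Optional[Callable[[str], str]] = None,
    check_length: bool = True,
) -> FoldResult:
    """Fold a candidate precursor.

    Default engine: maximum base pairing under the constraints (canonical +
    G:U pairs, hairpin loops >= 3 nt, nested structures only). Among
    co-optimal structures the deterministic traceback follows the one with
    the most stacked pairs. ``engine`` may be any callable mapping a
    sequence to a dot-bracket string (e.g. a thermodynamic folder); its
    output is validated and converted. ``check_length`` enforces the
    precursor-window range; disable it to fold short fragments.
    """
    n = len(seq)
    if check_length and not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise ValueError(f"fold input length {n} outside [{MIN_FOLD_LEN},{MAX_FOLD_LEN}]")
    if engine is not None:
        return fold_from_dotbracket(seq, engine(seq))
    return _nussinov(seq)


# Pair count is the primary objective; among co-optimal structures the
# traceback follows the one with the most stacked pairs (helix contiguity),
# which is what distinguishes a genuine precursor stem from the incidental
# scattered pairing a max-pairing objective alone would accept. Scores are
# packed lexicographically as pairs * _STACK_BASE + stacks; both components
# are additive under concatenation, so the packed values add like the DP.
_STACK_BASE = 1024
_NEG = -(1 << 24)


def _nussinov(seq: str) -> FoldResult:
    n = len(seq)
    P = _pair_matrix(seq)
    W = np.zeros((n, n), dtype=np.int32)  # packed best over s[i..j]
    V = np.full((n, n), _NEG, dtype=np.int32)  # packed best with (i,j) paired

    idx = np.arange(n)
    for d in range(MIN_LOOP + 1, n):
        ii = idx[: n - d]
        jj = ii + d
        # V[i, j]: (i,j) paired around the inner segment [i+1, j-1]
        if d == MIN_LOOP + 1:
            inner = np.zeros(len(ii), dtype=np.int32)
        else:
            w_in = W[ii + 1, jj - 1]
            v_in = V[ii + 1, jj - 1]
            stacked = v_in + 1  # one more stack when the inner pair closes flush
            same_pairs = (v_in // _STACK_BASE) == (w_in // _STACK_BASE)
            inner = np.where(same_pairs & (stacked > w_in), stacked, w_in)
        V[ii, jj] = np.where(P[ii, jj], _STACK_BASE + inner, _NEG)

        best = W[ii, jj - 1].copy()  # j unpaired
        for t in range(0, d - MIN_LOOP):  # j paired with k = i + t
            left = W[ii, ii + t - 1] if t >= 1 else np.zeros(len(ii), dtype=np.int32)
            np.maximum(best, left + V[ii + t, jj], out=best)
        W[ii, jj] = best

    pairs: set[tuple[int, int]] = set()
    work: list[tuple[int, int, bool]] = [(0, n - 1, False)]
    while work:
        i, j, closed = work.pop()
        if j - i <= MIN_LOOP and not closed:
            continue
        if closed:
            pairs.add((i + 1, j + 1))
            if j - 1 - (i + 1) < MIN_LOOP + 1:
                if j - 1 - (i + 1) > MIN_LOOP:
                    work.append((i + 1, j - 1, False))
                continue
            w_in, v_in = W[i + 1, j - 1], V[i + 1, j - 1]
            stacked_ok = (
                v_in > _NEG
                and (v_in // _STACK_BASE) == (w_in // _STACK_BASE)
                and v_in + 1 > w_in
            )
            if V[i, j] == _STACK_BASE + (v_in + 1 if stacked_ok else w_in) and stacked_ok:
                work.append((i + 1, j - 1, True))
            else:
                work.append((i + 1, j - 1, False))
            continue
        if W[i, j] == W[i, j - 1]:
            work.append((i, j - 1, False))
            continue
        target = W[i, j]
        for k in range(i, j - MIN_LOOP):
            if V[k, j] <= _NEG:
                continue
            left = W[i, k - 1] if k > i else 0
            if left + V[k, j] == target:
                if k > i:
                    work.append((i, k - 1, False))
                work.append((k, j, True))
                break

    structure = ["."] * n
    for i, j in pairs:
        structure[i - 1] = "("
        structure[j - 1] = ")"
    return FoldResult(seq=seq, structure="".join(structure), pairs=frozenset(pairs))


def fold_from_dotbracket(seq: str, structure: str) -> FoldResult:
    """Validate a dot-bracket string against a sequence and build FoldResult."""
    if len(structure) != len(seq):
        raise ValueError("structure length differs from sequence length")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced brackets")
            i = stack.pop()
            if pos - i - 1 < MIN_LOOP:
                raise ValueError(f"hairpin loop shorter than {MIN_LOOP} at pair ({i},{pos})")
            if not can_pair(seq[i - 1], seq[pos - 1]):
                raise ValueError(f"disallowed pair {seq[i-1]}:{seq[pos-1]} at ({i},{pos})")
            pairs.add((i, pos))
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced brackets")
    return FoldResult(seq=seq, structure=structure, pairs=frozenset(pairs))


def viennarna_engine(seq: str) -> str:
    """Optional external-folder plug-in: minimum-free-energy dot-bracket from
    the ViennaRNA bindings, usable as ``fold(seq, engine=viennarna_engine)``."""
    import RNA  # deferred: optional plug-in

    structure, _ = RNA.fold(seq.replace("T", "U"))
    return structure


# ---------------------------------------------------------------------------
# duplex analysis


def find_star(fold_result: FoldResult, mature: tuple[int, int]) -> Optional[tuple[int, int]]:
    """Predict the miRNA* interval for a mature interval (1-based inclusive).

    The star spans the positions pairing with the mature, shifted 3' by two
    positions so each duplex end carries the canonical 2-nt 3' overhang.
    Returns None when the mature is unpaired, spans the terminal loop, or
    pairs onto both sides of itself.
    """
    m5, m3 = mature
    if not (1 <= m5 <= m3 <= len(fold_result.seq)):
        raise ValueError("mature interval outside the folded sequence")
    partner = fold_result.partner()
    partners = [partner[p] for p in range(m5, m3 + 1) if p in partner]
    if not partners:
        return None
    if any(m5 <= q <= m3 for q in partners):
        return None  # mature pairs with itself: spans the terminal loop
    if not (all(q < m5 for q in partners) or all(q > m3 for q in partners)):
        return None  # partners on both arms
    s5 = min(partners) + 2
    s3 = max(partners) + 2
    s5 = max(1, min(s5, len(fold_result.seq)))
    s3 = max(1, min(s3, len(fold_result.seq)))
    if s3 - s5 < 2:
        return None
    return (s5, s3)


def _duplex_stats(
    fold_result: FoldResult, mature: tuple[int, int], star: tuple[int, int]
) -> DuplexStats:
    partner = fold_result.partner()
    m5, m3 = mature
    matched = sum(
        1 for p in range(m5, m3 + 1) if p in partner and not (m5 <= partner[p] <= m3)
    )
    mature_len = m3 - m5 + 1
    star_len = star[1] - star[0] + 1
    return DuplexStats(matched_pairs=matched, size_diff=abs(mature_len - star_len))


def evaluate_candidate(
    window: CandidateWindow,
    reads: Sequence[CollapsedRead],
    min_matched_pairs: int = MIN_MATCHED_PAIRS,
    max_size_diff: int = MAX_SIZE_DIFF,
    engine: Optional[Callable[[str], str]] = None,
) -> HairpinCandidate:
    """Fold a window and apply the duplex acceptance criteria.

    The putative mature is the most abundant read occurring in the window
    (ties broken lexicographically); acceptance requires a located star on
    the opposite arm, matched pairs >= ``min_matched_pairs`` and strand size
    difference <= ``max_size_diff``. The first failed criterion is recorded
    as the rejection reason.
    """
    cand = HairpinCandidate(window=window, fold=None, mature=None, star=None, duplex=None)

    present = [r for r in reads if r.seq in window.seq]
    if not present:
        cand.reason = "no_reads"
        return cand
    mature_read = min(present, key=lambda r: (-r.count, r.seq))
    cand.mature_seq, cand.mature_count = mature_read.seq, mature_read.count

    if len(window.seq) < MIN_FOLD_LEN or len(window.seq) > MAX_FOLD_LEN:
        cand.reason = "window_length_out_of_range"
        return cand
    fr = fold(window.seq, engine=engine)
    cand.fold = fr

    m0 = window.seq.find(mature_read.seq)
    mature = (m0 + 1, m0 + len(mature_read.seq))
    cand.mature = mature

    star = find_star(fr, mature)
    if star is None:
        cand.reason = "no_star_arm"
        return cand
    cand.star = star
    cand.star_seq = window.seq[star[0] - 1 : star[1]]

    stats = _duplex_stats(fr, mature, star)
    cand.duplex = stats
    cand.star_count = _observed_star_count(window.seq, star, present, exclude=mature_read.seq)

    if stats.matched_pairs < min_matched_pairs:
        cand.reason = f"matched_pairs<{min_matched_pairs}"
        return cand
    if stats.size_diff > max_size_diff:
        cand.reason = f"size_diff>{max_size_diff}"
        return cand
    cand.accepted = True
    cand.reason = "accepted"
    return cand


def _observed_star_count(
    window_seq: str,
    star: tuple[int, int],
    reads: Sequence[CollapsedRead],
    exclude: str = "",
    tol: int = STAR_END_TOLERANCE,
) -> int:
    total = 0
    for r in reads:
        if r.seq == exclude:
            continue
        pos = window_seq.find(r.seq)
        while pos >= 0:
            s, e = pos + 1, pos + len(r.seq)
            if abs(s - star[0]) <= tol and abs(e - star[1]) <= tol:
                total += r.count
                break
            pos = window_seq.find(r.seq, pos + 1)
    return total


def detect_known_stars(
    known_precursors: Sequence[SequenceRecord],
    known_matures: Mapping[str, str],
    reads: Sequence[CollapsedRead],
    engine: Optional[Callable[[str], str]] = None,
) -> list[tuple[str, str, int]]:
    """Detect sequenced miRNA* species for known precursors.

    ``known_matures`` maps precursor id -> mature sequence. For each
    precursor the star interval is predicted from the fold and reads whose
    ends coincide with it within +/-2 nt are summed. Precursors whose mature
    cannot be located are skipped with a warning entry omitted from output.
    Stars more abundant than their matures are still reported as stars;
    relabeling (a star that is itself a functional miRNA) is the caller's
    interpretation.
    """
    out: list[tuple[str, str, int]] = []
    for prec in known_precursors:
        mature = known_matures.get(prec.id)
        if mature is None:
            continue
        m0 = prec.seq.find(mature)
        if m0 < 0:
            import warnings

            warnings.warn(f"mature not found in precursor {prec.id!r}; skipped")
            continue
        fr = fold(prec.seq, engine=engine)
        star = find_star(fr, (m0 + 1, m0 + len(mature)))
        if star is None:
            continue
        best_seq, total = "", 0
        for r in sorted(reads, key=lambda r: (-r.count, r.seq)):
            if r.seq == mature:
                continue
            pos = prec.seq.find(r.seq)
            if pos < 0:
                continue
            s, e = pos + 1, pos + len(r.seq)
            if abs(s - star[0]) <= STAR_END_TOLERANCE and abs(e - star[1]) <= STAR_END_TOLERANCE:
                if not best_seq:
                    best_seq = r.seq
                total += r.count
        if total > 0:
            out.append((prec.id, best_seq, total))
    return out


def write_candidate_report(candidates: Sequence[HairpinCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref\tstart\tend\tstrand\tverdict\treason\tmatched_pairs\tsize_diff\t"
            "mature_seq\tmature_count\tstar_seq\tstar_count\n"
        )
        for c in candidates:
            w = c.window
            mp = c.duplex.matched_pairs if c.duplex else ""
            sd = c.duplex.size_diff if c.duplex else ""
            verdict = "accepted" if c.accepted else "rejected"
            fh.write(
                f"{w.ref_id}\t{w.start}\t{w.end}\t{w.strand}\t{verdict}\t{c.reason}\t"
                f"{mp}\t{sd}\t{c.mature_seq}\t{c.mature_count}\t{c.star_seq}\t{c.star_count}\n"
            )


def write_vienna(candidates: Sequence[HairpinCandidate], path) -> None:
    """Precursor structures in Vienna format (header, RNA sequence, dot-bracket)."""
    with open(path, "w") as fh:
        for c in candidates:
            if c.fold is None:
                continue
            w = c.window
            fh.write(f">{w.ref_id}:{w.start}-{w.end}({w.strand})\n")
            fh.write(c.fold.seq.replace("T", "U") + "\n")
            fh.write(c.fold.structure + "\n")
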