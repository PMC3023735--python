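"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: folding is checked by
leftmost-decomposition enumeration of all admissible structures, alignment
scoring by explicit enumeration of every gap placement, mapping by a full
substring scan, and classification by a direct max/median recomputation via
the statistics module.
"""

from statistics import median_low

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOB = {("G", "T"), ("T", "G")}


def max_pairs_enumeration(seq: str) -> int:
    """Maximum number of base pairs over all nested structures with hairpin
    loops >= 3, by leftmost-position decomposition."""
    memo: dict[tuple[int, int], int] = {}

    def go(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        key = (i, j)
        if key in memo:
            return memo[key]
        best = go(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                best = max(best, 1 + go(i + 1, k - 1) + go(k + 1, j))
        memo[key] = best
        return best

    return go(0, len(seq) - 1)


def _pen(kind: str, pos: float) -> float:
    base = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0, "gap": 1.0}[kind]
    return base * 2 if (base and 2 <= pos <= 13) else base


def _state(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "match"
    if (m, t) in _WOB:
        return "wobble"
    return "mismatch"


def best_alignment_enumeration(mirna: str, site: str, score_max: float = 7.0):
    """Minimum admissible alignment score (or None) over every gap placement.

    Anti-parallel: miRNA position 1 pairs the site's 3'-most base. Admissible
    alignments have perfect Watson-Crick pairs at miRNA positions 10 and 11,
    no bulge between them, and total score <= score_max.
    """
    n, m = len(mirna), len(site)
    options = []

    if m == n:
        rsite = site[::-1]
        score, states = 0.0, []
        for i in range(1, n + 1):
            st = _state(mirna[i - 1], rsite[i - 1])
            states.append(st)
            score += _pen(st, i)
        options.append((score, states, None))
    elif m == n + 1:
        for skip in range(m):  # site index (0-based) left bulged
            kept = site[:skip] + site[skip + 1 :]
            rkept = kept[::-1]
            # bases 3' of the bulge pair miRNA positions 1..(m-1-skip)
            gap_pos = (m - 1 - skip) + 0.5
            score, states = _pen("gap", gap_pos), []
            for i in range(1, n + 1):
                st = _state(mirna[i - 1], rkept[i - 1])
                states.append(st)
                score += _pen(st, i)
            options.append((score, states, gap_pos))
    elif m == n - 1:
        for g in range(1, n + 1):  # miRNA position g bulged
            rsite = site[::-1]
            score, states = 0.0, []
            ti = 0
            for i in range(1, n + 1):
                if i == g:
                    states.append("gap")
                    score += _pen("gap", i)
                    continue
                st = _state(mirna[i - 1], rsite[ti])
                ti += 1
                states.append(st)
                score += _pen(st, i)
            options.append((score, states, float(g)))
    else:
        return None

    best = None
    for score, states, gap_pos in options:
        if states[9] != "match" or states[10] != "match":
            continue
        if gap_pos is not None and 10 <= gap_pos <= 11:
            continue
        if score > score_max:
            continue
        if best is None or score < best:
            best = score
    return best


def scan_hits(read: str, refs: dict[str, str], both_strands: bool = True):
    """All exact full-length placements by scanning every offset."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(read))
    out = []
    for rid, ref in refs.items():
        for i in range(len(ref) - len(read) + 1):
            if ref[i : i + len(read)] == read:
                out.append((rid, i + 1, "+"))
            if both_strands and ref[i : i + len(read)] == rc:
                out.append((rid, i + 1, "-"))
    return sorted(out)


def classify_direct(
    abundance_by_pos: dict[int, float], cleave_pos: int, directed: set[int]
) -> str:
    """Direct recomputation of the Class I-IV rules."""
    if set(abundance_by_pos) <= directed:
        return "I"
    ab = abundance_by_pos[cleave_pos]
    values = list(abundance_by_pos.values())
    if ab >= max(values):
        return "II"
    if ab > median_low(values):
        return "III"
    return "IV"
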