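# Methods

This note documents the models and procedures implemented in `mirslice`,
the defaults they run with, and what the synthetic-data tests do and do not
demonstrate about real libraries.

## Read preprocessing and bookkeeping

Raw reads are adapter-clipped against a configurable 3' adapter: the insert
is the prefix before the leftmost exact adapter occurrence, or before an
adapter prefix of ≥ `min_overlap` nt flush with the read's 3' end. Reads
with no adapter evidence are discarded — an insert shorter than the
sequencing read length must expose adapter, so adapter-negative reads are
either artifacts or inserts running past the read end. Reads containing N
are dropped before collapsing (exact-match mapping cannot place them);
their count is logged. All sequences are held as DNA (U→T on ingest);
hairpin display converts back to RNA.

Collapsed reads sort by descending count then lexicographically, making
"the most abundant read" a deterministic notion everywhere downstream.
Abundances are normalized to reads per ten million, RP10M = count /
library_total × 10⁷ (printed as TP10M for degradome tags); the sum over a
library is 10⁷ by construction and is asserted to 1e-6 relative tolerance.

## Exact mapping

Queries are 18–25-nt (small RNA) or 20–21-nt (degradome) sequences mapped
with zero mismatches at full length, so the mapper is a k-mer seed index
(k = 18, the minimum retained query length) with full verification rather
than a BWT aligner. Genome mode indexes both strands; transcriptome mode is
sense-only, because degradome tags are 5' ends of mRNA 3' fragments. All
hits are reported; reads with more than 20 genomic loci are flagged
hyper-repetitive and excluded from novel-miRNA candidacy (repetitive loci
inflate hairpin candidates without adding evidence). Hit multiplicities are
tabulated in the {0, 1, 2, ≥3} classes used in degradome mapping reports.

## Read categorization

Genome-matched unique reads partition into three disjoint categories with
fixed precedence: known miRNA (exact identity with a known mature
sequence) > ncRNA (full-length containment in an rRNA/tRNA/snRNA/snoRNA
reference; substring containment replaces BLAST for determinism) >
unannotated. Keeping categories disjoint makes the unique/total tallies sum
exactly to the genome-matched totals. Exon overlap is a sub-flag of
unannotated: it bars a read from novel-miRNA candidacy (likely mRNA
degradation) without disturbing the category arithmetic. IsomiRs of known
miRNAs therefore count as unannotated in the category table while still
appearing in their precursor's isomiR tabulation (variant, count, 5'/3'
offsets against the reference mature, star-arm flag).

## Hairpin discovery

Candidate loci are the 150-nt-flank windows around unannotated,
non-exonic, non-hyper-repetitive reads with count ≥ 10 (the
`min_candidate_count` default; sequencing noise below that abundance
produces no credible precursor evidence). Overlapping windows merge into
loci; within a locus, candidates are seeded abundance-first: the most
abundant unclaimed read defines the fold window (its own ±150-nt flanks),
and all reads inside that window are claimed. This keeps one candidate per
genuine precursor while preventing a single read between two hairpins from
fusing them into one candidate.

### Fold

The fold maximizes the number of base pairs subject to: pairs ∈ {AU, GC,
GU}, hairpin loops ≥ 3 nt, nested structures only. The dynamic program
packs a secondary objective into the same table: among structures with the
maximal pair count, the traceback follows the one with the most stacked
pairs (pairs (i,j) with (i+1,j−1) also paired). Pair count — the criterion
the duplex filters consume — is exactly optimal and is verified against an
exhaustive structure enumeration for short sequences; the stacking
preference only selects *which* optimal structure is reported, favoring
contiguous helices over the scattered pairing that base-pair maximization
alone would happily return on a 300-nt window. The traceback is fully
deterministic (prefer 3'-most base unpaired; otherwise pair it with the
5'-most partner achieving the packed optimum). Window lengths are
restricted to 40–400 nt in pipeline use; `check_length=False` folds
arbitrary fragments. Free energies are deliberately out of scope: the
acceptance criteria are structural counts, and a thermodynamic folder can
be supplied as `fold(seq, engine=...)` (any callable returning dot-bracket,
e.g. the ViennaRNA binding) and is consumed through the same validated
interface.

### Duplex criteria

The putative mature is the window's most abundant read (ties
lexicographic). Its star interval is the span of its pairing partners
shifted 3' by 2 nt — the uniform expression, for either arm, of the 2-nt 3'
overhangs Dicer leaves on each duplex end. `find_star` returns nothing when
the mature is unpaired, pairs into itself (spans the terminal loop), or
pairs onto both sides; a star overlapping the mature is rejected.
Acceptance requires matched pairs ≥ 16 (config-switchable to ≥ 17, since
"exceeding 16" is ambiguous between the two readings; ≥ 16 is the default,
matching the conventional minimum semantics) and mature/star size
difference ≤ 4 nt. The first failed criterion is recorded as the rejection
reason. Observed star reads are matched to the predicted interval with
±2 nt end tolerance; a star more abundant than its mature is still reported
as the star (relabeling is interpretation, not detection).

## Degradome targeting

A t-signature is built per distinct (transcript, tag 5'-end) with the
30-nt window [pos−15, pos+14]; the asymmetric convention (15 up, 14 down
plus the tag base) is config-exposed. Positions lacking 15 nt of context on
either side are dropped from signatures but retained in the library total,
so normalization is unaffected. Multi-hit tags contribute their full count
at every position they map to (degradome reads in duplicated genomes
frequently map twice; discarding them would blind the analysis to
paralogous targets).

Alignment scoring adopts the plant-standard degradome scheme — mismatch
1.0, G:U wobble 0.5, single-nt gap 1.0, each doubled at miRNA positions
2–13 — with total score ≤ 7 and a hard requirement of Watson–Crick pairs at
positions 10 and 11 (no mismatch, wobble, gap, or bulged site base between
them). The site aligned to a signature is pinned so that the tag's 5'-end
base pairs miRNA position 10 (site 3' end = cleave_pos + 9); with gaps
enabled, sites one base shorter/longer are also tried and the accepted
alignment must preserve that anchoring. Scoring is verified against an
exhaustive enumeration of all single-gap placements.

Classification uses only abundance ratios on the transcript, so it is
invariant under library-size rescaling: Class I when every signature
position on the transcript is attributable to an accepted miRNA call; else
Class II when the cleavage abundance ties the maximum (ties count as II);
else Class III when strictly above the lower median of all per-position
abundances (cleavage position included); else Class IV. Report rows merge
adjacent validated positions of one miRNA/transcript pair into an "a/b"
site, keeping the more abundant position's class and abundance; per-target
t-plot data (position, TP10M, cleavage flag) accompany the table.

## Synthetic data

The generator emulates the study conditions end to end, from one integer
seed through named RNG streams (byte-identical reruns):

* **Genome**: i.i.d. uniform background (negligible accidental hairpins at
  the 150-nt scale) carrying planted precursors — arm, ≥ 4-nt loop,
  complementary arm — at 300-nt spacing, 30% on the minus strand. 20% of
  hairpins are planted with < 16 matched pairs (non-pairable same-letter
  substitutions opposite interior mature positions) and 20% with size
  difference > 4 (bulged insertions in the star arm); the rest satisfy both
  criteria. Each construct is re-folded exactly as discovery will fold it
  (the context pads are sized so the mature ± 150 window reproduces the
  construct) and redrawn, deterministically, until the realized verdict
  matches intent — the fold itself is validated independently, so this
  guarantees the truth file is consistent without assuming anything about
  the pipeline under test. A fast construction-only mode skips
  re-verification for degradome-focused studies.
* **Small-RNA library**: mature species (≥ 20 counts each), stars at 0.3×
  the mature (the typical asymmetry; the occasional star-dominant locus is
  a config away), 5'/3'-shifted isomiRs at geometric decay 0.25, ncRNA
  fragments (10%), and genome-derived degradation background filling the
  library to its nominal size (planted species take ~30% of the total, the
  dominant remainder being background, matching the minority share mature
  miRNAs hold in real seed libraries) with the 21/22/24-nt length profile
  at weights 0.5/0.3/0.2.
* **Degradome**: transcripts of 1.2 kb with CDS bounds; complementary
  sites embedded in the CDS (where plant cleavage sites predominantly
  fall); planted tags at the position opposite miRNA position 10 with peak
  counts 50–80; background tags per position as Poisson draws with mean
  peak/ratio damped by a 0.001-per-nt 5'→3' exponential decay; tag length
  20 or 21 with equal probability. At peak:background 1 the truth marks
  events "weak" (they may legitimately classify III/IV).

What the synthetic tests show: the pipeline recovers planted duplex
verdicts exactly and planted cleavage events at ≥ 95% as Class I/II under
5× peaks, with no oracle-refuted calls for composition-matched shuffled
guides. What they do not show: robustness to sequencing error, spliced or
mismatched mapping, realistic expression skew, RNA-structure-dependent
degradation hot spots, or genomes with repeat families — none of which the
generator models.

## Problem sizes and numerical choices

The test suite and acceptance script run at deliberately moderated sizes
chosen as representative samples of the generator's behavior: 50-hairpin
truth sets for verdict agreement, 20 replicates × 10 transcripts × 800 nt
for cleavage recovery, 200 random sequences (n ≤ 14) for the fold oracle,
500 random pairs for the scoring oracle. Ties everywhere break
lexicographically or toward the 5' end; scores are plain floats (all
penalty sums are multiples of 0.5, so equality comparisons are exact);
the classifier's median is `median_low` semantics. Known limitations:
exact-match mapping only (a single SNP hides a locus), no conservation or
expression-based candidate ranking, no statistical model of cleavage
significance (tiering is rule-based, as in the original four-class
scheme), and hairpin discovery evaluates one mature per locus — tandem
miRNA clusters closer than the flank length are reported as their dominant
member.
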