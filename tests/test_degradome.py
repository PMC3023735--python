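import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import rand_seq
from oracles import best_alignment_enumeration, classify_direct

from mirslice.degradome_targeting import (
    TSignature,
    TargetAlignment,
    TargetCall,
    build_signatures,
    call_targets,
    classify_all,
    classify_target,
    emit_target_table,
    locate_site_region,
    score_alignment,
    tplot_data,
)
from mirslice.read_mapper import MappedHit
from mirslice.seq_io import TranscriptRecord, revcomp


def _tr(seq, tid="t1", cds=None):
    if cds:
        return TranscriptRecord(id=tid, seq=seq, cds_start=cds[0], cds_end=cds[1])
    return TranscriptRecord(id=tid, seq=seq)


class TestSignatures:
    def test_window_slicing(self, rng):
        t = _tr(rand_seq(rng, 100))
        hit = MappedHit(t.seq[49:69], "t1", 50, "+")
        sigs = build_signatures([t], [(hit, 3)], 100)
        assert len(sigs) == 1
        s = sigs[0]
        assert s.cleave_pos == 50 and s.tag30 == t.seq[34:64]
        assert s.count == 3 and s.tp10m == pytest.approx(3e5)

    def test_insufficient_context_dropped(self, rng):
        t = _tr(rand_seq(rng, 100))
        early = MappedHit(t.seq[9:29], "t1", 10, "+")
        late = MappedHit(t.seq[89:99], "t1", 90, "+")
        assert build_signatures([t], [(early, 1), (late, 1)], 100) == []

    def test_counts_aggregate_by_five_prime_end(self, rng):
        t = _tr(rand_seq(rng, 100))
        h20 = MappedHit(t.seq[49:69], "t1", 50, "+")
        h21 = MappedHit(t.seq[49:70], "t1", 50, "+")
        sigs = build_signatures([t], [(h20, 2), (h21, 1)], 100)
        assert len(sigs) == 1 and sigs[0].count == 3

    def test_antisense_tags_rejected(self, rng):
        t = _tr(rand_seq(rng, 100))
        bad = MappedHit("A" * 20, "t1", 50, "-")
        with pytest.raises(ValueError):
            build_signatures([t], [(bad, 1)], 100)


class TestScoreAlignment:
    MIRNA = "A" * 19 + "GA"  # 21 nt; position 20 is G, the rest A

    def _perfect_site(self):
        return revcomp(self.MIRNA)

    def test_perfect_complement_scores_zero(self):
        res = score_alignment(self.MIRNA, self._perfect_site())
        assert res is not None and res[0] == 0.0

    def test_wobble_and_core_mismatch(self):
        site = list(self._perfect_site())
        site[1] = "T"  # pairs miRNA position 20: G:U wobble, 0.5
        site[16] = "G"  # pairs miRNA position 5: mismatch in the doubled core, 2.0
        res = score_alignment(self.MIRNA, "".join(site))
        assert res is not None and res[0] == pytest.approx(2.5)

    def test_cleavage_site_mismatch_rejected(self):
        site = list(self._perfect_site())
        site[11] = "G"  # pairs miRNA position 10
        assert score_alignment(self.MIRNA, "".join(site)) is None

    def test_score_boundary_seven(self):
        site = list(self._perfect_site())
        for pos in (14, 15, 16, 17, 18, 19, 21):  # non-core mismatches, 1.0 each
            site[21 - pos] = "C"
        res = score_alignment(self.MIRNA, "".join(site))
        assert res is not None and res[0] == pytest.approx(7.0)
        site[1] = "T"  # add a 0.5 wobble at position 20 -> 7.5
        assert score_alignment(self.MIRNA, "".join(site)) is None

    def test_length_validation(self):
        with pytest.raises(ValueError):
            score_alignment("ACGT", "ACGT")
        with pytest.raises(ValueError):
            score_alignment("N" * 21, "A" * 21)

    def test_gapped_site_must_be_enabled(self, rng):
        m = rand_seq(rng, 21)
        assert score_alignment(m, revcomp(m)[:-1]) is None

    def test_matches_enumeration_oracle(self, rng):
        """Best admissible score equals exhaustive gap-placement enumeration."""
        n_checked = 0
        for _ in range(200):
            n = int(rng.integers(18, 22))
            mirna = rand_seq(rng, n)
            site = list(revcomp(mirna))
            for _ in range(int(rng.integers(0, 7))):
                site[int(rng.integers(0, len(site)))] = "ACGT"[int(rng.integers(0, 4))]
            delta = int(rng.integers(0, 3)) - 1
            if delta == 1:
                site.insert(int(rng.integers(0, len(site) + 1)), "ACGT"[int(rng.integers(0, 4))])
            elif delta == -1:
                site.pop(int(rng.integers(0, len(site))))
            site = "".join(site)
            got = score_alignment(mirna, site, allow_gap=(delta != 0))
            want = best_alignment_enumeration(mirna, site)
            if want is None:
                assert got is None
            else:
                assert got is not None and got[0] == pytest.approx(want)
                n_checked += 1
        assert n_checked > 20  # sanity: plenty of accepted alignments exercised


class TestCallTargets:
    def _setup(self, rng, offset=0):
        mirna = rand_seq(rng, 21)
        t = rand_seq(rng, 200) + revcomp(mirna) + rand_seq(rng, 200)
        tr = _tr(t)
        site_end = 200 + 21
        cleave = site_end - 9 + offset
        sig = TSignature("t1", cleave, t[cleave - 16 : cleave + 14], 40, 4e6)
        return mirna, tr, sig

    def test_planted_site_yields_one_call(self, rng):
        mirna, tr, sig = self._setup(rng)
        calls = call_targets({"m1": mirna}, [sig], [tr])
        assert len(calls) == 1
        c = calls[0]
        assert c.cleave_pos == sig.cleave_pos and c.alignment.score == 0.0
        assert c.alignment.pos10_target == sig.cleave_pos

    def test_displaced_signature_not_called(self, rng):
        mirna, tr, sig = self._setup(rng, offset=3)
        assert call_targets({"m1": mirna}, [sig], [tr]) == []

    def test_identical_paralogs_each_called(self, rng):
        mirna, tr, sig = self._setup(rng)
        calls = call_targets({"m1": mirna, "m2": mirna}, [sig], [tr])
        assert sorted(c.alignment.mirna_id for c in calls) == ["m1", "m2"]

    def test_empty_mirna_set_rejected(self, rng):
        with pytest.raises(ValueError):
            call_targets({}, [], [])


def _sig(pos, ab, tid="t1"):
    return TSignature(tid, pos, "A" * 30, max(1, int(ab)), float(ab))


def _call(pos, ab, tid="t1"):
    aln = TargetAlignment("m1", "A" * 21, tid, pos - 11, pos + 9, 0.0, ("match",) * 21, pos)
    return TargetCall(alignment=aln, cleave_pos=pos, cleave_count=int(ab), cleave_abundance=ab)


class TestClassify:
    def test_sole_signature_is_class_one(self):
        assert classify_target(_call(50, 40.0), [_sig(50, 40)]) == "I"

    def test_dominant_signature_is_class_two(self):
        sigs = [_sig(50, 40), _sig(10, 12), _sig(90, 3)]
        assert classify_target(_call(50, 40.0), sigs) == "II"

    def test_above_median_is_class_three(self):
        sigs = [_sig(50, 8), _sig(10, 16), _sig(90, 4), _sig(20, 1), _sig(70, 2)]
        assert classify_target(_call(50, 8.0), sigs) == "III"

    def test_at_or_below_median_is_class_four(self):
        sigs = [_sig(50, 2), _sig(10, 16), _sig(90, 4), _sig(20, 3), _sig(70, 5)]
        assert classify_target(_call(50, 2.0), sigs) == "IV"

    def test_class_one_takes_precedence_over_two(self):
        # every signature is miRNA-directed, so I wins even though the
        # cleavage trivially ties the maximum
        sigs = [_sig(50, 40), _sig(80, 10)]
        assert classify_target(_call(50, 40.0), sigs, {50, 80}) == "I"

    def test_missing_position_raises(self):
        with pytest.raises(ValueError):
            classify_target(_call(55, 40.0), [_sig(50, 40)])

    @given(
        abundances=st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=12),
        scale=st.floats(min_value=0.01, max_value=1000),
    )
    @settings(max_examples=80, deadline=None)
    def test_invariant_under_abundance_scaling(self, abundances, scale):
        positions = list(range(10, 10 + 20 * len(abundances), 20))
        base = [_sig(p, a) for p, a in zip(positions, abundances)]
        scaled = [_sig(p, a * scale) for p, a in zip(positions, abundances)]
        p0, a0 = positions[0], abundances[0]
        assert classify_target(_call(p0, float(a0)), base) == classify_target(
            _call(p0, a0 * scale), scaled
        )

    def test_matches_direct_recomputation(self, rng):
        for _ in range(300):
            k = int(rng.integers(1, 15))
            positions = (rng.permutation(500)[:k] + 16).tolist()
            abundances = rng.integers(1, 200, size=k).astype(float).tolist()
            sigs = [_sig(p, a) for p, a in zip(positions, abundances)]
            cp, ca = positions[0], abundances[0]
            directed = {cp}
            got = classify_target(_call(cp, ca), sigs, directed)
            want = classify_direct(dict(zip(positions, abundances)), cp, directed)
            assert got == want


class TestRegions:
    @pytest.mark.parametrize(
        "pos, region", [(50, "5'UTR"), (100, "CDS"), (250, "CDS"), (400, "CDS"), (450, "3'UTR")]
    )
    def test_examples(self, rng, pos, region):
        t = _tr(rand_seq(rng, 500), cds=(100, 400))
        assert locate_site_region(t, pos) == region

    def test_unknown_without_cds(self, rng):
        assert locate_site_region(_tr(rand_seq(rng, 100)), 50) == "unknown"

    def test_out_of_bounds_raises(self, rng):
        with pytest.raises(ValueError):
            locate_site_region(_tr(rand_seq(rng, 100)), 101)


class TestReport:
    def test_single_call_single_row(self):
        c = _call(100, 25.0)
        c.class_label, c.site_region = "I", "CDS"
        rows = emit_target_table([c], {"t1": "some gene"})
        assert rows == [("m1", "t1", "some gene", "I", 25.0, "100", "CDS")]

    def test_adjacent_positions_merge(self):
        a, b = _call(688, 109.0), _call(689, 40.0)
        for c in (a, b):
            c.class_label, c.site_region = "I", "CDS"
        rows = emit_target_table([a, b])
        assert len(rows) == 1 and rows[0][5] == "688/689"
        assert rows[0][4] == 109.0  # more abundant position leads

    def test_empty_input(self):
        assert emit_target_table([]) == []

    def test_tplot_rows(self):
        sigs = [_sig(30, 5.0), _sig(10, 2.0), _sig(50, 9.0)]
        rows = tplot_data("t1", sigs, {50})
        assert rows == [(10, 2.0, 0), (30, 5.0, 0), (50, 9.0, 1)]
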