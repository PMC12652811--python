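"""Motif grammar parsing and exhaustive flexible-gap scanning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abascan import (
    CANONICAL_AA,
    MotifElement,
    MotifMatch,
    MotifSyntaxError,
    SequenceRecord,
    UNIFORM_AA_FREQS,
    expected_match_count,
    merge_matches,
    parse_motif,
    scan_sequence,
)
from abascan.motifs import MotifPattern

from .conftest import oracle_spans

AA = sorted(CANONICAL_AA)


def _rec(seq: str) -> SequenceRecord:
    return SequenceRecord("s", "", seq)


class TestParse:
    @pytest.mark.parametrize(
        "text,n_elements,n_anchors,span_min,span_max",
        [
            ("D.{7,8}R.{3,4}D.{5,6}Y.{6,7}H", 9, 5, 26, 30),
            ("D.{7,8}R.{8,10}Y.{6,7}H", 7, 4, 25, 29),
            ("[RSK][YFW][DE].{8,12}[RK].{1,3}[DE]", 7, 5, 14, 20),
            ("[RSK].[DE].{8,12}[RK].{1,3}[DE]", 7, 4, 14, 20),
            ("[VILAR]P.[VILAR]P", 5, 4, 5, 5),
        ],
    )
    def test_pattern_compilation(self, text, n_elements, n_anchors, span_min, span_max):
        m = parse_motif("m", text)
        assert len(m.elements) == n_elements
        assert m.n_anchors == n_anchors
        assert (m.span_min, m.span_max) == (span_min, span_max)
        assert m.source_text == text  # lossless

    def test_consecutive_gaps_not_coalesced(self):
        m = parse_motif("m", "D..{2,3}R")
        kinds = [e.kind for e in m.elements]
        assert kinds == ["anchor", "gap", "gap", "anchor"]

    @pytest.mark.parametrize(
        "bad",
        ["", "D.{8,7}H", "D.{-1,2}H", "D.{1;2}H", "D.{1}H", "[XD]", "[]A",
         "[RS", "D.{3,4", "d", "D*H", "D+", "^D", "D$", "D?H", "1A"],
    )
    def test_grammar_violations_raise(self, bad):
        with pytest.raises(MotifSyntaxError):
            parse_motif("bad", bad)


class TestScan:
    def test_planted_stringent_instance_single_exact_span(self, motif_set):
        seq = "DAAAAAAARAAADAAAAAYAAAAAAH"
        matches = scan_sequence(_rec(seq), motif_set["ABA_STRINGENT"])
        assert [(m.start, m.end) for m in matches] == [(1, 26)]
        assert matches[0].anchor_positions == (1, 9, 13, 19, 26)
        assert matches[0].matched_text == seq

    def test_overlapping_matches_both_reported(self, motif_set):
        matches = scan_sequence(_rec("VPAVPAVP"), motif_set["SH3"])
        assert [(m.start, m.end) for m in matches] == [(1, 5), (4, 8)]

    def test_no_match_on_missing_anchor(self, motif_set):
        assert scan_sequence(_rec("AAAA"), motif_set["SH3"]) == []

    def test_ambiguity_code_never_satisfies_anchor(self, motif_set):
        # X replaces the leading D: the anchor must fail even though X
        # would be tolerated in a gap position
        assert scan_sequence(
            _rec("XAAAAAAARAAADAAAAAYAAAAAAH"), motif_set["ABA_STRINGENT"]
        ) == []

    def test_ambiguity_code_allowed_inside_gap(self, motif_set):
        seq = "DXXXXXXXRXXXDXXXXXYXXXXXXH"
        matches = scan_sequence(_rec(seq), motif_set["ABA_STRINGENT"])
        assert [(m.start, m.end) for m in matches] == [(1, 26)]

    def test_matches_revalidate_anchors_and_span(self, motif_set):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(AA, size=4000))
        for motif in motif_set.values():
            for m in scan_sequence(_rec(seq), motif):
                assert motif.span_min <= m.end - m.start + 1 <= motif.span_max
                anchors = [e for e in motif.elements if e.kind == "anchor"]
                assert len(m.anchor_positions) == len(anchors)
                for pos, el in zip(m.anchor_positions, anchors):
                    assert seq[pos - 1] in el.allowed
                assert list(m.anchor_positions) == sorted(set(m.anchor_positions))

    def test_shift_equivariance(self, motif_set):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(AA, size=300))
        motif = motif_set["ABA_RELAXED"]
        base = {(m.start, m.end) for m in scan_sequence(_rec(seq), motif)}
        for k in (1, 5, 17):
            shifted = {
                (m.start, m.end)
                for m in scan_sequence(_rec("G" * k + seq), motif)
                if m.start > k  # new prefix may create additional hits
            }
            assert {(s + k, e + k) for s, e in base} <= shifted

    def test_relaxing_gap_max_preserves_matches(self, motif_set):
        rng = np.random.default_rng(13)
        motif = motif_set["AC_TEXT"]
        relaxed = parse_motif("AC_WIDE", "[RSK][YFW][DE].{8,14}[RK].{1,5}[DE]")
        for _ in range(20):
            seq = "".join(rng.choice(AA, size=200))
            tight = {(m.start, m.end) for m in scan_sequence(_rec(seq), motif)}
            wide = {(m.start, m.end) for m in scan_sequence(_rec(seq), relaxed)}
            assert tight <= wide

    def test_scan_agrees_with_regex_oracle(self, motif_set):
        rng = np.random.default_rng(42)
        for motif in motif_set.values():
            for _ in range(40):
                seq = "".join(rng.choice(AA, size=100))
                got = {(m.start, m.end) for m in scan_sequence(_rec(seq), motif)}
                assert got == oracle_spans(seq, motif)


class TestMerge:
    def _mk(self, spans):
        return [
            MotifMatch("s", "m", s, e, "", ()) for s, e in spans
        ]

    def test_overlapping_matches_merge_to_envelope(self):
        sites = merge_matches(self._mk([(1, 26), (2, 27)]))
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end, sites[0].n_matches) == (1, 27, 2)

    def test_disjoint_matches_stay_separate(self):
        sites = merge_matches(self._mk([(1, 5), (10, 14)]))
        assert [(s.start, s.end) for s in sites] == [(1, 5), (10, 14)]

    def test_adjacent_but_nonoverlapping_not_merged(self):
        assert len(merge_matches(self._mk([(1, 5), (6, 9)]))) == 2

    def test_empty_input(self):
        assert merge_matches([]) == []

    def test_mixed_ids_rejected(self):
        bad = [MotifMatch("a", "m", 1, 5, "", ()), MotifMatch("b", "m", 2, 6, "", ())]
        with pytest.raises(ValueError):
            merge_matches(bad)

    @given(
        st.lists(
            st.tuples(st.integers(1, 80), st.integers(1, 20)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=25,
        )
    )
    def test_merge_conserves_match_count_and_sorting(self, spans):
        sites = merge_matches(self._mk(spans))
        assert sum(s.n_matches for s in sites) == len(spans)
        assert all(a.end < b.start for a, b in zip(sites, sites[1:]))


class TestExpectedCount:
    def test_sh3_closed_form(self, motif_set):
        # per-start (5/20)(1/20)(1)(5/20)(1/20) = 1.5625e-4; 100 starts
        val = expected_match_count(motif_set["SH3"], UNIFORM_AA_FREQS, 104)
        assert val == pytest.approx(0.015625, rel=1e-12)

    def test_zero_when_sequence_shorter_than_span(self, motif_set):
        m = motif_set["ABA_STRINGENT"]
        assert expected_match_count(m, UNIFORM_AA_FREQS, m.span_min - 1) == 0.0

    def test_stringent_sums_sixteen_configurations(self, motif_set):
        m = motif_set["ABA_STRINGENT"]
        t = 10_000
        per = (1 / 20) ** 5
        expected = sum(
            (t - span + 1) * per
            for span in [5 + g1 + g2 + g3 + g4
                         for g1 in (7, 8) for g2 in (3, 4)
                         for g3 in (5, 6) for g4 in (6, 7)]
        )
        assert expected_match_count(m, UNIFORM_AA_FREQS, t) == pytest.approx(expected)

    def test_unnormalized_frequencies_rejected(self, motif_set):
        freqs = {a: 0.04 for a in AA}
        with pytest.raises(ValueError):
            expected_match_count(motif_set["SH3"], freqs, 100)

    def test_count_sanity_on_megaresidue_background(self, motif_set):
        # observed distinct hits on an i.i.d. background should fall in the
        # central 99% Poisson band around the analytic expectation
        # (tolerance x3 either way below expectation 5, as the expectation
        # is a union-bound approximation)
        from scipy.stats import poisson

        rng = np.random.default_rng(2024)
        seq = "".join(rng.choice(AA, size=1_000_000))
        motif = motif_set["ABA_STRINGENT"]
        observed = len(scan_sequence(_rec(seq), motif))
        mu = expected_match_count(motif, UNIFORM_AA_FREQS, len(seq))
        lo, hi = poisson.ppf(0.005, mu), poisson.ppf(0.995, mu)
        if mu < 5:
            lo, hi = lo / 3, hi * 3
        assert lo <= observed <= hi
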