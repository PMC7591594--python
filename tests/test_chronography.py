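import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respchron.chronography import (
    BaseCategory,
    ExclusionReason,
    InhStatus,
    InputFormatError,
    Talkspurt,
    TTKind,
    apply_exclusions,
    augment_inh,
    classify_intervals,
    merge_talkspurts,
    tt_events,
)
from respchron.signal_core import BreathCycle, CalibrationState, RIPTrace

from oracles import classify_oracle, merge_oracle


def ts(spk, a, b):
    return Talkspurt(speaker_id=spk, t_start=a, t_end=b)


def cycle(on, pk, off, i=0):
    return BreathCycle(t_onset=on, t_peak=pk, t_offset=off,
                       v_onset=0.0, v_peak=1.0, v_offset=0.0, index=i)


class TestMergeTalkspurts:
    def test_short_gap_merges(self):
        out = merge_talkspurts([(0, 1.0), (1.1, 2.0)], "A")
        assert [(t.t_start, t.t_end) for t in out] == [(0.0, 2.0)]

    def test_gap_at_threshold_stays_separate(self):
        out = merge_talkspurts([(0, 1.0), (1.3, 2.0)], "A")
        assert len(out) == 2

    def test_backchannel_flag_follows_one_second_rule(self):
        out = merge_talkspurts([(0, 0.8), (5, 6.5)], "A")
        assert out[0].is_backchannel and not out[1].is_backchannel

    def test_overlapping_input_rejected(self):
        with pytest.raises(InputFormatError):
            merge_talkspurts([(0, 2.0), (1.5, 3.0)], "A")

    def test_matches_sort_and_sweep_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            starts = np.sort(rng.uniform(0, 100, 12))
            ivs = []
            prev_end = -1.0
            for s in starts:
                a = max(s, prev_end + 0.01)
                b = a + rng.uniform(0.1, 3.0)
                ivs.append((a, b))
                prev_end = b
            got = [(t.t_start, t.t_end)
                   for t in merge_talkspurts(ivs, "A", min_pause_s=0.2)]
            assert got == merge_oracle(ivs, 0.2)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 50), min_size=1, max_size=10),
           st.floats(0.05, 2.0))
    def test_merge_is_idempotent(self, starts, width):
        ivs, prev = [], -10.0
        for s in sorted(starts):
            a = max(s, prev + 0.01)
            ivs.append((a, a + width))
            prev = a + width
        once = merge_talkspurts(ivs, "A")
        twice = merge_talkspurts(
            [(t.t_start, t.t_end) for t in once], "A")
        assert [(t.t_start, t.t_end) for t in once] == \
               [(t.t_start, t.t_end) for t in twice]


class TestClassifyIntervals:
    def test_within_speaker_silence(self):
        evs = classify_intervals([ts("A", 0, 2), ts("A", 3, 5)])
        assert len(evs) == 1
        e = evs[0]
        assert e.base is BaseCategory.WSS
        assert (e.t_start, e.t_end) == (2, 3)

    def test_between_speaker_silence(self):
        e = classify_intervals([ts("A", 0, 2), ts("B", 3, 5)])[0]
        assert e.base is BaseCategory.BSS
        assert e.prev_speaker == "A" and e.next_speaker == "B"

    def test_between_speaker_overlap(self):
        e = classify_intervals([ts("A", 0, 3), ts("B", 2, 5)])[0]
        assert e.base is BaseCategory.BSO
        assert (e.t_start, e.t_end) == (2, 3)

    def test_embedded_talkspurt_is_wso(self):
        evs = classify_intervals([ts("A", 0, 5), ts("B", 1, 2), ts("A", 6, 8)])
        bases = [e.base for e in evs]
        assert BaseCategory.WSO in bases and BaseCategory.WSS in bases
        wso = next(e for e in evs if e.base is BaseCategory.WSO)
        assert (wso.t_start, wso.t_end) == (1, 2)
        # A's offset still pairs past the embedded backchannel
        wss = next(e for e in evs if e.base is BaseCategory.WSS)
        assert (wss.t_start, wss.t_end) == (5, 6)

    def test_random_three_party_layouts_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            spurts, cursor = [], {}
            for _ in range(rng.integers(3, 9)):
                spk = "ABC"[rng.integers(3)]
                a = max(cursor.get(spk, 0.0) + 0.05, rng.uniform(0, 30))
                b = a + rng.uniform(0.2, 4.0)
                cursor[spk] = b
                spurts.append((spk, a, b))
            got = {
                (e.base.value, e.prev_speaker, e.next_speaker,
                 e.t_start, e.t_end)
                for e in classify_intervals(
                    [ts(s, a, b) for s, a, b in spurts])
            }
            assert got == classify_oracle(spurts)

    def test_dyadic_no_overlap_reduces_to_classic_chronogram(self):
        # strict alternation without overlap: BSS only, one per junction
        spurts = [ts("AB"[i % 2], 2 * i, 2 * i + 1.5) for i in range(8)]
        evs = classify_intervals(spurts)
        assert all(e.base is BaseCategory.BSS for e in evs)
        assert len(evs) == 7

    def test_chronogram_completeness(self, short_sim):
        *_, result = short_sim
        evs = result.events
        # every adjacent pair yields exactly one event; categories disjoint
        spurts = result.all_talkspurts
        non_wso = [e for e in evs if e.base is not BaseCategory.WSO]
        assert len(non_wso) <= len(spurts) - 1
        keys = [(e.prev_ts.t_end, e.prev_speaker) for e in non_wso]
        assert len(keys) == len(set(keys))


class TestAugmentInh:
    def test_continued_exhalation_is_minus(self):
        spurts = [ts("A", 0, 2), ts("A", 3, 5)]
        ev = classify_intervals(spurts)[0]
        cycles = [cycle(-1.5, -0.5, 6.0)]   # one exhalation spans both
        out = augment_inh(ev, cycles, spurts)
        assert out.inh is InhStatus.MINUS

    def test_intervening_inhalation_onset_is_plus(self):
        spurts = [ts("A", 0, 2), ts("A", 4, 6)]
        ev = classify_intervals(spurts)[0]
        cycles = [cycle(-1.5, -0.5, 2.4), cycle(2.4, 3.1, 7.0, i=1)]
        out = augment_inh(ev, cycles, spurts)
        assert out.inh is InhStatus.PLUS

    def test_no_further_own_speech_is_na(self):
        spurts = [ts("A", 0, 2), ts("B", 3, 5)]
        ev = classify_intervals(spurts)[0]
        out = augment_inh(ev, [cycle(-1, -0.5, 6)], spurts)
        assert out.inh is InhStatus.NA

    def test_counts_conservation(self, short_sim):
        *_, result = short_sim
        non_wso = [e for e in result.events
                   if e.base is not BaseCategory.WSO]
        n_pm = sum(e.inh in (InhStatus.PLUS, InhStatus.MINUS)
                   for e in non_wso)
        n_na = sum(e.inh is InhStatus.NA for e in non_wso)
        assert n_pm + n_na == len(non_wso)


def make_sv_trace(points, rate=100.0, t_end=20.0):
    tt = np.arange(0, t_end, 1 / rate)
    t, v = zip(*points)
    xx = np.interp(tt, t, v)
    return RIPTrace(speaker_id="A", samples=xx, sample_rate=rate,
                    calibration=CalibrationState.SV_UNITS)


class TestApplyExclusions:
    def build(self, spurts, cycles):
        evs = classify_intervals(spurts)
        return [augment_inh(e, cycles, spurts) for e in evs]

    def test_offset_inside_inhalation_excluded(self):
        spurts = [ts("A", 0, 2), ts("B", 3, 5)]
        cycles = {"A": [cycle(1.5, 2.5, 6.0)], "B": [cycle(0, 1, 9)]}
        evs = self.build(spurts, cycles["A"])
        out = apply_exclusions(evs, cycles)
        assert out[0].excluded is ExclusionReason.EDGE_INHALATION

    def test_backchannel_bounded_event_excluded(self):
        spurts = [ts("A", 0, 0.8), ts("B", 2, 5)]   # 0.8 s: backchannel
        cycles = {"A": [cycle(-1, -0.5, 1.5)], "B": [cycle(0.2, 1.2, 9)]}
        evs = self.build(spurts, cycles["A"])
        out = apply_exclusions(evs, cycles)
        assert out[0].excluded is ExclusionReason.BACKCHANNEL

    def test_laughter_overlap_excluded(self):
        spurts = [ts("A", 0, 2), ts("B", 3, 5)]
        cycles = {"A": [cycle(-1, -0.5, 2.5), cycle(2.5, 2.8, 9, i=1)],
                  "B": [cycle(0.2, 1.2, 9)]}
        evs = self.build(spurts, cycles["A"])
        out = apply_exclusions(evs, cycles, {"A": [(1.5, 2.2)]})
        assert out[0].excluded is ExclusionReason.LAUGHTER

    def test_clean_event_not_excluded(self):
        spurts = [ts("A", 0, 2), ts("B", 3, 5)]
        cycles = {"A": [cycle(-1, -0.5, 2.5), cycle(2.5, 2.8, 9, i=1)],
                  "B": [cycle(0.2, 1.2, 9)]}
        evs = self.build(spurts, cycles["A"])
        out = apply_exclusions(evs, cycles)
        assert out[0].excluded is None

    def test_rise_in_minus_exhalation_flags_missed_inhalation(self):
        spurts = [ts("A", 0, 2), ts("A", 4, 6)]
        cycles = {"A": [cycle(-1, -0.5, 8.0)]}
        evs = self.build(spurts, cycles["A"])
        assert evs[0].inh is InhStatus.MINUS
        # monotone descent: not flagged
        flat = make_sv_trace([(-0.5, 1.0), (8.0, 0.0), (20, 0.0)])
        out = apply_exclusions(evs, cycles, traces_by_speaker={"A": flat})
        assert out[0].excluded is None
        # a 30%-amplitude bump inside the exhalation: flagged
        bump = make_sv_trace([(-0.5, 1.0), (2.8, 0.55), (3.2, 0.85),
                              (8.0, 0.0), (20, 0.0)])
        out = apply_exclusions(evs, cycles, traces_by_speaker={"A": bump})
        assert out[0].excluded is ExclusionReason.MISSED_INHALATION_SUSPECT

    def test_duration_fallback_without_trace(self):
        spurts = [ts("A", 0, 2), ts("A", 4, 6)]
        cycles = {"A": [cycle(-1, -0.5, 8.0),
                        cycle(8.0, 9.0, 10.0, i=1),
                        cycle(10.0, 11.0, 12.0, i=2)]}
        evs = self.build(spurts, cycles["A"])
        out = apply_exclusions(evs, cycles)
        # 8.5 s exhalation > 2 x median cycle duration (2-9.5 s range)
        assert out[0].excluded is ExclusionReason.MISSED_INHALATION_SUSPECT


class TestTTEvents:
    def test_silence_initiated_turn_is_tt_s(self):
        spurts = [ts("A", 0, 2), ts("B", 2.4, 5)]
        cycles = {"A": [cycle(-1, -0.5, 3)], "B": [cycle(0.5, 1.8, 8)]}
        evs = [augment_inh(e, cycles["A"], spurts)
               for e in classify_intervals(spurts)]
        tts = tt_events(evs, cycles)
        assert len(tts) == 1 and tts[0].kind is TTKind.TT_S
        assert tts[0].inhalation_cycle.t_onset == 0.5

    def test_overlap_initiated_turn_is_tt_o(self):
        spurts = [ts("A", 0, 3), ts("B", 2, 5)]
        cycles = {"A": [cycle(-1, -0.5, 4)], "B": [cycle(0.5, 1.5, 8)]}
        evs = classify_intervals(spurts)
        tts = tt_events(evs, cycles)
        assert len(tts) == 1 and tts[0].kind is TTKind.TT_O

    def test_simulator_labels_match_exactly(self, noiseless_sim):
        *_, truth, result = noiseless_sim
        truth_by_onset = {
            (r.speaker, round(r.t_onset, 3)): r.kind
            for r in truth.tt_labels.itertuples()
        }
        checked = 0
        for tt in result.tts:
            key = (tt.incoming_speaker, round(tt.talkspurt.t_start, 3))
            if key in truth_by_onset:
                assert tt.kind.value == truth_by_onset[key]
                checked += 1
        assert checked >= 0.9 * len(truth_by_onset)
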