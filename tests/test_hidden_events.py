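import numpy as np
import pytest

from respchron.chronography import (
    Talkspurt,
    augment_inh,
    classify_intervals,
)
from respchron.hidden_events import (
    abandoned_candidates,
    compare_silent_cycle_inhalations,
    hold_position,
    speaker_change_given_hold,
)
from respchron.hold_detector import BreathHold
from respchron.signal_core import BreathCycle


def cycle(on, pk, off, v_on=0.0, v_pk=1.0, v_off=0.0, i=0, silent=True):
    return BreathCycle(t_onset=on, t_peak=pk, t_offset=off,
                       v_onset=v_on, v_peak=v_pk, v_offset=v_off,
                       index=i, silent=silent)


def hold(a, b, level, i=0):
    return BreathHold(cycle_index=i, t_start=a, t_end=b, level=level,
                      in_exhalation=True, during_silence=True)


class TestHoldPosition:
    def test_hold_at_peak_is_origin(self):
        c = cycle(0, 1, 5)
        assert hold_position(hold(1.0, 1.4, 1.0), c) == (0.0, 0.0)

    def test_hold_at_exhalation_end_is_unit(self):
        c = cycle(0, 1, 5)
        rel_t, rel_a = hold_position(hold(4.6, 5.0, 0.0), c)
        assert rel_t == pytest.approx(0.9)
        assert rel_a == pytest.approx(1.0)

    def test_midpoint_hold(self):
        c = cycle(0, 1, 5)
        rel_t, rel_a = hold_position(hold(3.0, 3.4, 0.5), c)
        assert rel_t == pytest.approx(0.5)
        assert rel_a == pytest.approx(0.5)

    def test_zero_amplitude_exhalation_rejected(self):
        c = BreathCycle(0, 1, 5, v_onset=0, v_peak=1, v_offset=1 - 1e-12,
                        index=0)
        object.__setattr__(c, "v_offset", 1.0)
        with pytest.raises(ValueError):
            hold_position(hold(2, 2.5, 1.0), c)


class TestAbandonedCandidates:
    def test_top_hold_in_silent_cycle_is_candidate(self):
        cycles = [cycle(0, 1, 5)]
        cands = abandoned_candidates(cycles, [hold(1.2, 1.6, 0.9)])
        assert len(cands) == 1
        assert cands[0].rel_amp_pos == pytest.approx(0.1)

    def test_mid_level_hold_is_not_candidate(self):
        cycles = [cycle(0, 1, 5)]
        assert abandoned_candidates(cycles, [hold(2, 2.5, 0.5)]) == []

    def test_simulator_top_holds_recovered(self, short_sim):
        *_, truth, result = short_sim
        planted = truth.holds[truth.holds["position"] == "top"]
        n_found = sum(len(c) for c in result.candidates.values())
        recovered = 0
        all_cands = [
            (sid, result.cycles[sid][c.cycle_index])
            for sid, cands in result.candidates.items() for c in cands
        ]
        for row in planted.itertuples():
            ok = any(sid == row.speaker
                     and cyc.t_onset - 0.2 < row.t_start < cyc.t_offset + 0.2
                     for sid, cyc in all_cands)
            recovered += ok
        if len(planted):
            assert recovered / len(planted) >= 0.95
        assert n_found >= recovered


class TestSpeakerChangeGivenHold:
    def make(self, specs):
        """specs: list of (change: bool, with_hold: bool).

        Each spec is an isolated silence between its own speaker pair;
        the second talkspurt of each spec overlaps into the next spec so
        the inter-spec junction is an overlap, never a silence.
        """
        spurts, cycles, holds_by = [], {}, {}
        t = 0.0
        for i, (change, with_hold) in enumerate(specs):
            prev = f"P{i}"
            nxt = f"Q{i}" if change else prev
            a = Talkspurt(prev, t, t + 2.0)
            b = Talkspurt(nxt, t + 3.0, t + 10.5)
            spurts += [a, b]
            cycles.setdefault(prev, []).append(
                cycle(t - 1.5, t - 0.3, t + 5.5, i=0))
            if change:
                cycles.setdefault(nxt, []).append(
                    cycle(t + 1.5, t + 2.9, t + 14.0, i=0))
            holds_by.setdefault(prev, [])
            holds_by.setdefault(nxt, [])
            if with_hold:
                holds_by[prev].append(hold(t + 2.2, t + 2.7, 0.5))
            t += 10.0
        events = classify_intervals(spurts)
        events = [augment_inh(e, cycles.get(e.prev_speaker, ()), spurts)
                  for e in events]
        return events, holds_by, cycles

    def test_all_changes_give_probability_one_in_both_strata(self):
        events, holds_by, cycles = self.make(
            [(True, True), (True, False), (True, True), (True, False)])
        table = speaker_change_given_hold(events, holds_by, cycles,
                                          include_excluded=True)
        assert table.p_change_given_hold == pytest.approx(1.0)
        assert table.p_change_given_no_hold == pytest.approx(1.0)

    def test_no_holds_leaves_conditional_undefined(self):
        events, holds_by, cycles = self.make([(True, False), (False, False)])
        table = speaker_change_given_hold(events, holds_by, cycles,
                                          include_excluded=True)
        assert table.p_change_given_hold is None
        assert table.n_silence_with_hold == 0

    def test_recovers_planted_joint_distribution(self):
        rng = np.random.default_rng(12)
        p_hold, p_change_h, p_change_nh = 0.3, 0.8, 0.4
        specs = []
        for _ in range(1000):
            h = rng.random() < p_hold
            change = rng.random() < (p_change_h if h else p_change_nh)
            specs.append((change, h))
        events, holds_by, cycles = self.make(specs)
        table = speaker_change_given_hold(events, holds_by, cycles,
                                          include_excluded=True)
        # within 3 binomial standard errors
        n_h = table.n_silence_with_hold
        n_nh = table.n_silence_without_hold
        se_h = (p_change_h * (1 - p_change_h) / n_h) ** 0.5
        se_nh = (p_change_nh * (1 - p_change_nh) / n_nh) ** 0.5
        assert abs(table.p_change_given_hold - p_change_h) < 3 * se_h
        assert abs(table.p_change_given_no_hold - p_change_nh) < 3 * se_nh

    def test_law_of_total_probability(self, short_sim):
        *_, result = short_sim
        t = result.hold_condition
        n = t.n_silence_with_hold + t.n_silence_without_hold
        if n == 0:
            pytest.skip("no silences in fixture")
        marginal = (t.n_change_with_hold + t.n_change_without_hold) / n
        weighted = ((t.p_change_given_hold or 0.0) * t.n_silence_with_hold
                    + (t.p_change_given_no_hold or 0.0)
                    * t.n_silence_without_hold) / n
        assert weighted == pytest.approx(marginal, abs=1e-12)


class TestSilentCycleTable:
    def test_three_group_partition(self, short_sim, identity_calib):
        *_, result = short_sim
        df = result.silent_cycle_table
        assert set(df["group"]) <= {"Silent", "Hold", "TT(S)"}
        # every analyzed cycle appears exactly once
        assert not df.duplicated(["speaker_id", "cycle_index"]).any()

    def test_groups_assigned_as_specified(self, identity_calib):
        from respchron.hidden_events import AbandonedCandidate
        cycles = [cycle(0, 1, 4, i=0), cycle(4, 5, 8, i=1),
                  cycle(8, 9, 12, i=2, silent=False)]
        cand = AbandonedCandidate(cycle_index=0, hold=hold(1.1, 1.5, 0.9),
                                  rel_time_pos=0.0, rel_amp_pos=0.1)
        from respchron.chronography import TTEvent, TTKind, Talkspurt
        tt = TTEvent(kind=TTKind.TT_S, incoming_speaker="A",
                     talkspurt=Talkspurt("A", 9.5, 11.0),
                     inhalation_cycle=cycles[2])
        df = compare_silent_cycle_inhalations(
            cycles, [cand], [tt], identity_calib, speaker_id="A")
        by_idx = dict(zip(df["cycle_index"], df["group"]))
        assert by_idx == {0: "Hold", 1: "Silent", 2: "TT(S)"}
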