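"""Hidden turn-taking events recovered from the breathing signal.

A silence-based chronogram cannot distinguish a pause interruption from a
smooth speaker change, nor show a turn initiation that was abandoned before
any speech was produced.  Two breathing-based probes address this:

* **Hold-conditioned speaker change**: over all silence intervals
  (WSS and BSS), the probability of a speaker change conditional on a
  breath hold overlapping the previous speaker's post-speech exhalation.
  A high P(change | hold) relative to P(change | no hold) indicates holds
  are reactive (warding off incoming talk) rather than turn-holding cues.

* **Abandoned initiation candidates**: silent breathing cycles whose
  exhalation carries a hold in the top 20% of the exhalation amplitude —
  the speaker inhaled, held their breath at the top, and exhaled without
  speaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chronography import BaseCategory, TTEvent, TTKind, TurnEvent, anchoring_exhalation
from .feature_extraction import inhalation_features
from .hold_detector import BreathHold
from .signal_core import BreathCycle, Calibration


@dataclass(frozen=True)
class AbandonedCandidate:
    """A silent cycle with a hold near the top of its exhalation.

    ``rel_time_pos``/``rel_amp_pos`` locate the hold start as fractions of
    the exhalation duration and of the amplitude descended.
    """

    cycle_index: int
    hold: BreathHold
    rel_time_pos: float
    rel_amp_pos: float


@dataclass
class HoldConditionTable:
    """Counts and conditional probabilities of speaker change by hold status.

    Probabilities are None when their stratum is empty.
    """

    n_silence_with_hold: int
    n_silence_without_hold: int
    n_change_with_hold: int
    n_change_without_hold: int

    @property
    def p_change_given_hold(self) -> float | None:
        if self.n_silence_with_hold == 0:
            return None
        return self.n_change_with_hold / self.n_silence_with_hold

    @property
    def p_change_given_no_hold(self) -> float | None:
        if self.n_silence_without_hold == 0:
            return None
        return self.n_change_without_hold / self.n_silence_without_hold

    @property
    def p_change_marginal(self) -> float | None:
        n = self.n_silence_with_hold + self.n_silence_without_hold
        if n == 0:
            return None
        return (self.n_change_with_hold + self.n_change_without_hold) / n


def hold_position(hold: BreathHold, cycle: BreathCycle) -> tuple[float, float]:
    """Relative position of a hold within its cycle's exhalation.

    Returns ``(rel_time_pos, rel_amp_pos)``: the hold start as a fraction
    of the exhalation duration, and the fraction of the exhalation
    amplitude already descended at the hold level.  Both are clipped to
    [0, 1].
    """
    exh_dur = cycle.exhalation_duration
    amp = cycle.v_peak - cycle.v_offset
    if amp <= 0:
        raise ValueError("zero-amplitude exhalation")
    rel_t = (hold.t_start - cycle.t_peak) / exh_dur
    rel_a = (cycle.v_peak - hold.level) / amp
    clip = lambda v: min(1.0, max(0.0, v))
    return clip(rel_t), clip(rel_a)


def abandoned_candidates(
    cycles: Sequence[BreathCycle],
    silent_holds: Sequence[BreathHold],
    calib: Calibration | None = None,
    top_frac: float = 0.2,
) -> list[AbandonedCandidate]:
    """Holds in the top ``top_frac`` of the exhalation amplitude of silent
    cycles.

    ``silent_holds`` must already be restricted to silent exhalations
    (:func:`respchron.hold_detector.filter_silent_holds`); ``cycles`` carry
    their ``silent`` flags.  When a calibration is given, the hold level is
    compared against cycle landmarks in SV units; otherwise landmark values
    are assumed to share the hold's scale.
    """
    by_index = {c.index: c for c in cycles}
    out = []
    for h in silent_holds:
        c = by_index.get(h.cycle_index)
        if c is None or c.silent is False:
            continue
        if calib is not None:
            c = _cycle_in_sv(c, calib)
        rel_t, rel_a = hold_position(h, c)
        if rel_a <= top_frac:
            out.append(
                AbandonedCandidate(
                    cycle_index=h.cycle_index, hold=h,
                    rel_time_pos=rel_t, rel_amp_pos=rel_a,
                )
            )
    return out


def _cycle_in_sv(c: BreathCycle, calib: Calibration) -> BreathCycle:
    from dataclasses import replace

    return replace(
        c,
        v_onset=float(calib.to_sv(c.t_onset, c.v_onset)),
        v_peak=float(calib.to_sv(c.t_peak, c.v_peak)),
        v_offset=float(calib.to_sv(c.t_offset, c.v_offset)),
    )


def speaker_change_given_hold(
    events: Sequence[TurnEvent],
    holds_by_speaker: Mapping[str, Sequence[BreathHold]],
    cycles_by_speaker: Mapping[str, Sequence[BreathCycle]],
    include_excluded: bool = False,
) -> HoldConditionTable:
    """Conditional probabilities of speaker change given a breath hold.

    Silences are all (by default non-excluded) WSS and BSS events; a hold
    co-occurs with a silence when it overlaps the anchoring exhalation of
    the previous speaker.  Speaker change corresponds to BSS.
    """
    n_sh = n_snh = n_ch = n_cnh = 0
    for ev in events:
        if ev.base not in (BaseCategory.WSS, BaseCategory.BSS):
            continue
        if ev.excluded is not None and not include_excluded:
            continue
        cyc = anchoring_exhalation(ev, cycles_by_speaker.get(ev.prev_speaker, ()))
        has_hold = False
        if cyc is not None:
            # an exhalation hosting several talkspurts anchors several
            # events; a hold co-occurs with the event whose silent stretch
            # (talkspurt offset up to the speaker's next own talkspurt, or
            # the exhalation offset) contains it
            lo = max(cyc.t_peak, ev.prev_ts.t_end)
            hi = cyc.t_offset
            if ev.next_own_ts is not None:
                hi = min(hi, ev.next_own_ts.t_start)
            has_hold = any(
                h.t_start < hi and h.t_end > lo
                for h in holds_by_speaker.get(ev.prev_speaker, ())
            )
        change = ev.base is BaseCategory.BSS
        if has_hold:
            n_sh += 1
            n_ch += change
        else:
            n_snh += 1
            n_cnh += change
    return HoldConditionTable(
        n_silence_with_hold=n_sh,
        n_silence_without_hold=n_snh,
        n_change_with_hold=n_ch,
        n_change_without_hold=n_cnh,
    )


def compare_silent_cycle_inhalations(
    cycles: Sequence[BreathCycle],
    candidates: Sequence[AbandonedCandidate],
    tts: Sequence[TTEvent],
    calib: Calibration,
    speaker_id: str | None = None,
    min_duration_s: float = 0.01,
) -> pd.DataFrame:
    """Three-group inhalation table: Silent, Hold, and TT(S) cycles.

    Every analyzed silent cycle appears exactly once: in the Hold group if
    it is an abandoned-initiation candidate, in the TT(S) group if its
    inhalation precedes a TT(S) turn initiation, otherwise in Silent.
    Columns: group, inhalation duration (log2 s) and amplitude (SV units).
    """
    hold_idx = {c.cycle_index for c in candidates}
    tts_idx = {
        tt.inhalation_cycle.index
        for tt in tts
        if tt.kind is TTKind.TT_S
        and (speaker_id is None or tt.incoming_speaker == speaker_id)
    }
    rows = []
    for c in cycles:
        if c.index in tts_idx:
            group = "TT(S)"
        elif c.silent is not True:
            continue
        elif c.index in hold_idx:
            group = "Hold"
        else:
            group = "Silent"
        feats = inhalation_features(c, calib, min_duration_s=min_duration_s)
        rows.append(
            {
                "speaker_id": speaker_id or "",
                "cycle_index": c.index,
                "group": group,
                "inh_duration_log2s": feats["inh_duration_log2s"],
                "inh_amplitude_sv": feats["inh_amplitude_sv"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["speaker_id", "cycle_index", "group",
                 "inh_duration_log2s", "inh_amplitude_sv"],
    )
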