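"""Interaction chronography: talkspurts and augmented turn-taking categories.

A conversation is represented mechanistically as each speaker's talkspurts
(interpausal units): stretches of voice activity delimited by pauses of at
least 200 ms.  Every pair of temporally adjacent talkspurts defines one
interactional interval, classified by two criteria — presence of speaker
change and presence of overlapping speech — into the four classic chronogram
categories:

* WSS / WSO: within-speaker silence / overlap (no speaker change),
* BSS / BSO: between-speaker silence / overlap (speaker change).

WSS, BSS and BSO are further augmented by whether the *previous* speaker's
next own talkspurt is preceded by an inhalation (+INH) or continues on the
same exhalation (-INH); lack of an inhalation is treated downstream as a
proxy for pragmatic incompleteness of the preceding speech.  Turn-initial
talkspurts are additionally classified from the incoming speaker's side as
TT(S) (onset after silence) or TT(O) (onset in overlap).

Intervals bounded by backchannels (talkspurts shorter than 1 s), overlapping
laughter, or whose speech edges coincide with an inhalation are flagged for
exclusion rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .signal_core import BreathCycle

BACKCHANNEL_MAX_S = 1.0


class BaseCategory(str, Enum):
    WSS = "WSS"
    WSO = "WSO"
    BSS = "BSS"
    BSO = "BSO"


class InhStatus(str, Enum):
    PLUS = "+INH"
    MINUS = "-INH"
    NA = "n/a"


class ExclusionReason(str, Enum):
    LAUGHTER = "laughter"
    BACKCHANNEL = "backchannel"
    EDGE_INHALATION = "edge_inhalation"
    MISSED_INHALATION_SUSPECT = "missed_inhalation_suspect"
    EXTREME_SLOPE = "extreme_slope"


@dataclass(frozen=True)
class Talkspurt:
    """A pause-merged speech interval (interpausal unit)."""

    speaker_id: str
    t_start: float
    t_end: float
    contains_laughter: bool = False

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("talkspurt must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def is_backchannel(self) -> bool:
        return self.duration < BACKCHANNEL_MAX_S


@dataclass
class TurnEvent:
    """A classified interactional interval between two adjacent talkspurts.

    For silence categories ``[t_start, t_end]`` is the gap; for overlap
    categories it is the overlapped span.  ``prev_ts``/``next_ts`` are the
    bounding talkspurts; for WSO, ``next_ts`` is the embedded talkspurt.
    """

    base: BaseCategory
    prev_speaker: str
    next_speaker: str
    t_start: float
    t_end: float
    prev_ts: Talkspurt
    next_ts: Talkspurt
    inh: InhStatus = InhStatus.NA
    next_own_ts: Talkspurt | None = None
    excluded: ExclusionReason | None = None

    @property
    def category(self) -> str:
        """Augmented label, e.g. ``'BSS+INH'`` or ``'WSO'``."""
        if self.base is BaseCategory.WSO or self.inh is InhStatus.NA:
            return self.base.value
        return self.base.value + ("+INH" if self.inh is InhStatus.PLUS else "-INH")


class TTKind(str, Enum):
    TT_S = "TT(S)"
    TT_O = "TT(O)"


@dataclass
class TTEvent:
    """A turn-initial talkspurt viewed from the incoming speaker.

    ``inhalation_cycle`` is the incoming speaker's breathing cycle whose
    inhalation immediately precedes the talkspurt onset.
    """

    kind: TTKind
    incoming_speaker: str
    talkspurt: Talkspurt
    inhalation_cycle: BreathCycle
    excluded: ExclusionReason | None = None


class InputFormatError(ValueError):
    pass


def merge_talkspurts(
    raw_intervals: Iterable[tuple[float, float]],
    speaker_id: str,
    min_pause_s: float = 0.2,
    laughter: Sequence[tuple[float, float]] = (),
) -> list[Talkspurt]:
    """Merge one speaker's raw speech intervals into talkspurts.

    Same-speaker intervals separated by gaps shorter than ``min_pause_s``
    (default 200 ms) are merged; the backchannel property follows from the
    1-s duration rule.  ``laughter`` intervals mark overlapping talkspurts.
    """
    ivs = sorted((float(a), float(b)) for a, b in raw_intervals)
    for (a1, b1), (a2, _) in zip(ivs, ivs[1:]):
        if a2 < b1:
            raise InputFormatError(
                f"overlapping input intervals for speaker {speaker_id!r} "
                f"at {a2:.3f}s"
            )
    merged: list[list[float]] = []
    for a, b in ivs:
        if merged and a - merged[-1][1] < min_pause_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        has_laugh = any(la < b and lb > a for la, lb in laughter)
        out.append(
            Talkspurt(speaker_id=speaker_id, t_start=a, t_end=b,
                      contains_laughter=has_laugh)
        )
    return out


def classify_intervals(talkspurts: Sequence[Talkspurt]) -> list[TurnEvent]:
    """Classify every adjacent-talkspurt interval into WSS/WSO/BSS/BSO.

    Each talkspurt offset is paired with the temporally next talkspurt
    onset, any speaker.  Gap > 0 yields WSS (same speaker) or BSS (speaker
    change); an onset before the offset yields BSO when the incomer outlasts
    the current talkspurt, and a WSO event when it is fully embedded (the
    scan then continues to the next onset).  Simultaneous onsets break
    toward the longer incoming talkspurt.
    """
    ts = sorted(talkspurts, key=lambda s: (s.t_start, -s.duration))
    events: list[TurnEvent] = []
    for i, a in enumerate(ts):
        for b in ts[i + 1:]:
            if b.speaker_id == a.speaker_id and b.t_start < a.t_end:
                raise InputFormatError("same-speaker talkspurts overlap")
            if b.t_start >= a.t_end:
                gap = b.t_start - a.t_end
                if gap <= 0:
                    continue  # knife-edge adjacency: no interval to classify
                base = (BaseCategory.WSS if b.speaker_id == a.speaker_id
                        else BaseCategory.BSS)
                events.append(
                    TurnEvent(base=base, prev_speaker=a.speaker_id,
                              next_speaker=b.speaker_id,
                              t_start=a.t_end, t_end=b.t_start,
                              prev_ts=a, next_ts=b)
                )
                break
            if b.t_end <= a.t_end:
                # embedded talkspurt: a WSO in A's context; keep scanning
                events.append(
                    TurnEvent(base=BaseCategory.WSO, prev_speaker=a.speaker_id,
                              next_speaker=a.speaker_id,
                              t_start=b.t_start, t_end=b.t_end,
                              prev_ts=a, next_ts=b)
                )
                continue
            events.append(
                TurnEvent(base=BaseCategory.BSO, prev_speaker=a.speaker_id,
                          next_speaker=b.speaker_id,
                          t_start=b.t_start, t_end=a.t_end,
                          prev_ts=a, next_ts=b)
            )
            break
    events.sort(key=lambda e: (e.t_start, e.t_end))
    return events


def _next_own_talkspurt(
    event: TurnEvent, talkspurts: Sequence[Talkspurt]
) -> Talkspurt | None:
    later = [
        s for s in talkspurts
        if s.speaker_id == event.prev_speaker and s.t_start >= event.prev_ts.t_end
    ]
    return min(later, key=lambda s: s.t_start) if later else None


def augment_inh(
    event: TurnEvent,
    prev_speaker_cycles: Sequence[BreathCycle],
    talkspurts: Sequence[Talkspurt],
) -> TurnEvent:
    """Set the +/-INH status of a WSS/BSS/BSO event.

    +INH iff an inhalation onset of the previous speaker falls strictly
    between the anchoring talkspurt's offset and that speaker's next own
    talkspurt onset; -INH when the next own talkspurt continues on the same
    exhalation.  Events whose previous speaker never speaks again stay n/a
    and are excluded from feature analysis.
    """
    if event.base is BaseCategory.WSO:
        return event
    nxt = _next_own_talkspurt(event, talkspurts)
    if nxt is None:
        return replace(event, inh=InhStatus.NA, next_own_ts=None)
    lo, hi = event.prev_ts.t_end, nxt.t_start
    has_inh = any(lo < c.t_onset < hi for c in prev_speaker_cycles)
    return replace(
        event,
        inh=InhStatus.PLUS if has_inh else InhStatus.MINUS,
        next_own_ts=nxt,
    )


def _in_inhalation(t: float, cycles: Sequence[BreathCycle]) -> bool:
    return any(c.t_onset <= t < c.t_peak for c in cycles)


def anchoring_exhalation(
    event: TurnEvent, prev_speaker_cycles: Sequence[BreathCycle]
) -> BreathCycle | None:
    """The previous speaker's cycle whose exhalation spans the talkspurt offset."""
    t = event.prev_ts.t_end
    for c in prev_speaker_cycles:
        if c.t_peak <= t < c.t_offset:
            return c
    return None


def _max_cumulative_rise(trace, t_a: float, t_b: float) -> tuple[float, float]:
    """Largest ascent within [t_a, t_b] and the segment's amplitude."""
    times = trace.times
    sel = (times >= t_a) & (times <= t_b)
    seg = trace.samples[sel]
    if seg.size < 2:
        return 0.0, 0.0
    rise = float(np.max(seg - np.minimum.accumulate(seg)))
    return rise, float(seg.max() - seg.min())


def apply_exclusions(
    events: Sequence[TurnEvent],
    cycles_by_speaker: Mapping[str, Sequence[BreathCycle]],
    laughter_by_speaker: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    flag_missed_inhalations: bool = True,
    traces_by_speaker: Mapping[str, object] | None = None,
    rise_frac: float = 0.2,
    duration_ratio: float = 2.0,
) -> list[TurnEvent]:
    """Flag events excluded from feature analysis (nothing is deleted).

    Reasons, in precedence order: overlapping laughter (interval or bounding
    talkspurts), a backchannel bounding talkspurt, a speech edge falling
    inside an inhalation, and — for -INH events — a suspected missed
    inhalation in the anchoring exhalation (an automatic stand-in for a
    manual check).

    The missed-inhalation probe looks for direct evidence: when traces are
    supplied, a -INH event is flagged if the signal rises by more than
    ``rise_frac`` of the exhalation amplitude inside the anchoring
    exhalation (a small inhalation the segmentation merged away).  Without
    traces, a cruder duration heuristic flags exhalations longer than
    ``duration_ratio`` times the speaker's median cycle duration; note it
    also hits legitimately long waits such as held pause interruptions.
    """
    laughter_by_speaker = laughter_by_speaker or {}
    traces_by_speaker = traces_by_speaker or {}
    median_cycle: dict[str, float] = {
        spk: float(np.median([c.duration for c in cyc])) if cyc else np.inf
        for spk, cyc in cycles_by_speaker.items()
    }
    all_laughs = [iv for ivs in laughter_by_speaker.values() for iv in ivs]
    out = []
    for ev in events:
        reason: ExclusionReason | None = None
        spans = [(ev.t_start, ev.t_end),
                 (ev.prev_ts.t_start, ev.prev_ts.t_end),
                 (ev.next_ts.t_start, ev.next_ts.t_end)]
        laugh_hit = (
            ev.prev_ts.contains_laughter or ev.next_ts.contains_laughter
            or any(la < b and lb > a for a, b in spans for la, lb in all_laughs)
        )
        if laugh_hit:
            reason = ExclusionReason.LAUGHTER
        elif ev.prev_ts.is_backchannel or ev.next_ts.is_backchannel:
            reason = ExclusionReason.BACKCHANNEL
        else:
            prev_cycles = cycles_by_speaker.get(ev.prev_speaker, ())
            next_cycles = cycles_by_speaker.get(ev.next_speaker, ())
            if (_in_inhalation(ev.prev_ts.t_end, prev_cycles)
                    or _in_inhalation(ev.next_ts.t_start, next_cycles)):
                reason = ExclusionReason.EDGE_INHALATION
            elif flag_missed_inhalations and ev.inh is InhStatus.MINUS:
                anchor = anchoring_exhalation(ev, prev_cycles)
                trace = traces_by_speaker.get(ev.prev_speaker)
                if anchor is not None and trace is not None:
                    rise, amp = _max_cumulative_rise(
                        trace, anchor.t_peak, anchor.t_offset)
                    if amp > 0 and rise >= rise_frac * amp:
                        reason = ExclusionReason.MISSED_INHALATION_SUSPECT
                elif (anchor is not None
                        and anchor.exhalation_duration
                        > duration_ratio * median_cycle.get(
                            ev.prev_speaker, np.inf)):
                    reason = ExclusionReason.MISSED_INHALATION_SUSPECT
        out.append(replace(ev, excluded=reason))
    return out


def preceding_inhalation(
    t_onset: float, cycles: Sequence[BreathCycle]
) -> BreathCycle | None:
    """The cycle whose inhalation onset most recently precedes ``t_onset``."""
    before = [c for c in cycles if c.t_onset < t_onset]
    return max(before, key=lambda c: c.t_onset) if before else None


def tt_events(
    events: Sequence[TurnEvent],
    cycles_by_speaker: Mapping[str, Sequence[BreathCycle]],
    talkspurts: Sequence[Talkspurt] | None = None,
) -> list[TTEvent]:
    """Turn-initial talkspurts from the incoming speaker's side.

    A talkspurt effecting a speaker change (the incoming side of a BSS or
    BSO event) yields one TT event: TT(S) when its onset follows silence
    across all speakers, TT(O) when any other speaker is talking at the
    onset — in three-party talk the two can differ from the underlying
    event's base, and one talkspurt may close several between-speaker
    events.  Requires a preceding own inhalation.  The exclusion flag is
    clear when any underlying event is clean.
    """
    if talkspurts is None:
        talkspurts = sorted(
            {id(ts): ts for e in events
             for ts in (e.prev_ts, e.next_ts)}.values(),
            key=lambda s: s.t_start,
        )
    seen: dict[tuple, TTEvent] = {}
    for ev in events:
        if ev.base not in (BaseCategory.BSS, BaseCategory.BSO):
            continue
        b = ev.next_ts
        key = (b.speaker_id, b.t_start, b.t_end)
        if key in seen:
            if ev.excluded is None:
                seen[key].excluded = None
            continue
        cyc = preceding_inhalation(
            b.t_start, cycles_by_speaker.get(ev.next_speaker, ())
        )
        if cyc is None:
            continue
        overlapped = any(
            ts.speaker_id != b.speaker_id
            and ts.t_start <= b.t_start < ts.t_end
            for ts in talkspurts
        )
        seen[key] = TTEvent(
            kind=TTKind.TT_O if overlapped else TTKind.TT_S,
            incoming_speaker=ev.next_speaker,
            talkspurt=b,
            inhalation_cycle=cyc,
            excluded=ev.excluded,
        )
    return sorted(seen.values(), key=lambda t: t.talkspurt.t_start)
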