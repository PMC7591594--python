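"""Breath-hold detection: plateaus in the lung-volume trace.

A breath hold — airflow suspended with the glottis or articulators closed —
shows up as a plateau in a RIP trace recorded without high-pass filtering.
Following the histogram-mode approach developed for airflow recordings, each
breathing cycle's sample values are histogrammed; a prominent histogram peak
marks a level at which the signal dwells, and the hold is the maximal time
interval during which the signal stays within a small margin of that level.

Defaults: minimum hold duration 250 ms, minimum gap between holds 150 ms
(closer holds at one level are merged), 100 histogram bins, prominence
threshold 3x the median bin count, margin +/-2.5% of the cycle amplitude.

Because slowly decaying speech segments mimic plateaus, downstream analysis
keeps only holds produced during silent exhalations
(:func:`filter_silent_holds`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .signal_core import BreathCycle, CalibrationState, RIPTrace


@dataclass(frozen=True)
class BreathHold:
    """A plateau interval within one breathing cycle.

    ``level`` is the plateau's signal level (SV units).  ``in_exhalation``
    is True when at least half of the hold's duration falls after the
    cycle's peak landmark.  ``during_silence`` is set by
    :func:`filter_silent_holds`.
    """

    cycle_index: int
    t_start: float
    t_end: float
    level: float
    in_exhalation: bool
    during_silence: bool | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("hold must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _prominent_levels(
    values: np.ndarray, n_bins: int, prominence_ratio: float
) -> list[float]:
    """Histogram-mode levels: local-maximum bins with prominent counts."""
    counts, edges = np.histogram(values, bins=n_bins)
    threshold = prominence_ratio * float(np.median(counts))
    centers = 0.5 * (edges[:-1] + edges[1:])
    levels = []
    for i in np.argsort(counts)[::-1]:
        c = counts[i]
        if c < threshold or c == 0:
            break
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n_bins - 1 else -1
        if c >= left and c >= right:
            levels.append(float(centers[i]))
    return levels


def _runs_at_level(
    t: np.ndarray, x: np.ndarray, level: float, margin: float
) -> list[tuple[float, float]]:
    """Maximal index runs where |x - level| <= margin, as (t_start, t_end)."""
    inside = np.abs(x - level) <= margin
    if not inside.any():
        return []
    d = np.diff(inside.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if inside[0]:
        starts.insert(0, 0)
    if inside[-1]:
        ends.append(inside.size)
    return [(float(t[a]), float(t[b - 1])) for a, b in zip(starts, ends) if b - a >= 2]


def _merge_close(
    runs: list[tuple[float, float]], min_gap_s: float
) -> list[tuple[float, float]]:
    runs = sorted(runs)
    merged: list[tuple[float, float]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < min_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def detect_holds(
    trace: RIPTrace,
    cycle: BreathCycle,
    min_hold_s: float = 0.25,
    min_gap_s: float = 0.15,
    margin_frac: float = 0.025,
    n_bins: int = 100,
    prominence_ratio: float = 3.0,
) -> list[BreathHold]:
    """Detect plateau holds within one breathing cycle.

    Parameters
    ----------
    trace : RIPTrace
        The speaker's trace in SV units (cycle landmark times index into it).
    cycle : BreathCycle
        The cycle to scan.
    min_hold_s, min_gap_s : float
        Minimum hold duration (shorter runs dropped) and minimum gap between
        holds at one level (closer runs merged), in seconds.
    margin_frac : float
        Half-width of the dwell band around a histogram-mode level, as a
        fraction of the cycle amplitude ``v_peak - v_offset``.
    n_bins, prominence_ratio : int, float
        Histogram resolution and the prominence threshold (multiple of the
        median bin count) a mode must reach.
    """
    if trace.calibration is not CalibrationState.SV_UNITS:
        raise ValueError("detect_holds expects a trace in SV units")
    if cycle.duration < min_hold_s:
        return []
    times = trace.times
    sel = (times >= cycle.t_onset) & (times <= cycle.t_offset)
    t, x = times[sel], trace.samples[sel]
    if t.size < 4:
        return []
    amplitude = trace.value_at(cycle.t_peak) - trace.value_at(cycle.t_offset)
    if amplitude <= 0:
        amplitude = float(x.max() - x.min())
    if amplitude <= 0:
        return []
    margin = margin_frac * amplitude

    holds: list[BreathHold] = []
    for level in _prominent_levels(x, n_bins, prominence_ratio):
        runs = _merge_close(_runs_at_level(t, x, level, margin), min_gap_s)
        for a, b in runs:
            if b - a >= min_hold_s:
                dur_after_peak = max(0.0, b - max(a, cycle.t_peak))
                holds.append(
                    BreathHold(
                        cycle_index=cycle.index,
                        t_start=a,
                        t_end=b,
                        level=level,
                        in_exhalation=dur_after_peak >= 0.5 * (b - a),
                    )
                )
    # resolve overlaps across levels: keep the longer hold
    holds.sort(key=lambda h: (-(h.duration), h.t_start))
    kept: list[BreathHold] = []
    for h in holds:
        if all(h.t_end <= k.t_start or h.t_start >= k.t_end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.t_start)
    return kept


def detect_all_holds(
    trace: RIPTrace, cycles: Sequence[BreathCycle], **kwargs
) -> list[BreathHold]:
    """Run :func:`detect_holds` over every cycle of a trace."""
    out: list[BreathHold] = []
    for c in cycles:
        out.extend(detect_holds(trace, c, **kwargs))
    return out


def filter_silent_holds(
    holds: Sequence[BreathHold],
    own_talkspurts: Sequence[tuple[float, float]],
    min_hold_s: float = 0.25,
) -> list[BreathHold]:
    """Keep exhalation holds produced during silent (non-speech) portions.

    Speech segments can mimic plateaus; restricting candidates to silent
    exhalations is the guard against that.  A hold whose dwell band bleeds
    marginally into adjacent speech is trimmed to its longest silent
    sub-span and kept when that span still lasts ``min_hold_s``; holds
    mostly inside own speech are dropped.  Sets ``during_silence``.
    """
    spans = sorted((float(a), float(b)) for a, b in own_talkspurts)
    out = []
    for h in holds:
        if not h.in_exhalation:
            continue
        # silent sub-spans of the hold
        silent_spans: list[tuple[float, float]] = []
        cursor = h.t_start
        for a, b in spans:
            if b <= cursor or a >= h.t_end:
                continue
            if a > cursor:
                silent_spans.append((cursor, min(a, h.t_end)))
            cursor = max(cursor, b)
        if cursor < h.t_end:
            silent_spans.append((cursor, h.t_end))
        if not silent_spans:
            continue
        a, b = max(silent_spans, key=lambda s: s[1] - s[0])
        if b - a >= min_hold_s:
            out.append(replace(h, t_start=a, t_end=b, during_silence=True))
    return out
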