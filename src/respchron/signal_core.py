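"""Breathing-signal normalization, cycle segmentation and calibration.

A respiratory inductance plethysmography (RIP) belt pair yields a single
lung-volume proxy per speaker, in arbitrary units.  This module turns such a
trace into a sequence of breathing cycles (trough -> peak -> trough) and
estimates the two per-speaker calibration quantities used throughout the
pipeline:

* **SV** (speaking volume): the 5th-95th percentile span of all peak and
  trough values, used as the amplitude/level unit.
* **REL** (resting expiratory level): the dynamic baseline, estimated as the
  median trough value within a sliding 60-s window; REL maps to 0 in
  calibrated units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d


class CalibrationState(str, Enum):
    RAW = "raw"
    ZSCORED = "zscored"
    SV_UNITS = "sv_units"


class DegenerateSignalError(ValueError):
    """Raised for traces or calibrations with no usable variation."""


@dataclass(frozen=True)
class RIPTrace:
    """One speaker's uniformly sampled lung-volume proxy.

    Parameters
    ----------
    speaker_id : str
        Identifier consistent with the speech-activity annotations.
    samples : np.ndarray
        Lung-volume values (arbitrary units before calibration).
    sample_rate : float
        Sampling frequency in Hz.
    calibration : CalibrationState
        Which normalization has been applied.
    t0 : float
        Time of the first sample, in seconds.
    """

    speaker_id: str
    samples: np.ndarray
    sample_rate: float
    calibration: CalibrationState = CalibrationState.RAW
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace needs at least 2 samples in one channel")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sample_rate

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at time(s) ``t``."""
        return np.interp(t, self.times, self.samples)


@dataclass(frozen=True)
class BreathCycle:
    """One inhalation + exhalation delimited by trough/peak/trough landmarks.

    The inhalation is ``[t_onset, t_peak]``, the exhalation
    ``[t_peak, t_offset]``.  ``silent`` is set once speech activity is known:
    True when no own talkspurt overlaps the cycle.
    """

    t_onset: float
    t_peak: float
    t_offset: float
    v_onset: float
    v_peak: float
    v_offset: float
    silent: bool | None = None
    index: int = -1

    def __post_init__(self) -> None:
        if not (self.t_onset < self.t_peak < self.t_offset):
            raise ValueError("cycle landmarks must be time-ordered")
        if not (self.v_peak > self.v_onset and self.v_peak > self.v_offset):
            raise ValueError("peak value must exceed both trough values")

    @property
    def inhalation_duration(self) -> float:
        return self.t_peak - self.t_onset

    @property
    def exhalation_duration(self) -> float:
        return self.t_offset - self.t_peak

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset


@dataclass
class Calibration:
    """Per-speaker SV span and dynamic REL track.

    ``rel_track`` holds (time, REL) pairs evaluated at trough times; REL at
    arbitrary times is linearly interpolated with constant extrapolation.
    """

    sv: float
    rel_times: np.ndarray
    rel_values: np.ndarray
    window_s: float = 60.0
    _rel_interp: interp1d = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        self.rel_values = np.asarray(self.rel_values, dtype=float)
        if self.sv <= 0:
            raise DegenerateSignalError("SV span must be positive")
        if np.any(np.diff(self.rel_times) <= 0):
            raise ValueError("rel_track times must be strictly increasing")
        if self.rel_times.size == 1:
            t, v = float(self.rel_times[0]), float(self.rel_values[0])
            self._rel_interp = lambda x: np.full_like(np.asarray(x, float), v)  # type: ignore[assignment]
        else:
            self._rel_interp = interp1d(
                self.rel_times, self.rel_values, bounds_error=False,
                fill_value=(self.rel_values[0], self.rel_values[-1]),
            )

    def rel_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.asarray(self._rel_interp(t))

    def to_sv(self, t: float | np.ndarray, value: float | np.ndarray) -> np.ndarray:
        """Map a raw-scale value at time ``t`` to SV units (REL -> 0)."""
        return (np.asarray(value, float) - self.rel_at(t)) / self.sv


def zscore_trace(trace: RIPTrace) -> RIPTrace:
    """Standardize a raw trace to mean 0, SD 1 over the whole conversation.

    Raises
    ------
    DegenerateSignalError
        If the trace is constant (zero sample standard deviation).
    """
    if trace.calibration is not CalibrationState.RAW:
        raise ValueError("zscore_trace expects a raw trace")
    mu = float(np.mean(trace.samples))
    sd = float(np.std(trace.samples, ddof=1))
    if sd == 0.0:
        raise DegenerateSignalError(
            f"constant trace for speaker {trace.speaker_id!r}: SD is 0"
        )
    return replace(
        trace,
        samples=(trace.samples - mu) / sd,
        calibration=CalibrationState.ZSCORED,
    )


def resample_trace(trace: RIPTrace, rate_hz: float = 100.0) -> RIPTrace:
    """Resample to a uniform working rate by linear interpolation."""
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if abs(rate_hz - trace.sample_rate) < 1e-12:
        return trace
    n_out = max(2, int(np.floor(trace.duration * rate_hz)) + 1)
    t_new = trace.t0 + np.arange(n_out) / rate_hz
    return replace(
        trace,
        samples=np.interp(t_new, trace.times, trace.samples),
        sample_rate=rate_hz,
    )


def smooth_trace(trace: RIPTrace, window_s: float = 0.2) -> RIPTrace:
    """Low-pass the trace with a normalized Hann window.

    Used before extremum search so that sensor noise does not jitter the
    located peak and trough positions; plateau analysis should use the
    unsmoothed trace.
    """
    w = int(round(window_s * trace.sample_rate))
    if w < 3:
        return trace
    win = np.hanning(w)
    win /= win.sum()
    padded = np.pad(trace.samples, w, mode="edge")
    return replace(trace, samples=np.convolve(padded, win, "same")[w:-w])


def _local_extrema(x: np.ndarray) -> list[tuple[int, bool]]:
    """Time-ordered (index, is_peak) for all local extrema.

    Flat extrema (runs of equal values) are represented by the run's first
    sample.  Endpoints are never extrema.
    """
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return []
    signs = np.sign(d[nz])
    change = np.flatnonzero(signs[:-1] != signs[1:])
    idx = nz[change] + 1          # first sample of the extremal (flat) run
    is_peak = signs[change] > 0
    return [(int(i), bool(p)) for i, p in zip(idx, is_peak)]


def _alternating_landmarks(
    x: np.ndarray, min_sep: float
) -> list[tuple[int, bool]]:
    """Alternating (index, is_peak) landmark sequence with value separation.

    All local extrema are found first (strictly alternating by
    construction); adjacent peak/trough pairs whose values differ by less
    than ``min_sep`` are then pruned, weakest pair first, until every
    surviving adjacent pair is separated by at least ``min_sep``.  Removing
    an adjacent opposite-type pair preserves alternation, so this greedy
    pruning is well defined; a heap over pair differences makes it
    O(n log n).
    """
    import heapq

    marks = _local_extrema(x)
    n = len(marks)
    if n == 0:
        return []
    values = np.array([x[i] for i, _ in marks])
    prev = np.arange(n) - 1
    nxt = np.arange(n) + 1
    alive = np.ones(n, dtype=bool)

    heap: list[tuple[float, int, int]] = [
        (abs(values[k + 1] - values[k]), k, k + 1) for k in range(n - 1)
    ]
    heapq.heapify(heap)
    while heap:
        diff, i, j = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or nxt[i] != j:
            continue
        if diff >= min_sep:
            break
        alive[i] = alive[j] = False
        p, q = prev[i], nxt[j]
        if p >= 0:
            nxt[p] = q
        if q < n:
            prev[q] = p
        if p >= 0 and q < n:
            heapq.heappush(heap, (abs(values[q] - values[p]), p, q))
    return [marks[k] for k in range(n) if alive[k]]


def segment_cycles(trace: RIPTrace, min_sep: float = 1.0) -> list[BreathCycle]:
    """Segment a z-scored trace into breathing cycles.

    Peaks and troughs are located as alternating local extrema separated by
    at least ``min_sep`` (default one standard deviation of the z-scored
    signal).  Each cycle is a trough/peak/trough triple; consecutive cycles
    share their boundary trough.  Returns an empty list when no landmark
    pair satisfies the separation criterion.
    """
    if trace.calibration is not CalibrationState.ZSCORED:
        raise ValueError("segment_cycles expects a z-scored trace")
    x = trace.samples
    marks = _alternating_landmarks(x, min_sep)
    times = trace.times

    cycles: list[BreathCycle] = []
    k = 0
    n = 0
    while k + 2 < len(marks):
        (i0, p0), (i1, p1), (i2, p2) = marks[k], marks[k + 1], marks[k + 2]
        if not p0 and p1 and not p2:
            cycles.append(
                BreathCycle(
                    t_onset=float(times[i0]),
                    t_peak=float(times[i1]),
                    t_offset=float(times[i2]),
                    v_onset=float(x[i0]),
                    v_peak=float(x[i1]),
                    v_offset=float(x[i2]),
                    index=n,
                )
            )
            n += 1
            k += 2  # boundary trough shared with the next cycle
        else:
            k += 1
    return cycles


def estimate_sv(
    cycles: Sequence[BreathCycle],
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> float:
    """Speaking volume: percentile span of pooled peak and trough values.

    The pooled multiset is ``{v_peak} U {v_onset, v_offset}`` over all
    cycles; percentiles use linear interpolation between order statistics.
    """
    if len(cycles) < 2:
        raise ValueError("estimate_sv needs at least 2 cycles")
    pooled = np.concatenate(
        [
            [c.v_peak for c in cycles],
            [c.v_onset for c in cycles],
            [c.v_offset for c in cycles],
        ]
    )
    sv = float(
        np.percentile(pooled, upper_pct) - np.percentile(pooled, lower_pct)
    )
    if sv == 0.0:
        raise DegenerateSignalError("pooled landmark values are all equal")
    return sv


def trough_track(cycles: Sequence[BreathCycle]) -> tuple[np.ndarray, np.ndarray]:
    """Unique (time, value) trough landmarks, time-sorted.

    Shared boundary troughs between consecutive cycles are counted once.
    """
    seen: dict[float, float] = {}
    for c in cycles:
        seen.setdefault(c.t_onset, c.v_onset)
        seen.setdefault(c.t_offset, c.v_offset)
    times = np.array(sorted(seen))
    return times, np.array([seen[t] for t in times])


def estimate_rel(
    cycles: Sequence[BreathCycle],
    t: float,
    window_s: float = 60.0,
    mode: str = "centred",
) -> float:
    """Resting expiratory level at time ``t``.

    Median of trough values within a ``window_s`` window around ``t``
    (centred by default; ``mode='trailing'`` uses ``[t - window_s, t]``).
    Falls back to the global trough median, with a warning, when the window
    is empty.
    """
    times, values = trough_track(cycles)
    if times.size == 0:
        raise ValueError("no troughs available for REL estimation")
    if mode == "centred":
        lo, hi = t - window_s / 2.0, t + window_s / 2.0
    elif mode == "trailing":
        lo, hi = t - window_s, t
    else:
        raise ValueError(f"unknown REL window mode {mode!r}")
    mask = (times >= lo) & (times <= hi)
    if not np.any(mask):
        warnings.warn(
            f"no troughs in {window_s}-s window at t={t:.2f}s; "
            "using global trough median",
            stacklevel=2,
        )
        return float(np.median(values))
    return float(np.median(values[mask]))


def calibrate(
    cycles: Sequence[BreathCycle],
    window_s: float = 60.0,
    mode: str = "centred",
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> Calibration:
    """Estimate SV and the dynamic REL track from segmented cycles."""
    sv = estimate_sv(cycles, lower_pct=lower_pct, upper_pct=upper_pct)
    times, _ = trough_track(cycles)
    rel = np.array(
        [estimate_rel(cycles, float(t), window_s=window_s, mode=mode) for t in times]
    )
    return Calibration(sv=sv, rel_times=times, rel_values=rel, window_s=window_s)


def to_sv_units(trace: RIPTrace, calib: Calibration) -> RIPTrace:
    """Map a trace into SV units: REL maps to 0, one SV span above REL to 1."""
    rel = calib.rel_at(trace.times)
    return replace(
        trace,
        samples=(trace.samples - rel) / calib.sv,
        calibration=CalibrationState.SV_UNITS,
    )


def mark_silent_cycles(
    cycles: Sequence[BreathCycle], own_talkspurts: Sequence[tuple[float, float]]
) -> list[BreathCycle]:
    """Set each cycle's ``silent`` flag: no own talkspurt overlaps the cycle."""
    spans = sorted((float(a), float(b)) for a, b in own_talkspurts)
    out = []
    for c in cycles:
        overlaps = any(a < c.t_offset and b > c.t_onset for a, b in spans)
        out.append(replace(c, silent=not overlaps))
    return out
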