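"""Kinematic features of exhalations and inhalations around turn events.

For every non-excluded interactional interval the pipeline extracts, from
the previous speaker's post-speech exhalation:

* amplitude ``a`` (SV units), duration ``b`` (log2 s), slope ``-a/b``
  (SV/s, negative: falling lung volume), and lung-volume levels at the
  exhalation onset and offset (fractions of SV relative to REL = 0);

and, where a linked inhalation exists (+INH intervals and turn-initial
TT events), from that inhalation:

* duration ``c`` (log2 s), amplitude ``d`` (SV units), slope (SV/s,
  positive), offset level ``h``, and — when the inhalation precedes the
  same speaker's speech — the speech lag ``e`` (inhalation onset to speech
  onset, log2 s).

Rows whose slope lies at least three standard deviations from the mean of
its slope type are flagged as extreme and excluded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chronography import (
    BaseCategory,
    ExclusionReason,
    InhStatus,
    TTEvent,
    TurnEvent,
    anchoring_exhalation,
)
from .signal_core import BreathCycle, Calibration

#: columns of the wide per-event feature table
FEATURE_COLUMNS = [
    "event_id", "category", "kind", "prev_speaker", "next_speaker",
    "t_start", "t_end", "excluded",
    "exh_amplitude_sv", "exh_duration_log2s", "exh_slope_sv_per_s",
    "exh_onset_level", "exh_offset_level", "hold_present",
    "inh_duration_log2s", "inh_amplitude_sv", "inh_slope_sv_per_s",
    "inh_offset_level", "speech_lag_log2s",
]


class FeatureDataError(ValueError):
    pass


def _log2_floored(duration: float, min_duration: float) -> float:
    """log2 of a duration in seconds, floored at one sample period."""
    return float(np.log2(max(duration, min_duration)))


def exhalation_features(
    event: TurnEvent,
    cycles: Sequence[BreathCycle],
    calib: Calibration,
    holds: Sequence = (),
    min_duration_s: float = 0.01,
) -> dict | None:
    """Exhalatory features of the exhalation following the previous
    speaker's talkspurt (for WSS, the exhalation after the pre-pausal
    talkspurt).

    Returns None when no exhalation of the previous speaker spans the
    talkspurt offset (the edge falls in an inhalation; such events carry an
    exclusion flag already).
    """
    cyc = anchoring_exhalation(event, cycles)
    if cyc is None:
        return None
    dur = cyc.exhalation_duration
    if dur <= 0:
        raise FeatureDataError("non-positive exhalation duration")
    onset_level = float(calib.to_sv(cyc.t_peak, cyc.v_peak))
    offset_level = float(calib.to_sv(cyc.t_offset, cyc.v_offset))
    amplitude = onset_level - offset_level
    post_speech = max(cyc.t_peak, event.prev_ts.t_end)
    until = cyc.t_offset
    if event.next_own_ts is not None:
        until = min(until, event.next_own_ts.t_start)
    hold_present = any(
        h.t_start < until and h.t_end > post_speech for h in holds
    )
    return {
        "exh_amplitude_sv": amplitude,
        "exh_duration_log2s": _log2_floored(dur, min_duration_s),
        "exh_slope_sv_per_s": -amplitude / dur,
        "exh_onset_level": onset_level,
        "exh_offset_level": offset_level,
        "hold_present": hold_present,
        "_exh_cycle_index": cyc.index,
    }


def inhalation_features(
    cycle: BreathCycle,
    calib: Calibration,
    speech_onset: float | None = None,
    min_duration_s: float = 0.01,
    slope_denominator: str = "duration",
) -> dict:
    """Inhalatory features of one breathing cycle's inhalation.

    ``speech_onset`` (when given) must not precede the inhalation onset;
    it defines the speech lag.  The slope denominator is the inhalation
    duration by default; ``slope_denominator='speech_lag'`` divides the
    amplitude by the speech lag instead (defined only with a speech onset).
    """
    dur = cycle.inhalation_duration
    if dur <= 0:
        raise FeatureDataError("non-positive inhalation duration")
    onset_level = float(calib.to_sv(cycle.t_onset, cycle.v_onset))
    offset_level = float(calib.to_sv(cycle.t_peak, cycle.v_peak))
    amplitude = offset_level - onset_level
    lag = None
    if speech_onset is not None:
        lag = speech_onset - cycle.t_onset
        if lag < 0:
            raise FeatureDataError("speech onset precedes inhalation onset")
    if slope_denominator == "duration":
        slope = amplitude / dur
    elif slope_denominator == "speech_lag":
        if lag is None:
            raise FeatureDataError(
                "speech-lag slope requested without a speech onset"
            )
        slope = amplitude / max(lag, min_duration_s)
    else:
        raise ValueError(f"unknown slope_denominator {slope_denominator!r}")
    return {
        "inh_duration_log2s": _log2_floored(dur, min_duration_s),
        "inh_amplitude_sv": amplitude,
        "inh_slope_sv_per_s": slope,
        "inh_offset_level": offset_level,
        "speech_lag_log2s": (
            _log2_floored(lag, min_duration_s) if lag is not None else np.nan
        ),
    }


def _linked_inhalation(
    event: TurnEvent, cycles: Sequence[BreathCycle]
) -> BreathCycle | None:
    """The previous speaker's inhalation immediately preceding their next
    own talkspurt (defined for +INH events)."""
    if event.next_own_ts is None:
        return None
    lo, hi = event.prev_ts.t_end, event.next_own_ts.t_start
    between = [c for c in cycles if lo < c.t_onset < hi]
    return max(between, key=lambda c: c.t_onset) if between else None


def feature_table(
    events: Sequence[TurnEvent],
    tts: Sequence[TTEvent],
    cycles_by_speaker: Mapping[str, Sequence[BreathCycle]],
    calibs: Mapping[str, Calibration],
    holds_by_speaker: Mapping[str, Sequence] | None = None,
    min_duration_s: float = 0.01,
    slope_denominator: str = "duration",
) -> pd.DataFrame:
    """Build the wide per-event feature table for the statistical models.

    One row per WSS/BSS/BSO event (exhalatory block, plus the inhalatory
    block for +INH events) and one row per TT(S)/TT(O) event (inhalatory
    block of the incoming speaker, with speech lag).  Excluded events keep
    their rows, labelled with the exclusion reason.
    """
    holds_by_speaker = holds_by_speaker or {}
    rows: list[dict] = []
    for i, ev in enumerate(events):
        if ev.base is BaseCategory.WSO:
            continue
        row: dict = {
            "event_id": f"ev{i:05d}",
            "category": ev.category,
            "kind": "interval",
            "prev_speaker": ev.prev_speaker,
            "next_speaker": ev.next_speaker,
            "t_start": ev.t_start,
            "t_end": ev.t_end,
            "excluded": ev.excluded.value if ev.excluded else "",
        }
        cycles = cycles_by_speaker.get(ev.prev_speaker, ())
        calib = calibs[ev.prev_speaker]
        exh = exhalation_features(
            ev, cycles, calib,
            holds=holds_by_speaker.get(ev.prev_speaker, ()),
            min_duration_s=min_duration_s,
        )
        if exh is not None:
            row.update({k: v for k, v in exh.items() if not k.startswith("_")})
        if ev.inh is InhStatus.PLUS:
            cyc = _linked_inhalation(ev, cycles)
            if cyc is not None:
                speech_onset = (
                    ev.next_own_ts.t_start
                    if ev.base is BaseCategory.WSS and ev.next_own_ts else None
                )
                row.update(
                    inhalation_features(
                        cyc, calib, speech_onset=speech_onset,
                        min_duration_s=min_duration_s,
                        slope_denominator=slope_denominator
                        if speech_onset is not None else "duration",
                    )
                )
        rows.append(row)
    for j, tt in enumerate(tts):
        calib = calibs[tt.incoming_speaker]
        row = {
            "event_id": f"tt{j:05d}",
            "category": tt.kind.value,
            "kind": "turn_taking",
            "prev_speaker": "",
            "next_speaker": tt.incoming_speaker,
            "t_start": tt.talkspurt.t_start,
            "t_end": tt.talkspurt.t_end,
            "excluded": tt.excluded.value if tt.excluded else "",
        }
        row.update(
            inhalation_features(
                tt.inhalation_cycle, calib,
                speech_onset=tt.talkspurt.t_start,
                min_duration_s=min_duration_s,
                slope_denominator=slope_denominator,
            )
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[FEATURE_COLUMNS]


def flag_extreme_slopes(
    table: pd.DataFrame,
    n_sd: float = 3.0,
    columns: Sequence[str] = ("exh_slope_sv_per_s", "inh_slope_sv_per_s"),
) -> pd.DataFrame:
    """Mark rows with slopes >= ``n_sd`` standard deviations from the mean.

    Mean and SD are computed per slope type over all non-excluded rows with
    that slope defined, pooled across speakers.  An all-equal slope column
    (SD = 0) excludes nothing.  Returns a copy; already-excluded rows are
    untouched, so the operation is idempotent on its own output.
    """
    if len(table) < 2:
        return table.copy()
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        eligible = (out["excluded"] == "") & out[col].notna()
        vals = out.loc[eligible, col].to_numpy(float)
        if vals.size < 2:
            continue
        mu, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        if sd == 0.0:
            continue
        extreme = eligible & (np.abs(out[col] - mu) >= n_sd * sd)
        out.loc[extreme, "excluded"] = ExclusionReason.EXTREME_SLOPE.value
    return out
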