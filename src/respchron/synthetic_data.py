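"""Synthetic multiparty conversations with ground-truth breathing structure.

The generator emits, for a configurable number of speakers, (i) talkspurt
and laughter interval tables, (ii) per-speaker lung-volume traces built
from piecewise-linear breathing cycles with raised-cosine corner smoothing
and additive Gaussian noise, and (iii) the complete ground truth: planted
cycle landmarks, hold intervals, event labels (WSS/BSS/BSO with +/-INH,
TT(S)/TT(O)) and backchannel flags.  Every analysis stage can therefore be
scored against known structure without corpus data.

The default parameters emulate casual three-party conversation as the
analysis assumes it: ~20-minute conversations; quiet breathing far more
symmetric in its inhalation:exhalation ratio than speech breathing; speech
exhalations spanning whole talkspurts after a short pre-speech lag;
turn-holding (within-speaker) inhalations shorter and steeper than
turn-initial ones; occasional continuations on the same exhalation (-INH),
including pause interruptions in which the previous speaker waits out an
interjection, often with a breath hold; and holds in silent exhalations
concentrated near the bottom of the exhalation with a smaller cluster near
the top (abandoned turn initiations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chronography as chron
from .signal_core import BreathCycle, CalibrationState, RIPTrace


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the conversation simulator.

    Durations are seconds, levels are raw trace units (speech inhalations
    peak near 1.0 above the resting level at 0), probabilities are per
    opportunity.  ``noise_sd`` is the additive noise SD as a fraction of
    the speech breathing amplitude.  Two-tuples are (mean, SD) for normal
    draws or (low, high) for the ``*_range``/gap/overlap uniform draws.
    """

    n_speakers: int = 3
    duration_s: float = 1200.0
    sample_rate_hz: float = 100.0
    seed: int = 0

    # quiet breathing
    quiet_inh_s: tuple[float, float] = (1.1, 0.15)
    quiet_exh_s: tuple[float, float] = (2.9, 0.35)
    quiet_amp: tuple[float, float] = (0.6, 0.06)

    # speech breathing
    speech_inh_s: tuple[float, float] = (1.2, 0.18)   # turn-initial
    wss_inh_s: tuple[float, float] = (0.5, 0.08)      # turn-holding (+INH)
    speech_peak: tuple[float, float] = (0.9, 0.12)
    speech_lag_s: tuple[float, float] = (0.35, 0.05)  # inh offset -> speech
    wss_lag_s: tuple[float, float] = (0.2, 0.03)
    exh_tail_s: float = 0.3
    minus_end_level: tuple[float, float] = (0.3, 0.05)
    plus_end_level: tuple[float, float] = (0.05, 0.03)

    # talkspurts and turns
    talkspurt_log_s: tuple[float, float] = (np.log(1.8), 0.5)
    talkspurt_range_s: tuple[float, float] = (1.05, 6.0)
    spurt_continue_prob: float = 0.6
    max_spurts_per_turn: int = 5
    minus_inh_prob: float = 0.7
    max_spurts_per_exhalation: int = 3
    plus_gap_s: tuple[float, float] = (1.9, 2.8)      # uniform range
    minus_gap_s: tuple[float, float] = (0.3, 0.6)

    # transitions
    pause_log_s: tuple[float, float] = (np.log(0.5), 0.5)
    pause_range_s: tuple[float, float] = (0.25, 2.0)
    overlap_prob: float = 0.3
    overlap_s: tuple[float, float] = (0.15, 0.6)
    transition_matrix: np.ndarray | None = None       # rows: from, cols: to
    pause_interruption_prob: float = 0.08
    interruption_overlap_prob: float = 0.5
    hold_during_interruption_prob: float = 0.15
    backchannel_prob: float = 0.12
    backchannel_s: tuple[float, float] = (0.3, 0.9)

    # breath holds
    hold_prob: float = 0.12          # per silent quiet exhalation
    hold_given_change: float = 0.06  # post-speech tail hold at turn release
    wss_hold_prob: float = 0.015     # tail hold before a held-turn pause
    top_hold_frac: float = 0.25
    hold_duration_s: tuple[float, float] = (0.3, 0.7)
    top_hold_amp: tuple[float, float] = (0.03, 0.15)
    bottom_hold_amp: tuple[float, float] = (0.85, 0.97)

    # trace synthesis
    noise_sd: float = 0.02
    noise_corr_s: float = 0.0    # 0 = white; >0 band-limits sensor noise
    smooth_s: float = 0.06
    drift_amp: float = 0.08
    drift_period_s: float = 300.0
    laughter_prob: float = 0.03

    def validate(self) -> None:
        for name in ("overlap_prob", "backchannel_prob", "hold_prob",
                     "minus_inh_prob", "pause_interruption_prob",
                     "top_hold_frac", "laughter_prob", "wss_hold_prob",
                     "hold_during_interruption_prob", "spurt_continue_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_speakers < 2:
            raise ConfigError("need at least 2 speakers")
        if self.duration_s <= 30:
            raise ConfigError("duration_s too short for a conversation")
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, float)
            if tm.shape != (self.n_speakers, self.n_speakers):
                raise ConfigError("transition matrix shape mismatch")
            if not np.allclose(tm.sum(axis=1), 1.0):
                raise ConfigError("transition matrix rows must sum to 1")
        if self.talkspurt_range_s[0] <= self.wss_lag_s[0]:
            raise ConfigError("talkspurts shorter than the speech lag")
        if self.minus_gap_s[0] < 0.25:
            raise ConfigError(
                "within-exhalation gaps under 250 ms would merge talkspurts")


@dataclass
class GroundTruth:
    """Planted structure of one simulated conversation.

    ``cycles``: speaker, t_onset/t_peak/t_offset, v_* (raw units), silent.
    ``holds``: speaker, t_start, t_end, level, position
    ('top'/'bottom'/'interruption'/'tail'), silent.
    ``talkspurts``: speaker, t_start, t_end, backchannel, laughter.
    ``events``: base, inh, prev/next speaker, interval bounds (labels
    derived from the planted talkspurts and cycle landmarks, so they are
    consistent with the emitted traces by construction).
    ``tt_labels``: kind, speaker, talkspurt onset.
    """

    cycles: pd.DataFrame
    holds: pd.DataFrame
    talkspurts: pd.DataFrame
    laughter: pd.DataFrame
    events: pd.DataFrame
    tt_labels: pd.DataFrame
    config: SimConfig


@dataclass
class _Spurt:
    speaker: int
    t_start: float
    t_end: float
    backchannel: bool = False


@dataclass
class _Group:
    """One exhalation group: consecutive talkspurts on a single exhalation."""

    spurts: list[_Spurt]
    turn_initial: bool
    interruption_spans: list[tuple[float, float]] = field(default_factory=list)
    hold_in_gap: bool = False
    tail_hold_dur: float | None = None   # plateau planted in the final tail
    emitted: bool = True


def _truncated_lognormal(rng, mu_sigma, lo_hi) -> float:
    mu, sigma = mu_sigma
    lo, hi = lo_hi
    return float(np.clip(rng.lognormal(mu, sigma), lo, hi))


def _pos_normal(rng, mean_sd, minimum=0.05) -> float:
    m, s = mean_sd
    return float(max(minimum, rng.normal(m, s)))


def _build_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Draw the talkspurt schedule and exhalation-group structure."""
    if cfg.transition_matrix is None:
        tm = np.full((cfg.n_speakers, cfg.n_speakers),
                     1.0 / (cfg.n_speakers - 1))
        np.fill_diagonal(tm, 0.0)
    else:
        tm = np.asarray(cfg.transition_matrix, float)

    groups: dict[int, list[_Group]] = {s: [] for s in range(cfg.n_speakers)}
    speaker = int(rng.integers(cfg.n_speakers))
    t = 8.0  # leave room for initial quiet breathing
    margin = 12.0
    pending: tuple[int, _Group] | None = None

    while t < cfg.duration_s - margin:
        if pending is not None:
            speaker, group = pending
            pending = None
            continuing = True
        else:
            group = None
            continuing = False

        n_spurts = 1
        while (n_spurts < cfg.max_spurts_per_turn
               and rng.random() < cfg.spurt_continue_prob):
            n_spurts += 1

        for k in range(n_spurts):
            dur = _truncated_lognormal(rng, cfg.talkspurt_log_s,
                                       cfg.talkspurt_range_s)
            sp = _Spurt(speaker=speaker, t_start=t, t_end=t + dur)
            if continuing:
                group.spurts.append(sp)
            else:
                group = _Group(spurts=[sp], turn_initial=(k == 0))
                groups[speaker].append(group)
            continuing = False
            t = sp.t_end
            if k < n_spurts - 1:
                if (rng.random() < cfg.minus_inh_prob
                        and len(group.spurts) < cfg.max_spurts_per_exhalation):
                    gap = float(rng.uniform(*cfg.minus_gap_s))
                    continuing = True          # same exhalation: WSS-INH
                else:
                    gap = float(rng.uniform(*cfg.plus_gap_s))  # WSS+INH
                    if rng.random() < cfg.wss_hold_prob:
                        group.tail_hold_dur = float(
                            rng.uniform(*cfg.hold_duration_s))
                t += gap

        # transition target first; backchannels come from a third party so
        # the incoming speaker never overlaps their own backchannel
        nxt = int(rng.choice(cfg.n_speakers, p=tm[speaker]))
        if rng.random() < cfg.backchannel_prob:
            others = [s for s in range(cfg.n_speakers)
                      if s not in (speaker, nxt)]
            if others:
                bc_spk = int(rng.choice(others))
                bdur = float(rng.uniform(*cfg.backchannel_s))
                last = group.spurts[-1]
                b_on = last.t_start + 0.3
                if b_on + bdur < last.t_end - 0.2:
                    bc = _Spurt(speaker=bc_spk, t_start=b_on,
                                t_end=b_on + bdur, backchannel=True)
                    groups[bc_spk].append(
                        _Group(spurts=[bc], turn_initial=False))
        if rng.random() < cfg.overlap_prob:
            t_next_on = t - float(rng.uniform(*cfg.overlap_s))   # BSO
        else:
            t_next_on = t + _truncated_lognormal(
                rng, cfg.pause_log_s, cfg.pause_range_s)         # BSS

        if (rng.random() < cfg.pause_interruption_prob
                and t_next_on > group.spurts[-1].t_start + 0.5):
            # pause interruption: the current speaker waits out a short
            # interjection on the same exhalation and then continues
            if rng.random() < cfg.interruption_overlap_prob:
                t_next_on = t - float(rng.uniform(*cfg.overlap_s))
            inter_dur = _truncated_lognormal(
                rng, cfg.talkspurt_log_s, (1.05, 2.5))
            inter = _Spurt(speaker=nxt, t_start=t_next_on,
                           t_end=t_next_on + inter_dur)
            groups[nxt].append(_Group(spurts=[inter], turn_initial=True))
            return_gap = _truncated_lognormal(rng, cfg.pause_log_s,
                                              cfg.pause_range_s)
            t_resume = inter.t_end + return_gap
            group.interruption_spans.append((group.spurts[-1].t_end, t_resume))
            group.hold_in_gap = (
                rng.random() < cfg.hold_during_interruption_prob)
            pending = (speaker, group)
            t = t_resume
        else:
            if rng.random() < cfg.hold_given_change:
                group.tail_hold_dur = float(
                    rng.uniform(*cfg.hold_duration_s))
            speaker = nxt
            t = t_next_on
    return groups


def _plant_hold(rng, cfg, t_a, v_a, t_b, v_b, position):
    """Breakpoints for a plateau inside a descending segment, or None."""
    d = float(rng.uniform(*cfg.hold_duration_s))
    if t_b - t_a - d < 0.4:
        return None
    if position == "top":
        r = float(rng.uniform(*cfg.top_hold_amp))
    elif position == "bottom":
        r = float(rng.uniform(*cfg.bottom_hold_amp))
    else:
        r = float(rng.uniform(0.3, 0.6))
    v_h = v_a - r * (v_a - v_b)
    t_h = t_a + r * (t_b - t_a - d)
    # keep a little descent on both sides of the plateau
    t_h = float(np.clip(t_h, t_a + 0.1, t_b - d - 0.1))
    return [(t_h, v_h), (t_h + d, v_h)], (t_h, t_h + d, v_h)


class _TraceBuilder:
    """Accumulates breakpoints, landmarks and holds for one speaker."""

    def __init__(self) -> None:
        self.points: list[tuple[float, float]] = []
        self.landmarks: list[tuple[float, float, str]] = []  # t, v, kind
        self.holds: list[dict] = []

    def add_point(self, t: float, v: float) -> None:
        if self.points and t <= self.points[-1][0]:
            return
        self.points.append((t, v))

    def add_landmark(self, t: float, v: float, kind: str) -> None:
        if self.landmarks and self.landmarks[-1][2] == kind:
            # merge same-kind landmarks, keeping the more extreme one
            pt, pv, _ = self.landmarks[-1]
            better = v > pv if kind == "peak" else v < pv
            if better:
                self.landmarks[-1] = (t, v, kind)
            return
        self.landmarks.append((t, v, kind))


def _quiet_fill(builder, rng, cfg, t0, v0, t1, v1, drift) -> None:
    """Fill [t0, t1] with quiet breathing cycles from level v0 to v1.

    The caller guarantees the gap hosts at least one cycle.
    """
    gap = t1 - t0
    cycle_mean = cfg.quiet_inh_s[0] + cfg.quiet_exh_s[0]
    k = max(1, int(round(gap / cycle_mean)))
    bounds = np.linspace(t0, t1, k + 1)
    trough_vals = np.empty(k + 1)
    trough_vals[0], trough_vals[-1] = v0, v1
    for i in range(1, k):
        trough_vals[i] = drift(bounds[i])
    inh_frac = cfg.quiet_inh_s[0] / cycle_mean
    for i in range(k):
        ta, tb = float(bounds[i]), float(bounds[i + 1])
        va, vb = float(trough_vals[i]), float(trough_vals[i + 1])
        f = float(np.clip(rng.normal(inh_frac, 0.03), 0.15, 0.6))
        tp = ta + f * (tb - ta)
        vp = max(va, vb) + _pos_normal(rng, cfg.quiet_amp, 0.2)
        builder.add_landmark(ta, va, "trough")
        builder.add_landmark(tp, vp, "peak")
        builder.add_landmark(tb, vb, "trough")
        builder.add_point(tp, vp)
        if rng.random() < cfg.hold_prob:
            position = "top" if rng.random() < cfg.top_hold_frac else "bottom"
            planted = _plant_hold(rng, cfg, tp, vp, tb, vb, position)
            if planted is not None:
                pts, (h0, h1, lvl) = planted
                for p in pts:
                    builder.add_point(*p)
                builder.holds.append(dict(
                    t_start=h0, t_end=h1, level=lvl,
                    position=position, silent=True))
        builder.add_point(tb, vb)


def _emit_group(builder, rng, cfg, group: _Group,
                t_on: float, v_on: float, t_peak: float, t_exh_end: float):
    """Emit one speech group's inhalation + exhalation breakpoints.

    Returns the end-of-group trough level.
    """
    multi = len(group.spurts) > 1 or group.interruption_spans
    # deeper pre-speech inhalation before longer planned stretches
    peak = (_pos_normal(rng, cfg.speech_peak, 0.7)
            + 0.15 * (len(group.spurts) - 1))
    end_level = _pos_normal(
        rng, cfg.minus_end_level if multi else cfg.plus_end_level, 0.0)
    end_level = min(end_level, peak - 0.35)

    builder.add_point(t_on, v_on)
    builder.add_landmark(t_on, v_on, "trough")
    builder.add_point(t_peak, peak)
    builder.add_landmark(t_peak, peak, "peak")

    # exhalation: descend through the group's spurts and gaps
    segs: list[tuple[float, float, str]] = []   # (ta, tb, kind)
    cursor = t_peak
    inter = sorted(group.interruption_spans)
    for sp in group.spurts:
        if sp.t_start > cursor:
            in_interruption = any(
                a - 1e-9 <= cursor and sp.t_start <= b + 1e-9
                for a, b in inter)
            kind = ("hold_gap" if in_interruption and group.hold_in_gap
                    else "gap")
            segs.append((cursor, sp.t_start, kind))
        segs.append((sp.t_start, sp.t_end, "speech"))
        cursor = sp.t_end
    segs.append((cursor, t_exh_end, "tail"))

    # exhalation is braked during phonation; silent portions fall faster
    weights = {"speech": 1.0, "gap": 2.5, "tail": 2.5, "hold_gap": 0.0}
    total_w = sum((tb - ta) * weights[k] for ta, tb, k in segs) or 1.0
    level = peak
    drop = peak - end_level
    for ta, tb, kind in segs:
        nxt_level = level - drop * (tb - ta) * weights[kind] / total_w
        if kind == "hold_gap" and tb - ta >= 0.45:
            h0, h1 = ta + 0.05, tb - 0.05
            builder.add_point(h0, level)
            builder.add_point(h1, level)
            builder.holds.append(dict(
                t_start=h0, t_end=h1, level=level,
                position="interruption", silent=True))
            nxt_level = level
        elif (kind == "tail" and group.tail_hold_dur
                and tb - ta >= group.tail_hold_dur + 0.35):
            d = group.tail_hold_dur
            r = float(rng.uniform(0.25, 0.55))
            v_h = level - r * (level - nxt_level)
            t_h = float(np.clip(ta + r * (tb - ta - d),
                                ta + 0.1, tb - d - 0.1))
            builder.add_point(t_h, v_h)
            builder.add_point(t_h + d, v_h)
            builder.holds.append(dict(
                t_start=t_h, t_end=t_h + d, level=v_h,
                position="tail", silent=True))
        builder.add_point(tb, nxt_level)
        level = nxt_level
    builder.add_landmark(t_exh_end, level, "trough")
    return level


def _derive_truth_events(talkspurts_df, laughter_df, cycles_df):
    """Chronogram + INH labels on the planted talkspurts and landmarks."""
    spurts = [
        chron.Talkspurt(speaker_id=r.speaker, t_start=r.t_start,
                        t_end=r.t_end, contains_laughter=bool(r.laughter))
        for r in talkspurts_df.itertuples()
    ]
    cycles_by_speaker: dict[str, list[BreathCycle]] = {}
    for sid, sub in cycles_df.groupby("speaker"):
        cycles_by_speaker[sid] = [
            BreathCycle(t_onset=r.t_onset, t_peak=r.t_peak,
                        t_offset=r.t_offset, v_onset=r.v_onset,
                        v_peak=r.v_peak, v_offset=r.v_offset,
                        silent=bool(r.silent), index=i)
            for i, r in enumerate(sub.itertuples())
        ]
    events = chron.classify_intervals(spurts)
    events = [
        chron.augment_inh(ev, cycles_by_speaker.get(ev.prev_speaker, ()),
                          spurts)
        for ev in events
    ]
    rows = [
        dict(base=ev.base.value, inh=ev.inh.value,
             prev_speaker=ev.prev_speaker, next_speaker=ev.next_speaker,
             t_start=ev.t_start, t_end=ev.t_end,
             prev_offset=ev.prev_ts.t_end, next_onset=ev.next_ts.t_start,
             backchannel=ev.prev_ts.is_backchannel or ev.next_ts.is_backchannel)
        for ev in events
    ]
    events_df = pd.DataFrame(rows, columns=[
        "base", "inh", "prev_speaker", "next_speaker", "t_start", "t_end",
        "prev_offset", "next_onset", "backchannel"])
    tt_rows, seen = [], set()
    for r in rows:
        if r["base"] not in ("BSS", "BSO") or r["backchannel"]:
            continue
        key = (r["next_speaker"], r["next_onset"])
        if key in seen:
            continue
        seen.add(key)
        onset = r["next_onset"]
        overlapped = any(
            s.speaker_id != r["next_speaker"]
            and s.t_start <= onset < s.t_end
            for s in spurts
        )
        tt_rows.append(dict(kind="TT(O)" if overlapped else "TT(S)",
                            speaker=r["next_speaker"], t_onset=onset))
    tt_df = pd.DataFrame(tt_rows, columns=["kind", "speaker", "t_onset"])
    return events_df, tt_df


def simulate_conversation(config: SimConfig | None = None,
                          seed: int | None = None):
    """Generate one conversation: traces, interval tables and ground truth.

    Returns ``(traces, talkspurts, laughter, truth)`` where ``traces`` maps
    speaker ids ('S0', 'S1', ...) to raw :class:`RIPTrace` objects, the
    interval tables are DataFrames (speaker, t_start, t_end[, label]) and
    ``truth`` is a :class:`GroundTruth`.  Deterministic given
    (config, seed): the same seed yields bit-identical output.
    """
    cfg = config or SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": int(seed)})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    groups = _build_schedule(cfg, rng)

    def drift(t):
        return cfg.drift_amp * np.sin(2 * np.pi * t / cfg.drift_period_s)

    traces: dict[str, RIPTrace] = {}
    cycle_rows: list[dict] = []
    hold_rows: list[dict] = []
    n = int(round(cfg.duration_s * cfg.sample_rate_hz)) + 1
    t_axis = np.arange(n) / cfg.sample_rate_hz
    min_fill_gap = 1.8   # shorter inter-group gaps extend the exhalation

    speaker_seeds = [int(rng.integers(2**31)) for _ in range(cfg.n_speakers)]
    for s in range(cfg.n_speakers):
        sid = f"S{s}"
        child = np.random.default_rng(speaker_seeds[s])
        my_groups = sorted(groups[s], key=lambda g: g.spurts[0].t_start)

        # pre-draw each group's inhalation geometry
        plan = []
        t_prev_end = 0.0
        for g in my_groups:
            if g.turn_initial:
                inh = _pos_normal(child, cfg.speech_inh_s, 0.3)
                lag = _pos_normal(child, cfg.speech_lag_s, 0.1)
            else:
                inh = _pos_normal(child, cfg.wss_inh_s, 0.2)
                lag = _pos_normal(child, cfg.wss_lag_s, 0.08)
            t_peak = g.spurts[0].t_start - lag
            t_on = t_peak - inh
            if t_on <= t_prev_end + 0.2:
                g.emitted = False
                continue
            plan.append((g, t_on, t_peak))
            t_prev_end = g.spurts[-1].t_end + cfg.exh_tail_s + (
                g.tail_hold_dur + 0.3 if g.tail_hold_dur else 0.0)

        builder = _TraceBuilder()
        # short descending lead-in so the first trough is a true extremum
        builder.add_point(0.0, 0.25)
        builder.add_point(0.6, 0.0)
        t_cursor, v_cursor = 0.6, 0.0
        for i, (g, t_on, t_peak) in enumerate(plan):
            gap = t_on - t_cursor
            if gap >= min_fill_gap:
                _quiet_fill(builder, child, cfg, t_cursor, v_cursor,
                            t_on, 0.0, drift)
                v_on = 0.0
            else:
                v_on = v_cursor   # exhalation extended to the next onset
            # exhalation end: the next own group onset when it is close,
            # otherwise the configured tail after the last talkspurt
            # (stretched to host a planted post-speech hold)
            tail = cfg.exh_tail_s
            if g.tail_hold_dur:
                tail += g.tail_hold_dur + 0.3
            t_tail = g.spurts[-1].t_end + tail
            if i + 1 < len(plan) and plan[i + 1][1] - t_tail < min_fill_gap:
                t_exh_end = plan[i + 1][1]
            else:
                t_exh_end = t_tail
            v_cursor = _emit_group(builder, child, cfg, g,
                                   t_on, v_on, t_peak, t_exh_end)
            t_cursor = t_exh_end
        # trailing quiet breathing, then a closing rise so the last trough
        # is a true extremum rather than the recording boundary
        if cfg.duration_s - 0.6 - t_cursor >= min_fill_gap:
            _quiet_fill(builder, child, cfg, t_cursor, v_cursor,
                        cfg.duration_s - 0.6, 0.0, drift)
        last_t, last_v = builder.points[-1]
        if last_t < cfg.duration_s:
            builder.add_point(cfg.duration_s, last_v + 0.25)

        pts = np.array(builder.points)
        x = np.interp(t_axis, pts[:, 0], pts[:, 1])
        w = int(round(cfg.smooth_s * cfg.sample_rate_hz))
        if w >= 3:
            win = np.hanning(w)
            win /= win.sum()
            x = np.convolve(np.pad(x, w, mode="edge"), win, "same")[w:-w]
        if cfg.noise_sd > 0:
            noise = child.standard_normal(x.size)
            wn = int(round(cfg.noise_corr_s * cfg.sample_rate_hz))
            if wn >= 3:
                kern = np.hanning(wn)
                kern /= np.sqrt(np.sum(kern**2))   # preserve the SD
                noise = np.convolve(noise, kern, "same")
            # noise_sd is relative to the quiet-breathing cycle amplitude,
            # the modal cycle type of the recording
            x = x + cfg.noise_sd * cfg.quiet_amp[0] * noise
        traces[sid] = RIPTrace(speaker_id=sid, samples=x,
                               sample_rate=cfg.sample_rate_hz,
                               calibration=CalibrationState.RAW)

        own = [(sp.t_start, sp.t_end)
               for g in my_groups if g.emitted for sp in g.spurts]
        lm = builder.landmarks
        for i in range(len(lm) - 2):
            (t0, v0, k0), (t1, v1, k1), (t2, v2, k2) = lm[i], lm[i + 1], lm[i + 2]
            if (k0, k1, k2) != ("trough", "peak", "trough"):
                continue
            silent = not any(a < t2 and b > t0 for a, b in own)
            cycle_rows.append(dict(
                speaker=sid, t_onset=t0, t_peak=t1, t_offset=t2,
                v_onset=v0, v_peak=v1, v_offset=v2, silent=silent))
        for h in builder.holds:
            hold_rows.append(dict(speaker=sid, **h))

    all_spurts = sorted(
        ((sp, g) for s in range(cfg.n_speakers)
         for g in groups[s] if g.emitted for sp in g.spurts),
        key=lambda t: t[0].t_start,
    )
    ts_rows, laugh_rows = [], []
    for sp, g in all_spurts:
        laughed = (not sp.backchannel) and (rng.random() < cfg.laughter_prob)
        ts_rows.append(dict(
            speaker=f"S{sp.speaker}", t_start=sp.t_start, t_end=sp.t_end,
            backchannel=sp.backchannel, laughter=laughed))
        if laughed:
            mid = 0.5 * (sp.t_start + sp.t_end)
            laugh_rows.append(dict(
                speaker=f"S{sp.speaker}", t_start=mid,
                t_end=min(sp.t_end, mid + 0.5)))

    talkspurts_df = pd.DataFrame(
        ts_rows, columns=["speaker", "t_start", "t_end", "backchannel",
                          "laughter"])
    laughter_df = pd.DataFrame(
        laugh_rows, columns=["speaker", "t_start", "t_end"])
    cycles_df = pd.DataFrame(
        cycle_rows, columns=["speaker", "t_onset", "t_peak", "t_offset",
                             "v_onset", "v_peak", "v_offset", "silent"])
    events_df, tt_df = _derive_truth_events(
        talkspurts_df, laughter_df, cycles_df)

    truth = GroundTruth(
        cycles=cycles_df,
        holds=pd.DataFrame(
            hold_rows, columns=["speaker", "t_start", "t_end", "level",
                                "position", "silent"]),
        talkspurts=talkspurts_df,
        laughter=laughter_df,
        events=events_df,
        tt_labels=tt_df,
        config=cfg,
    )
    talk_df = talkspurts_df[["speaker", "t_start", "t_end"]].assign(
        label="speech")
    return traces, talk_df, laughter_df.copy(), truth


def _interval_prf(
    truth: Sequence[tuple[float, float]],
    detected: Sequence[tuple[float, float]],
    min_overlap_frac: float = 0.5,
) -> tuple[float, float, float]:
    """Precision/recall/F1 with one-to-one greedy overlap matching."""
    truth = list(truth)
    detected = list(detected)
    if not truth and not detected:
        return 1.0, 1.0, 1.0
    used: set[int] = set()
    tp = 0
    for a, b in truth:
        best, best_ov = None, 0.0
        for j, (c, d) in enumerate(detected):
            if j in used:
                continue
            ov = max(0.0, min(b, d) - max(a, c))
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None and best_ov >= min_overlap_frac * (b - a):
            used.add(best)
            tp += 1
    precision = tp / len(detected) if detected else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def pipeline_recovery_report(
    truth: GroundTruth,
    cycles_by_speaker: Mapping[str, Sequence],
    holds_by_speaker: Mapping[str, Sequence] | None = None,
    events: Sequence | None = None,
    boundary_tol_s: float = 0.1,
    min_hold_s: float = 0.3,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Returns a flat dict of metrics: cycle-boundary recall at
    ``boundary_tol_s``, hold precision/recall/F1 restricted to planted
    plateaus of at least ``min_hold_s``, and the fraction of ground-truth
    events (matched by previous speaker and talkspurt offset) whose
    augmented label agrees with the detected classification.
    """
    report: dict[str, float] = {}

    tp = fn = n_det = 0
    for sid, cyc in cycles_by_speaker.items():
        tdf = truth.cycles[truth.cycles["speaker"] == sid]
        truth_bounds = np.unique(np.concatenate(
            [tdf["t_onset"], tdf["t_peak"], tdf["t_offset"]]))
        if len(cyc):
            det_bounds = np.unique(np.concatenate(
                [[c.t_onset, c.t_peak, c.t_offset] for c in cyc]))
        else:
            det_bounds = np.array([])
        n_det += det_bounds.size
        for tb in truth_bounds:
            if (det_bounds.size
                    and np.min(np.abs(det_bounds - tb)) <= boundary_tol_s):
                tp += 1
            else:
                fn += 1
    report["cycle_boundary_recall"] = tp / (tp + fn) if tp + fn else 1.0
    report["n_detected_boundaries"] = float(n_det)

    if holds_by_speaker is not None:
        tr_all, det_all = [], []
        for sid, holds in holds_by_speaker.items():
            hdf = truth.holds[
                (truth.holds["speaker"] == sid)
                & (truth.holds["t_end"] - truth.holds["t_start"] >= min_hold_s)
            ]
            p, r, f1 = _interval_prf(
                list(zip(hdf["t_start"], hdf["t_end"])),
                [(h.t_start, h.t_end) for h in holds],
            )
            tr_all.append((p, r, f1, len(hdf)))
        if tr_all:
            weights = np.array([w for *_, w in tr_all], float)
            weights = weights / weights.sum() if weights.sum() else None
            report["hold_precision"] = float(np.average(
                [p for p, *_ in tr_all], weights=weights))
            report["hold_recall"] = float(np.average(
                [r for _, r, *_ in tr_all], weights=weights))
            p, r = report["hold_precision"], report["hold_recall"]
            report["hold_f1"] = 2 * p * r / (p + r) if p + r else 0.0

    if events is not None:
        agree = total = 0
        det_index = [
            (e.prev_speaker, e.prev_ts.t_end, e.category) for e in events
        ]
        tdf = truth.events[truth.events["base"] != "WSO"]
        for row in tdf.itertuples():
            cands = [
                (abs(off - row.prev_offset), cat)
                for spk, off, cat in det_index
                if spk == row.prev_speaker and abs(off - row.prev_offset) < 0.3
            ]
            if not cands:
                continue
            total += 1
            _, cat = min(cands)
            truth_cat = (row.base if row.inh == "n/a"
                         else f"{row.base}{row.inh}")
            agree += cat == truth_cat
        report["event_label_agreement"] = agree / total if total else 1.0
        report["n_matched_events"] = float(total)
    return report


def simulate_multinomial(
    coefficients: np.ndarray,
    n: int,
    seed: int = 0,
    predictor_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw categorical outcomes from a known multinomial logit model.

    ``coefficients`` has shape (J-1, k+1): one row per non-reference level,
    columns = intercept followed by k predictor slopes.  Predictors are
    i.i.d. standard normal.  Returns a DataFrame with predictor columns and
    a ``category`` column whose reference level is ``'C0'``.
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, float))
    k = coefficients.shape[1] - 1
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    eta_alt = coefficients[:, 0][None, :]
    if k:
        eta_alt = eta_alt + X @ coefficients[:, 1:].T
    eta = np.column_stack([np.zeros(n), np.broadcast_to(eta_alt, (n, coefficients.shape[0]))])
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cats = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
    names = list(predictor_names) if predictor_names else [
        f"x{i}" for i in range(k)]
    df = pd.DataFrame(X, columns=names)
    df["category"] = [f"C{c}" for c in cats]
    return df
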