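"""End-to-end analysis pipeline tying the stages together.

segment -> holds -> chronogram -> features -> hidden events -> models.
The in-memory entry point is :func:`analyze_conversation`; the file-based
:func:`run_pipeline` adds per-stage TSV outputs, a JSON run manifest and a
log with exclusion counts per reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .chronography import (
    Talkspurt,
    TurnEvent,
    TTEvent,
    apply_exclusions,
    classify_intervals,
    augment_inh,
    merge_talkspurts,
    tt_events,
)
from .feature_extraction import feature_table, flag_extreme_slopes
from .hidden_events import (
    AbandonedCandidate,
    HoldConditionTable,
    abandoned_candidates,
    compare_silent_cycle_inhalations,
    speaker_change_given_hold,
)
from .hold_detector import BreathHold, detect_all_holds, filter_silent_holds
from .io import ConversationBundle, PipelineConfig, write_json, write_tsv
from .signal_core import (
    BreathCycle,
    Calibration,
    RIPTrace,
    calibrate,
    mark_silent_cycles,
    resample_trace,
    segment_cycles,
    smooth_trace,
    to_sv_units,
    zscore_trace,
)
from .stat_models import MODEL_FAMILIES, MultinomialFit, fit_family

logger = logging.getLogger("respchron")

STAGES = ["segment", "holds", "chronogram", "features", "hidden", "fit"]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineResult:
    """All per-stage outputs of one conversation."""

    config: PipelineConfig
    talkspurts: dict[str, list[Talkspurt]]
    cycles: dict[str, list[BreathCycle]]
    calibrations: dict[str, Calibration]
    sv_traces: dict[str, RIPTrace]
    holds: dict[str, list[BreathHold]]
    silent_holds: dict[str, list[BreathHold]]
    events: list[TurnEvent]
    tts: list[TTEvent]
    features: pd.DataFrame
    hold_condition: HoldConditionTable
    candidates: dict[str, list[AbandonedCandidate]]
    silent_cycle_table: pd.DataFrame
    fits: dict[str, MultinomialFit | None] = field(default_factory=dict)
    fit_errors: dict[str, str] = field(default_factory=dict)

    @property
    def all_talkspurts(self) -> list[Talkspurt]:
        return sorted(
            (ts for spurts in self.talkspurts.values() for ts in spurts),
            key=lambda s: s.t_start,
        )


def analyze_conversation(
    traces: Mapping[str, RIPTrace],
    speech: pd.DataFrame,
    laughter: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``speech``/``laughter`` are interval tables with columns speaker,
    t_start, t_end.  Every speaker with speech must have a trace.
    """
    cfg = config or PipelineConfig()
    laughter = laughter if laughter is not None else pd.DataFrame(
        columns=["speaker", "t_start", "t_end"])

    laughter_by_speaker = {
        sid: list(zip(sub["t_start"], sub["t_end"]))
        for sid, sub in laughter.groupby("speaker")
    }
    talkspurts: dict[str, list[Talkspurt]] = {}
    for sid in sorted(traces):
        sub = speech[speech["speaker"] == sid]
        talkspurts[sid] = merge_talkspurts(
            list(zip(sub["t_start"], sub["t_end"])), sid,
            min_pause_s=cfg.min_pause_s,
            laughter=laughter_by_speaker.get(sid, ()),
        )
    missing = set(speech["speaker"]) - set(traces)
    if missing:
        raise StageError("segment", f"no trace for speakers {sorted(missing)}")

    cycles: dict[str, list[BreathCycle]] = {}
    calibs: dict[str, Calibration] = {}
    sv_traces: dict[str, RIPTrace] = {}
    for sid, raw in traces.items():
        try:
            work = resample_trace(raw, cfg.working_rate_hz)
            z = zscore_trace(work)
            cyc = segment_cycles(smooth_trace(z, cfg.pre_smooth_s),
                                 min_sep=cfg.min_sep_sd)
            if len(cyc) < 2:
                raise ValueError(f"fewer than 2 breathing cycles for {sid}")
            calib = calibrate(cyc, window_s=cfg.rel_window_s,
                              mode=cfg.rel_window_mode,
                              lower_pct=cfg.sv_lower_pct,
                              upper_pct=cfg.sv_upper_pct)
            spans = [(t.t_start, t.t_end) for t in talkspurts.get(sid, ())]
            cycles[sid] = mark_silent_cycles(cyc, spans)
            calibs[sid] = calib
            sv_traces[sid] = to_sv_units(z, calib)
        except Exception as exc:
            raise StageError("segment", f"speaker {sid}: {exc}") from exc

    holds: dict[str, list[BreathHold]] = {}
    silent_holds: dict[str, list[BreathHold]] = {}
    for sid in traces:
        try:
            hs = detect_all_holds(
                smooth_trace(sv_traces[sid], cfg.hold_smooth_s), cycles[sid],
                min_hold_s=cfg.min_hold_s, min_gap_s=cfg.min_gap_s,
                margin_frac=cfg.margin_frac, n_bins=cfg.n_bins,
                prominence_ratio=cfg.prominence_ratio,
            )
            holds[sid] = hs
            silent_holds[sid] = filter_silent_holds(
                hs, [(t.t_start, t.t_end) for t in talkspurts.get(sid, ())],
                min_hold_s=cfg.min_hold_s)
        except Exception as exc:
            raise StageError("holds", f"speaker {sid}: {exc}") from exc

    all_spurts = sorted(
        (ts for spurts in talkspurts.values() for ts in spurts),
        key=lambda s: s.t_start,
    )
    try:
        events = classify_intervals(all_spurts)
        events = [
            augment_inh(ev, cycles.get(ev.prev_speaker, ()), all_spurts)
            for ev in events
        ]
        events = apply_exclusions(
            events, cycles, laughter_by_speaker,
            flag_missed_inhalations=cfg.flag_missed_inhalations,
            traces_by_speaker=sv_traces)
        tts = tt_events(events, cycles, all_spurts)
    except Exception as exc:
        raise StageError("chronogram", str(exc)) from exc

    try:
        feats = feature_table(
            events, tts, cycles, calibs,
            holds_by_speaker=silent_holds,
            min_duration_s=1.0 / cfg.working_rate_hz,
            slope_denominator=cfg.slope_denominator,
        )
        feats = flag_extreme_slopes(feats, n_sd=cfg.extreme_slope_sd)
    except Exception as exc:
        raise StageError("features", str(exc)) from exc

    try:
        hold_cond = speaker_change_given_hold(events, silent_holds, cycles)
        candidates = {
            sid: abandoned_candidates(cycles[sid], silent_holds[sid],
                                      calib=calibs[sid],
                                      top_frac=cfg.top_frac)
            for sid in traces
        }
        silent_tables = [
            compare_silent_cycle_inhalations(
                cycles[sid], candidates[sid], tts, calibs[sid],
                speaker_id=sid, min_duration_s=1.0 / cfg.working_rate_hz)
            for sid in sorted(traces)
        ]
        silent_table = pd.concat(silent_tables, ignore_index=True)
    except Exception as exc:
        raise StageError("hidden", str(exc)) from exc

    result = PipelineResult(
        config=cfg, talkspurts=talkspurts, cycles=cycles,
        calibrations=calibs, sv_traces=sv_traces, holds=holds,
        silent_holds=silent_holds, events=events, tts=tts, features=feats,
        hold_condition=hold_cond, candidates=candidates,
        silent_cycle_table=silent_table,
    )
    if cfg.fit_models:
        for family in MODEL_FAMILIES:
            table = (silent_table.rename(columns={"group": "category"})
                     if family == "silent_cycle" else feats)
            try:
                result.fits[family] = fit_family(
                    table, family, alpha=cfg.alpha)
            except Exception as exc:
                result.fits[family] = None
                result.fit_errors[family] = str(exc)
                logger.warning("model %s not fitted: %s", family, exc)
    return result


# -- tabular serialization ---------------------------------------------------

def cycles_frame(result: PipelineResult) -> pd.DataFrame:
    rows = [
        dict(speaker=sid, cycle_index=c.index, t_onset=c.t_onset,
             t_peak=c.t_peak, t_offset=c.t_offset, v_onset=c.v_onset,
             v_peak=c.v_peak, v_offset=c.v_offset, silent=c.silent)
        for sid, cyc in sorted(result.cycles.items()) for c in cyc
    ]
    return pd.DataFrame(rows)


def holds_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for sid, hs in sorted(result.silent_holds.items()):
        for h in hs:
            rows.append(dict(speaker=sid, cycle_index=h.cycle_index,
                             t_start=h.t_start, t_end=h.t_end,
                             level=h.level, during_silence=h.during_silence))
    return pd.DataFrame(rows, columns=["speaker", "cycle_index", "t_start",
                                       "t_end", "level", "during_silence"])


def chronogram_frame(result: PipelineResult) -> pd.DataFrame:
    rows = [
        dict(base=e.base.value, category=e.category,
             prev_speaker=e.prev_speaker, next_speaker=e.next_speaker,
             t_start=e.t_start, t_end=e.t_end,
             prev_offset=e.prev_ts.t_end, next_onset=e.next_ts.t_start,
             excluded=e.excluded.value if e.excluded else "")
        for e in result.events
    ]
    return pd.DataFrame(rows)


def run_pipeline(bundle: ConversationBundle, out_dir: str | Path) -> Path:
    """Run all stages on a bundle and write per-stage outputs.

    Writes cycles/holds/chronogram/features/silent-cycle TSVs, model
    coefficient TSVs, a JSON manifest (package version, config hash, stage
    list, exclusion counts) and a log file.  Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.time()
    try:
        traces, speech, laughter = bundle.load()
        logger.info("conversation %s: %d speakers, %d speech intervals",
                    bundle.conversation_id, len(traces), len(speech))
        result = analyze_conversation(traces, speech, laughter, bundle.config)

        write_tsv(out / "cycles.tsv", cycles_frame(result))
        write_tsv(out / "holds.tsv", holds_frame(result))
        write_tsv(out / "chronogram.tsv", chronogram_frame(result))
        feats = result.features.copy()
        feats.insert(0, "conversation_id", bundle.conversation_id)
        write_tsv(out / "features.tsv", feats)
        write_tsv(out / "silent_cycles.tsv", result.silent_cycle_table)

        hc = result.hold_condition
        write_json(out / "hold_condition.json", {
            "n_silence_with_hold": hc.n_silence_with_hold,
            "n_silence_without_hold": hc.n_silence_without_hold,
            "n_change_with_hold": hc.n_change_with_hold,
            "n_change_without_hold": hc.n_change_without_hold,
            "p_change_given_hold": hc.p_change_given_hold,
            "p_change_given_no_hold": hc.p_change_given_no_hold,
        })
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for family, fit in result.fits.items():
            if fit is None:
                continue
            df = fit.coefficients.copy()
            df.attrs = {}
            write_tsv(models_dir / f"{family}.tsv", df)

        excl_counts = (
            result.features["excluded"].replace("", "analyzed")
            .value_counts().to_dict()
        )
        for reason, count in sorted(excl_counts.items()):
            logger.info("events %s: %d", reason, count)
        config_hash = hashlib.sha256(
            json.dumps(bundle.config.__dict__, sort_keys=True).encode()
        ).hexdigest()[:16]
        write_json(out / "manifest.json", {
            "conversation_id": bundle.conversation_id,
            "package_version": __version__,
            "stages": STAGES,
            "config": bundle.config.__dict__,
            "config_hash": config_hash,
            "event_counts": excl_counts,
            "models_fitted": [k for k, v in result.fits.items()
                              if v is not None],
            "runtime_s": round(time.time() - t_start, 2),
        })
        logger.info("pipeline complete in %.1fs", time.time() - t_start)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
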