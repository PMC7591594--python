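"""Readers and writers for the pipeline's interchange formats.

Speech-activity and laughter annotations arrive as Praat TextGrid files
(long or short dialect) or as delimited tables; lung-volume traces as
single-channel WAV (sample rate from the header) or two-column delimited
text (time_s, value).  All tabular outputs are UTF-8 TSV with a header row
and times serialized as seconds with six decimals.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .signal_core import CalibrationState, RIPTrace


class TextGridParseError(ValueError):
    """Malformed TextGrid; carries the offending line number."""


# -- Praat TextGrid ---------------------------------------------------------

_QUOTED = re.compile(r'"((?:[^"]|"")*)"')
_NUMBER = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def _tokenize_textgrid(text: str) -> list[tuple[object, int]]:
    """Token stream of (value, line_number); values are str or float.

    Handles both dialects: the long format's ``key = value`` lines and the
    short format's bare values.  Flag lines (``<exists>``) are ignored.
    """
    tokens: list[tuple[object, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.endswith(":") or stripped.endswith("]:"):
            continue
        if "=" in stripped and not stripped.startswith('"'):
            stripped = stripped.split("=", 1)[1].strip()
        m = _QUOTED.match(stripped)
        if m:
            tokens.append((m.group(1).replace('""', '"'), lineno))
            continue
        m = _NUMBER.match(stripped)
        if m:
            tokens.append((float(m.group(0)), lineno))
    return tokens


class _TokenStream:
    def __init__(self, tokens: list[tuple[object, int]]):
        self._tokens = tokens
        self._pos = 0

    @property
    def line(self) -> int:
        if self._pos < len(self._tokens):
            return self._tokens[self._pos][1]
        return self._tokens[-1][1] if self._tokens else 0

    def next(self, kind: type) -> object:
        if self._pos >= len(self._tokens):
            raise TextGridParseError(
                f"unexpected end of file near line {self.line}")
        value, lineno = self._tokens[self._pos]
        if not isinstance(value, kind):
            raise TextGridParseError(
                f"expected {kind.__name__} at line {lineno}, got {value!r}")
        self._pos += 1
        return value


def read_textgrid(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a Praat TextGrid (long or short dialect).

    Returns a mapping from tier name to a DataFrame with columns
    ``t_start``, ``t_end``, ``label``; empty-label intervals are retained.
    Point tiers are skipped.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text.split("\n", 1)[0] and "ooTextFile" not in text:
        raise TextGridParseError("line 1: not an ooTextFile TextGrid")
    stream = _TokenStream(_tokenize_textgrid(text))
    try:
        stream.next(str)               # "ooTextFile"
        obj = stream.next(str)         # "TextGrid"
        if "TextGrid" not in obj:
            raise TextGridParseError(
                f"line {stream.line}: object class is {obj!r}, not TextGrid")
        stream.next(float)             # xmin
        stream.next(float)             # xmax
        n_tiers = int(stream.next(float))
        tiers: dict[str, pd.DataFrame] = {}
        for _ in range(n_tiers):
            tier_class = stream.next(str)
            name = stream.next(str)
            stream.next(float)         # tier xmin
            stream.next(float)         # tier xmax
            n_items = int(stream.next(float))
            rows = []
            if tier_class == "IntervalTier":
                for _ in range(n_items):
                    a = stream.next(float)
                    b = stream.next(float)
                    label = stream.next(str)
                    rows.append((a, b, label))
                tiers[name] = pd.DataFrame(
                    rows, columns=["t_start", "t_end", "label"])
            else:                      # point tier: time + mark, skipped
                for _ in range(n_items):
                    stream.next(float)
                    stream.next(str)
        return tiers
    except TextGridParseError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise TextGridParseError(f"line {stream.line}: {exc}") from exc


def write_textgrid(
    path: str | Path,
    tiers: Mapping[str, Iterable[tuple[float, float, str]]],
    xmin: float | None = None,
    xmax: float | None = None,
) -> None:
    """Write interval tiers as a long-format TextGrid.

    Gaps between supplied intervals are filled with empty-label intervals
    so every tier tiles ``[xmin, xmax]`` as Praat requires.
    """
    tier_data = {
        name: sorted((float(a), float(b), str(lab)) for a, b, lab in ivs)
        for name, ivs in tiers.items()
    }
    lo = min((iv[0] for ivs in tier_data.values() for iv in ivs), default=0.0)
    hi = max((iv[1] for ivs in tier_data.values() for iv in ivs), default=1.0)
    xmin = lo if xmin is None else xmin
    xmax = hi if xmax is None else xmax

    def fill(ivs):
        out, cursor = [], xmin
        for a, b, lab in ivs:
            if a > cursor:
                out.append((cursor, a, ""))
            out.append((a, b, lab))
            cursor = b
        if cursor < xmax:
            out.append((cursor, xmax, ""))
        return out

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tier_data)}",
        "item []:",
    ]
    for i, (name, ivs) in enumerate(tier_data.items(), start=1):
        filled = fill(ivs)
        lines += [
            f"    item [{i}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {xmin:.6f}",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(filled)}",
        ]
        for j, (a, b, lab) in enumerate(filled, start=1):
            lines += [
                f"        intervals [{j}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{lab.replace(chr(34), chr(34) * 2)}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def intervals_from_textgrid(
    tiers: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Flatten TextGrid tiers into (speaker, t_start, t_end, label) rows,
    keeping only non-empty labels (speech activity)."""
    rows = []
    for name, df in tiers.items():
        for r in df.itertuples():
            if str(r.label).strip():
                rows.append((name, r.t_start, r.t_end, r.label))
    return pd.DataFrame(rows, columns=["speaker", "t_start", "t_end", "label"])


# -- traces -----------------------------------------------------------------

def read_trace(path: str | Path, speaker_id: str | None = None) -> RIPTrace:
    """Read a lung-volume trace from WAV or two-column delimited text."""
    path = Path(path)
    sid = speaker_id or path.stem
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / np.iinfo(data.dtype).max
        return RIPTrace(speaker_id=sid, samples=data.astype(float),
                        sample_rate=float(rate))
    try:
        arr = np.loadtxt(path, delimiter=None, ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, delimiter=None, ndmin=2, skiprows=1)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s, value")
    t, x = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 0.01 * step:
        # non-uniform sampling: interpolate onto a uniform grid
        n = int(np.floor((t[-1] - t[0]) / step)) + 1
        tu = t[0] + np.arange(n) * step
        x = np.interp(tu, t, x)
        t = tu
    return RIPTrace(speaker_id=sid, samples=x, sample_rate=1.0 / step,
                    t0=float(t[0]))


def write_trace(path: str | Path, trace: RIPTrace) -> None:
    """Write a trace as float32 WAV or TSV, by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(trace.sample_rate)),
                      trace.samples.astype(np.float32))
    else:
        write_tsv(path, pd.DataFrame(
            {"time_s": trace.times, "value": trace.samples}))


# -- tables and config ------------------------------------------------------

def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    """TSV with header, UTF-8, floats at six decimals."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6f",
              encoding="utf-8")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, loadable from YAML."""

    working_rate_hz: float = 100.0
    pre_smooth_s: float = 0.2
    min_sep_sd: float = 1.0
    rel_window_s: float = 60.0
    rel_window_mode: str = "centred"
    sv_lower_pct: float = 5.0
    sv_upper_pct: float = 95.0
    hold_smooth_s: float = 0.25
    min_hold_s: float = 0.25
    min_gap_s: float = 0.15
    margin_frac: float = 0.025
    n_bins: int = 100
    prominence_ratio: float = 3.0
    min_pause_s: float = 0.2
    top_frac: float = 0.2
    slope_denominator: str = "duration"
    extreme_slope_sd: float = 3.0
    flag_missed_inhalations: bool = True
    alpha: float = 0.05
    fit_models: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.__dict__, sort_keys=False), encoding="utf-8")


@dataclass
class ConversationBundle:
    """Paths of one conversation's inputs with consistent speaker ids."""

    conversation_id: str
    trace_paths: dict[str, str]
    speech_path: str = ""
    laughter_path: str = ""
    language: str = ""
    config: PipelineConfig = dataclass_field(default_factory=PipelineConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConversationBundle":
        base = Path(path).parent
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = PipelineConfig(**data.get("config", {}))
        bundle = cls(
            conversation_id=data["conversation_id"],
            trace_paths={k: str(base / v)
                         for k, v in data["trace_paths"].items()},
            speech_path=str(base / data["speech_path"]),
            laughter_path=(str(base / data["laughter_path"])
                           if data.get("laughter_path") else ""),
            language=data.get("language", ""),
            config=cfg,
        )
        bundle.validate()
        return bundle

    def validate(self) -> None:
        missing = [p for p in [*self.trace_paths.values(), self.speech_path]
                   if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                f"bundle {self.conversation_id}: missing files {missing}")

    def load(self):
        """Read traces and annotation tables."""
        traces = {sid: read_trace(p, sid)
                  for sid, p in sorted(self.trace_paths.items())}
        speech = _read_intervals(self.speech_path)
        laughter = (_read_intervals(self.laughter_path)
                    if self.laughter_path else
                    pd.DataFrame(columns=["speaker", "t_start", "t_end",
                                          "label"]))
        extra = set(speech["speaker"]) - set(traces)
        if extra:
            raise ValueError(
                f"speakers {sorted(extra)} have annotations but no trace")
        return traces, speech, laughter


def _read_intervals(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".textgrid":
        return intervals_from_textgrid(read_textgrid(path))
    df = read_tsv(path)
    if "label" not in df.columns:
        df["label"] = "speech"
    return df[["speaker", "t_start", "t_end", "label"]]


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default),
                          encoding="utf-8")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
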