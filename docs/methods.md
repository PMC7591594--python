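# Methods

This note documents the models, numerical choices and known limitations of
`respchron`, module by module, including the design decisions taken where
the method left genuine freedom.

## Signal model and calibration

A RIP trace is a uniformly sampled lung-volume proxy in arbitrary units.
The pipeline resamples to a working rate (default 100 Hz), z-scores over
the whole conversation per speaker (no detrending beyond the dynamic
baseline below), and segments cycles as alternating troughs and peaks
separated by at least `min_sep_sd` (default 1.0) standard deviations.

*Extremum search.* All local extrema are found (first sample of a flat
run represents the run), then adjacent peak–trough pairs closer than
`min_sep` in value are pruned weakest-pair-first. Removing an adjacent
opposite-type pair preserves alternation, so the greedy rule is well
defined; a heap makes it O(n log n). Consecutive cycles share their
boundary trough.

*Pre-smoothing.* Extremum positions on noisy traces jitter by roughly
(noise SD)/(local slope). The trace is therefore low-passed with a
`pre_smooth_s` (default 0.2 s) Hann window **for segmentation only**; hold
detection and feature levels use their own copies (below). At 5% sensor
noise this keeps ≥ 95% of cycle boundaries within 100 ms of truth on
synthetic data.

*SV.* The 5th–95th percentile span of the pooled peak and trough values,
with linear interpolation between order statistics (configurable
percentile bounds). Invariant to cycle order by construction.

*REL.* The median trough value within a 60-s window. The window is
centred by default; a trailing mode is available (`rel_window_mode`)
because the original convention is not recoverable. REL is evaluated at
every trough and linearly interpolated between troughs (constant beyond
the ends); an empty window falls back to the global trough median with a
warning. Calibrated units: value → (value − REL(t)) / SV, so REL maps to
0 and one full speaking-volume span to 1.

## Breath-hold detection

Holds are plateaus. Per cycle, the detector histograms the signal values
(100 equal-width bins over the cycle's range), takes every local-maximum
bin whose count reaches `prominence_ratio` (default 3×) the median bin
count as a dwell level, and extracts maximal runs within
±`margin_frac`·(cycle amplitude) of that level (default ±2.5%). Runs
shorter than 250 ms are dropped; runs at one level closer than 150 ms are
merged; overlapping runs from different levels resolve to the longer.
Holds are assigned to the exhalation when at least half their duration
falls after the peak.

*Detection smoothing.* With noise at 2% of the cycle amplitude, the
samples of a 0.3–0.7-s plateau spread over ~8 histogram bins and cannot
reach the 3× prominence threshold; the detector therefore histograms a
copy of the trace smoothed with a `hold_smooth_s` (default 0.25 s — the
minimum hold duration; a plateau must survive smoothing at the hold
timescale) Hann window. On synthetic corpora this raises hold F1 from
~0.95 to ~0.98 at 2% noise without inflating false positives at cycle
corners, whose dwell stays below the 250-ms floor.

*Silent-exhalation restriction.* Slowly decaying speech segments mimic
plateaus, so only holds during silent exhalations are analysed. A hold
whose dwell band bleeds marginally into adjacent speech is trimmed to its
longest silent sub-span and kept if that still lasts the minimum duration;
strict any-overlap rejection silently discarded exactly the held-pause
interruptions of interest, whose plateaus end at the speaker's own speech
resumption.

## Chronography

Talkspurts merge same-speaker voice-activity intervals separated by less
than 200 ms; backchannels are talkspurts under 1 s. Events anchor at each
talkspurt offset, paired with the temporally next onset: a positive gap
gives WSS/BSS by speaker change; an onset inside the talkspurt gives BSO
when the incomer outlasts it and a WSO (chronogram-only) event when fully
embedded, in which case the scan continues; simultaneous onsets break
toward the longer incoming talkspurt. Time is in seconds with half-open
`[start, end)` intervals.

*±INH.* An event is +INH iff an inhalation onset (trough) of the previous
speaker falls strictly between the anchoring talkspurt's offset and that
speaker's next own talkspurt onset. An inhalation already in progress at
the talkspurt offset is an `edge_inhalation` exclusion, not +INH. Events
whose previous speaker never speaks again are n/a and excluded.

*TT events.* Each talkspurt effecting a speaker change yields one TT
event, classified by **global** silence at its onset — TT(O) iff any other
speaker's talkspurt spans the onset. In three-party talk this can differ
from the underlying event's base (the nearest-offset pairing can be a
silence while a third speaker still talks), and one incoming talkspurt can
close several between-speaker events; the global rule keeps one event per
turn-initial talkspurt.

*Exclusions* (flags, never row deletions): laughter overlapping the
interval or its bounding talkspurts (any positive intersection); a
backchannel bounding talkspurt; a speech edge inside an inhalation; and a
suspected missed inhalation. For the last, the default probe flags −INH
events whose anchoring exhalation *rises* by ≥ 20% of its amplitude —
direct evidence of a small inhalation the 1-SD segmentation merged away.
A duration heuristic (exhalation > 2× the speaker's median cycle duration)
is retained as a fallback when no trace is supplied, but it is a poor
proxy: it also fires on legitimately long held exhalations, i.e. precisely
the pause-interruption events the analysis is designed to surface.

## Features

Exhalatory features come from the previous speaker's exhalation spanning
the talkspurt offset: amplitude = onset level − offset level (SV),
duration in log₂ s, slope = −amplitude/duration (negative), levels as SV
fractions with dynamic REL at the landmark time. Inhalatory features are
analogous with positive slope; speech lag = speech onset − inhalation
onset (log₂ s), defined when the inhalation precedes the same speaker's
talkspurt. The slope denominator defaults to the inhalation duration —
a speech-lag denominator is available (`slope_denominator`) but is
undefined for between-speaker +INH intervals, where slopes must still be
reported. Durations are floored at one sample period before logs.
Hold co-occurrence for an event uses the window from its talkspurt offset
to the earlier of the exhalation offset and the speaker's next own
talkspurt onset, so holds on a shared multi-talkspurt exhalation count
once, for the event whose silence contains them. The 3-SD slope exclusion
pools all speakers, separately per slope type.

## Hidden events

Speaker-change probabilities condition on a hold in the (non-excluded)
WSS ∪ BSS silences' anchoring exhalations; the two conditional
probabilities and the marginal satisfy the law of total probability
exactly, by construction from shared counts. Abandoned-initiation
candidates are silent-cycle holds with relative amplitude position ≤ 0.2
(amplitude-based: fraction of the exhalation amplitude descended at the
hold level; the time position is descriptive only).

## Multinomial models

Fitting is maximum likelihood via Newton iterations (tolerance 1e-8, max
100 iterations; delegated to statsmodels MNLogit) with Wald 95% CIs
(B ± 1.96·SE) and Wald p-values. McFadden pseudo-R² = 1 − LL/LL₀ against
the intercept-only model. Forward stepwise selection adds candidates in
the stated order and keeps one iff 2·ΔLL exceeds the χ² critical value
with df = number of added coefficients. The collinearity screen is
declarative: within {duration, amplitude, slope} the slope is kept, within
{onset, offset level} the offset level — reproducibility over automatic
VIF pruning. Four model families are pre-registered: exhalatory (slope,
offset level, hold presence; reference WSS−INH), inhalatory over all
+INH/TT intervals (slope, offset level; reference WSS+INH), inhalatory
over WSS+INH/TT(S)/TT(O) with speech lag, and the silent-cycle model
(inhalation amplitude and duration over Silent/Hold/TT(S) groups).
Perfect separation and rank-deficient designs raise errors naming the
offending columns.

## The synthetic corpus

The generator emits the study conditions it is meant to emulate: 20-minute
three-party conversations; a semi-Markov turn process (uniform next-speaker
draw by default, configurable transition matrix) with 1–5 talkspurts per
turn; within-turn gaps continuing on the same exhalation (−INH, ~70% of
opportunities, at most 3 talkspurts per exhalation) or after a fresh
inhalation (+INH); between-turn transitions with 30% overlap; pause
interruptions (8% of transitions) in which the previous speaker waits out
a short interjection on a held exhalation and continues; backchannels
(< 1 s, 12% of turns, from a third party) and occasional laughter.
Breathing kinematics are piecewise linear with raised-cosine corner
smoothing: quiet breathing at ~15 cycles/min with a ~1:2.6
inhalation:exhalation asymmetry and amplitude ~0.6 of the speech
inhalation depth; speech inhalations are deeper and faster, deeper still
before longer planned stretches; turn-holding inhalations are shorter and
steeper with shorter speech lags; silent exhalation falls ~2.5× faster
than speech-braked exhalation. Holds are planted as exact plateaus then
noised: in quiet exhalations (12%, bimodal position — 25% near the top,
else near the bottom), in post-speech tails (6% at turn releases, 1.5%
before held-turn pauses), and during 15% of waited-out interruptions.
Traces begin with a short descending lead-in and end with a closing rise
so every planted trough is an interior extremum the detector can see.

Sensor noise is additive white Gaussian with SD expressed as a fraction
(default 2%) of the quiet-cycle amplitude — the modal cycle type and the
scale at which the hold-margin criterion operates; an optional correlation
time band-limits it. Ground-truth event labels are derived from the
planted talkspurts and cycle landmarks with the same classification rules
the pipeline applies to detected landmarks, so they are consistent with
the emitted traces by construction; what the recovery tests measure is
therefore landmark recovery from the noisy signal, while the
classification logic itself is validated against independent brute-force
oracles on random instances.

What the generator does **not** emulate: acoustic speech, belt slippage
and posture artifacts, isovolume miscalibration, drifting speech rates,
laughter breathing, or genuinely missed small inhalations. Passing
recovery tests on this corpus shows the pipeline recovers the structure it
assumes from clean RIP-like signals; it does not establish performance on
real recordings with VAD errors or motion artifacts.

## Known limitations

- The hold detector's margin criterion degrades when sensor noise exceeds
  ~2.5% of the host cycle's amplitude; detection smoothing compensates
  only partially.
- Three-way simultaneous starts resolve by a deterministic tie-break
  (earlier onset, then longer incoming talkspurt); other conventions are
  defensible.
- Dynamic REL at landmark times is assumed for level features; a
  per-conversation constant REL would shift levels slightly.
- The silent-cycle and turn-initial models separate more strongly on
  synthetic data than is typical of real recordings, where inhalation
  distributions overlap heavily across categories.
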