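# respchron

Respiratory chronography of multiparty conversation: a pipeline from raw
lung-volume traces and speech-activity annotations to breathing-cycle
segmentation, breath-hold detection, augmented turn-taking categories,
kinematic breathing features, hidden-event candidates, and multinomial
models of interval type.

## The problem

In casual conversation, who speaks next is negotiated partly through
breathing. A speaker who intends to keep the floor tends to inhale quickly
and shallowly between her own talkspurts — or not at all, continuing on the
same exhalation; a speaker releasing the turn exhales down to resting
expiratory level. Breath *holds* — plateaus in the lung-volume trace where
airflow is suspended — appear when a speaker waits out an interruption, or
when a listener gears up to speak and then abandons the attempt. None of
this is visible in a purely silence-based representation of interaction,
which is why such events are called *hidden events*.

`respchron` operationalizes this analysis for respiratory inductance
plethysmography (RIP) recordings:

1. **Signal calibration** (`signal_core`). Each speaker's trace is
   z-scored over the conversation and segmented into breathing cycles
   (trough → peak → trough) by locating alternating extrema separated by at
   least one standard deviation. Two per-speaker references are estimated:
   the **speaking volume** SV (the 5th–95th percentile span of all peak and
   trough values) and the dynamic **resting expiratory level** REL (median
   trough value in a sliding 60-s window). Levels and amplitudes are
   reported in SV units with REL at 0.
2. **Breath-hold detection** (`hold_detector`). Within each cycle, holds
   are plateaus: prominent modes of the value histogram where the signal
   dwells within a small margin for ≥ 250 ms (holds closer than 150 ms
   merge). Only holds in silent exhalations are kept, since slowly decaying
   speech segments mimic plateaus.
3. **Chronography** (`chronography`). Voice-activity intervals are merged
   into talkspurts (pauses < 200 ms bridged); every adjacent-talkspurt
   interval is classified by speaker change × overlap into WSS / WSO /
   BSS / BSO, then augmented by whether the previous speaker inhales before
   their next own talkspurt (±INH). Turn-initial talkspurts are classified
   from the incoming side as TT(S)/TT(O). Intervals bounded by backchannels
   (< 1 s), overlapping laughter, or whose speech edges fall inside an
   inhalation are flagged and excluded from feature analysis.
4. **Features** (`feature_extraction`). Post-speech exhalations yield
   amplitude (SV), duration (log₂ s), slope (SV/s), and onset/offset
   levels; linked inhalations yield duration, amplitude, slope, offset
   level and speech lag. Slopes more than 3 SD from the mean are excluded.
5. **Hidden events** (`hidden_events`). The probability of speaker change
   conditional on a hold in the previous speaker's post-speech exhalation,
   and abandoned-initiation candidates: silent cycles holding in the top
   20% of the exhalation amplitude.
6. **Models** (`stat_models`). Multinomial logistic regression of interval
   category on breathing features (reference: the unambiguously
   turn-holding WSS−INH), with forward stepwise selection by
   likelihood-ratio reduction of −2LL and McFadden's pseudo-R²
   (1 − LL/LL₀).

Because suitable corpora are not redistributable, `synthetic_data`
generates three-party conversations — talkspurt schedules, per-speaker RIP
traces and complete ground truth — with the statistical structure the
analysis assumes, so every stage is testable end to end.

## Worked example

```python
import respchron as rc

traces, speech, laughter, truth = rc.simulate_conversation(rc.SimConfig(), seed=42)
result = rc.analyze_conversation(traces, speech, laughter)

hc = result.hold_condition
print(f"P(speaker change | hold)    = {hc.p_change_given_hold:.2f}")
print(f"P(speaker change | no hold) = {hc.p_change_given_no_hold:.2f}")
fit = result.fits["exhalatory"]
print(f"exhalatory model: McFadden R2 = {fit.mcfadden_r2:.2f}")
```

prints

```
P(speaker change | hold)    = 0.86
P(speaker change | no hold) = 0.31
exhalatory model: McFadden R2 = 0.16
```

Holds in post-speech silences strongly predict an upcoming speaker change —
they are reactive (warding off incoming talk), not a turn-holding display.
A coefficient row of the exhalatory model (reference WSS−INH):

```
  level          predictor      b  exp_b  ci95_low  ci95_high    p
BSS+INH          Intercept  -2.27   0.10     -3.88      -0.66 0.01
BSS+INH exh_slope_sv_per_s -17.53   0.00    -24.26     -10.80 0.00
BSS+INH   exh_offset_level  -4.09   0.02     -8.02      -0.16 0.04
```

Higher (less negative) slopes and higher offset levels cut the odds of a
turn release with inhalation relative to the turn-holding reference: turn
releases end low and steep, continuations end high and shallow.

The same analyses run from the shell on file-based inputs (WAV or TSV
traces, Praat TextGrid or TSV annotations):

```sh
respchron simulate --seed 5 --out sim/
respchron run sim/bundle.yaml --out results/
```

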