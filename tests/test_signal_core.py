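import numpy as np
import pytest

from respchron.signal_core import (
    BreathCycle,
    CalibrationState,
    DegenerateSignalError,
    RIPTrace,
    calibrate,
    estimate_rel,
    estimate_sv,
    segment_cycles,
    to_sv_units,
    trough_track,
    zscore_trace,
)

from oracles import extrema_oracle, percentile_span_oracle, windowed_median_oracle


def make_trace(samples, rate=100.0, calibration=CalibrationState.RAW):
    return RIPTrace(speaker_id="S", samples=np.asarray(samples, float),
                    sample_rate=rate, calibration=calibration)


class TestZscore:
    def test_affine_standardization(self):
        z = zscore_trace(make_trace([0, 1, 2, 3, 4]))
        assert z.samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.samples.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert z.calibration is CalibrationState.ZSCORED

    def test_idempotent_on_standardized_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std(ddof=1)
        z = zscore_trace(make_trace(x))
        assert np.max(np.abs(z.samples - x)) < 1e-9

    def test_matches_two_pass_moment_oracle(self):
        rng = np.random.default_rng(1)
        x = 3.0 + 2.5 * rng.standard_normal(257)
        # independent summation oracle
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        z = zscore_trace(make_trace(x))
        assert np.allclose(z.samples, (x - mean) / sd, atol=1e-10)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            zscore_trace(make_trace(np.ones(10)))


class TestSegmentCycles:
    def test_sine_boundaries_at_analytic_extrema(self):
        rate = 100.0
        t = np.arange(0, 30, 1 / rate)
        x = 2.0 * np.sin(2 * np.pi * t / 4.0)   # amplitude 2 z-units, period 4
        cycles = segment_cycles(make_trace(x, calibration=CalibrationState.ZSCORED))
        assert cycles
        for c in cycles:
            # troughs at 3 + 4k s, peaks at 1 + 4k s
            assert (c.t_onset - 3.0) % 4.0 == pytest.approx(0, abs=1 / rate) \
                or (c.t_onset - 3.0) % 4.0 == pytest.approx(4.0, abs=1 / rate)
            assert (c.t_peak - 1.0) % 4.0 == pytest.approx(0, abs=1 / rate) \
                or (c.t_peak - 1.0) % 4.0 == pytest.approx(4.0, abs=1 / rate)

    def test_ripple_does_not_change_cycle_count(self):
        # count interior cycles only: edge extrema are phase-sensitive
        t = np.arange(0, 30, 0.01)
        base = 2.0 * np.sin(2 * np.pi * t / 4.0)
        ripple = 0.3 * np.sin(2 * np.pi * t * 3.1)

        def interior(x):
            cycles = segment_cycles(
                make_trace(x, calibration=CalibrationState.ZSCORED))
            return [c for c in cycles if 1.0 <= c.t_onset
                    and c.t_offset <= 29.0]

        clean, rippled = interior(base), interior(base + ripple)
        assert len(clean) == len(rippled)
        for a, b in zip(clean, rippled):
            assert a.t_peak == pytest.approx(b.t_peak, abs=0.2)

    def test_monotone_ramp_yields_no_cycles(self):
        x = np.linspace(0, 5, 200)
        assert segment_cycles(
            make_trace(x, calibration=CalibrationState.ZSCORED)) == []

    def test_alternation_and_separation_invariants(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.standard_normal(2000)) / 5
        cycles = segment_cycles(
            make_trace(x, calibration=CalibrationState.ZSCORED), min_sep=1.0)
        for c in cycles:
            assert c.t_onset < c.t_peak < c.t_offset
            assert c.v_peak - c.v_onset >= 1.0
            assert c.v_peak - c.v_offset >= 1.0
        for a, b in zip(cycles, cycles[1:]):
            assert a.t_offset <= b.t_onset

    def test_rejects_unscored_trace(self):
        with pytest.raises(ValueError):
            segment_cycles(make_trace([0, 1, 0, 1]))


def _random_cycles(rng, n):
    cycles = []
    t = 0.0
    for i in range(n):
        inh = rng.uniform(0.5, 2.0)
        exh = rng.uniform(1.0, 3.0)
        v0, v2 = rng.normal(0, 0.3, 2)
        vp = max(v0, v2) + rng.uniform(0.5, 2.0)
        cycles.append(BreathCycle(t_onset=t, t_peak=t + inh,
                                  t_offset=t + inh + exh,
                                  v_onset=v0, v_peak=vp, v_offset=v2,
                                  index=i))
        t += inh + exh
    return cycles


class TestCalibration:
    def test_two_point_span(self):
        cycles = [
            BreathCycle(0, 1, 2, 0.0, 1.0, 0.0, index=0),
            BreathCycle(2, 3, 4, 0.0, 1.0, 0.0, index=1),
        ]
        # pooled multiset is {0, 1} in equal proportion: p95 - p5 = 1
        assert estimate_sv(cycles) == pytest.approx(1.0)

    def test_linear_interpolation_percentiles(self):
        # pooled landmark values 0..100, one each -> span 90
        vals = np.arange(101.0)
        cycles = []
        for i in range(0, 99, 3):
            cycles.append(BreathCycle(
                i, i + 1, i + 2,
                v_onset=vals[i], v_peak=vals[i + 1] + 200, v_offset=vals[i + 2],
                index=i))
        pooled = [v for c in cycles for v in (c.v_peak, c.v_onset, c.v_offset)]
        assert estimate_sv(cycles) == pytest.approx(
            percentile_span_oracle(pooled))

    def test_sv_invariant_under_cycle_permutation(self):
        rng = np.random.default_rng(3)
        cycles = _random_cycles(rng, 30)
        shuffled = list(cycles)
        rng.shuffle(shuffled)
        assert estimate_sv(cycles) == pytest.approx(estimate_sv(shuffled))

    def test_degenerate_pooled_values(self):
        cycles = [BreathCycle(0, 1, 2, 0, 1, 0, index=0),
                  BreathCycle(2, 3, 4, 0, 1, 0, index=1)]
        with pytest.raises(DegenerateSignalError):
            estimate_sv(cycles, lower_pct=40, upper_pct=60)

    def test_rel_median_of_one_and_three(self):
        c = [BreathCycle(9.5, 10.5, 12.0, 0.2, 1.5, 0.2, index=0)]
        assert estimate_rel(c, 10.0) == pytest.approx(0.2)
        # consecutive cycles share the boundary trough at t=2
        c3 = [BreathCycle(0, 1, 2, 0.1, 2, 0.2, index=0),
              BreathCycle(2, 3, 4, 0.2, 2, 0.9, index=1)]
        # unique trough values within the window: 0.1, 0.2, 0.9 -> median 0.2
        assert estimate_rel(c3, 3.0, window_s=60) == pytest.approx(0.2)

    def test_rel_matches_windowed_median_oracle_on_drift(self):
        rng = np.random.default_rng(4)
        cycles = []
        t = 0.0
        for i in range(80):
            v = 0.002 * t + rng.normal(0, 0.05)
            cycles.append(BreathCycle(t, t + 1.0, t + 3.0,
                                      v_onset=v, v_peak=v + 1.0,
                                      v_offset=v + rng.normal(0, 0.02),
                                      index=i))
            t += 3.0
        times, values = trough_track(cycles)
        for tq in np.linspace(5, 230, 40):
            expected = windowed_median_oracle(times, values, tq, 60.0)
            assert estimate_rel(cycles, tq, 60.0) == pytest.approx(expected)

    def test_rel_empty_window_falls_back_with_warning(self):
        c = [BreathCycle(0, 1, 2, 0.3, 1.5, 0.5, index=0)]
        with pytest.warns(UserWarning):
            rel = estimate_rel(c, 500.0, window_s=60)
        assert rel == pytest.approx(0.4)   # global trough median

    def test_trailing_window_mode(self):
        c = [BreathCycle(0, 1, 2, 0.0, 1, 0.0, index=0),
             BreathCycle(50, 51, 52, 0.8, 2, 0.8, index=1)]
        # trailing [t-60, t] at t=55 sees all; centred at t=100 only late
        assert estimate_rel(c, 55.0, 60, mode="trailing") == pytest.approx(0.4)
        assert estimate_rel(c, 80.0, 60, mode="centred") == pytest.approx(0.8)


class TestToSvUnits:
    def test_rel_maps_to_zero_and_one_sv_to_one(self):
        rng = np.random.default_rng(5)
        cycles = _random_cycles(rng, 40)
        calib = calibrate(cycles)
        t = np.array([cycles[10].t_onset])
        rel = calib.rel_at(t)[0]
        assert calib.to_sv(t[0], rel) == pytest.approx(0.0)
        assert calib.to_sv(t[0], rel + calib.sv) == pytest.approx(1.0)

    def test_piecewise_linear_affine_map(self, identity_calib):
        x = np.array([0.0, 0.5, 1.0, 0.25])
        tr = make_trace(x, rate=1.0, calibration=CalibrationState.ZSCORED)
        out = to_sv_units(tr, identity_calib)
        assert np.allclose(out.samples, x)   # REL 0, SV 1: identity
        calib2 = type(identity_calib)(sv=2.0, rel_times=np.array([0.0]),
                                      rel_values=np.array([0.5]))
        out2 = to_sv_units(tr, calib2)
        assert np.allclose(out2.samples, (x - 0.5) / 2.0)
        assert out2.calibration is CalibrationState.SV_UNITS

    def test_monotone_in_value(self, identity_calib):
        assert identity_calib.to_sv(0.0, 0.3) < identity_calib.to_sv(0.0, 0.7)


class TestOracleEquivalence:
    def test_segmentation_agrees_with_pruning_oracle(self):
        """Heap-pruned landmark search equals the exhaustive scan oracle on
        many random walks."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(50, 400))
            x = np.cumsum(rng.standard_normal(n)) * rng.uniform(0.2, 1.5)
            min_sep = rng.uniform(0.5, 2.0)
            trace = make_trace(x, rate=10.0,
                               calibration=CalibrationState.ZSCORED)
            got = segment_cycles(trace, min_sep=min_sep)
            marks = extrema_oracle(x, min_sep)
            expected = []
            for k in range(len(marks) - 2):
                (i0, p0), (i1, p1), (i2, p2) = marks[k:k + 3]
                if (p0, p1, p2) == (False, True, False):
                    expected.append((i0, i1, i2))
            got_idx = [(round(c.t_onset * 10), round(c.t_peak * 10),
                        round(c.t_offset * 10)) for c in got]
            assert got_idx == expected


class TestPlantedRecovery:
    def test_boundaries_recovered_at_five_percent_noise(self):
        """>= 95% of planted cycle boundaries found within 100 ms when the
        noise SD is 5% of the breathing amplitude."""
        import warnings

        import respchron as rc

        traces, speech, laughter, truth = rc.simulate_conversation(
            rc.SimConfig(duration_s=300, noise_sd=0.05), seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rc.analyze_conversation(
                traces, speech, laughter,
                rc.PipelineConfig(fit_models=False))
        rep = rc.pipeline_recovery_report(truth, res.cycles)
        assert rep["cycle_boundary_recall"] >= 0.95
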