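"""Synthetic-generator contracts: envelopes, planted spikes, thermal, deviation."""

import numpy as np
import pytest

from grindforce import (
    AXES,
    GeneratorConfig,
    GrindingCondition,
    PerAxis,
    builtin_conditions,
    detect_spikes,
    generate_deviation_trace,
    generate_force_trace,
    generate_thermal_trace,
)
from grindforce.errors import InfeasibleConditionError

from conftest import EXPECTED_COUNTS


class TestBuiltinConditions:
    def test_exactly_six_presets(self):
        assert [c.series_id for c in builtin_conditions()] == [
            "1d", "1w", "2d", "2w", "3", "4",
        ]

    def test_series_1d_transcription(self, conditions):
        c = conditions["1d"]
        assert (c.base["x"], c.amplitude["x"]) == (-1.5, 1.5)
        assert c.spike_count["x"] == 23
        assert c.spike_peak_range["x"] == (-10.0, 5.0)
        assert c.atmosphere == "dry" and c.actuator == "manual"

    def test_wet_cortical_has_no_spikes(self, conditions):
        assert all(conditions["1w"].spike_count[a] == 0 for a in AXES)

    def test_cancellous_wet_single_y_spike(self, conditions):
        assert conditions["2w"].spike_count["y"] == 1

    def test_durations_and_feeds(self, conditions):
        for c in conditions.values():
            assert c.duration == 30.0
            assert c.feed_rate == 55.0


class TestForceGenerator:
    @pytest.mark.parametrize("series_id", sorted(EXPECTED_COUNTS))
    def test_spike_free_samples_respect_envelope(self, series_id, trace_cache, conditions):
        trace = trace_cache(series_id, 1)
        cond = conditions[series_id]
        planted = {a: {e.index for e in trace.annotations if e.axis == a} for a in AXES}
        for axis in AXES:
            f = trace.channel(axis)
            keep = np.ones(trace.n, bool)
            keep[list(planted[axis])] = False
            rest = f[keep]
            lo = cond.base[axis] - cond.amplitude[axis]
            hi = cond.base[axis] + cond.amplitude[axis]
            assert rest.min() >= lo - 1e-9 and rest.max() <= hi + 1e-9

    def test_spike_free_successive_differences_bounded(self, trace_cache):
        trace = trace_cache("3", 2)
        spikes = {e.index for e in trace.annotations}
        for axis in AXES:
            f = trace.channel(axis)
            for i in range(1, trace.n):
                if i in spikes or i - 1 in spikes:
                    continue
                assert abs(f[i] - f[i - 1]) < 2.0

    def test_planted_indices_separated_and_interior(self, trace_cache):
        # direct enumeration of the annotations of the 1d fixture
        trace = trace_cache("1d", 1)
        for axis in AXES:
            idx = sorted(e.index for e in trace.annotations if e.axis == axis)
            assert all(0 < i < trace.n - 1 for i in idx)
            assert all(b - a >= 50 for a, b in zip(idx, idx[1:]))

    def test_planted_peaks_within_declared_range(self, trace_cache, conditions):
        trace = trace_cache("4", 3)
        cond = conditions["4"]
        for e in trace.annotations:
            lo, hi = cond.spike_peak_range[e.axis]
            assert lo <= e.peak_force <= hi

    @pytest.mark.parametrize("series_id", sorted(EXPECTED_COUNTS))
    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_detector_recovers_planted_counts(self, series_id, seed, trace_cache):
        trace = trace_cache(series_id, seed)
        counts = {a: len(v) for a, v in detect_spikes(trace).items()}
        assert (counts["x"], counts["y"], counts["z"]) == EXPECTED_COUNTS[series_id]

    def test_zero_spike_condition_yields_none(self, trace_cache):
        events = detect_spikes(trace_cache("1w", 4))
        assert all(len(v) == 0 for v in events.values())

    def test_bit_identical_reproducibility(self, conditions):
        cfg = GeneratorConfig(seed=11)
        a = generate_force_trace(conditions["2d"], cfg)
        b = generate_force_trace(conditions["2d"], cfg)
        for ch in ("fx", "fy", "fz"):
            assert np.array_equal(getattr(a, ch), getattr(b, ch))
        c = generate_force_trace(conditions["2d"], GeneratorConfig(seed=12))
        assert not np.array_equal(a.fx, c.fx)

    def test_infeasible_peak_range_names_axis(self):
        cond = GrindingCondition(
            series_id="bad", tissue="cortical", atmosphere="dry",
            actuator="manual", travel="y-", duration=2.0,
            base=PerAxis(0.0, 0.0, 0.0), amplitude=PerAxis(1.0, 1.0, 1.0),
            spike_count=PerAxis(0, 3, 0),
            spike_peak_range=PerAxis((0, 0), (-2.0, 2.0), (0, 0)),
        )
        with pytest.raises(InfeasibleConditionError, match="axis y"):
            generate_force_trace(cond, GeneratorConfig(seed=1, sampling_rate=200.0))

    def test_generator_config_invariants(self):
        with pytest.raises(ValueError):
            GeneratorConfig(baseline_smoothness=6.0)
        with pytest.raises(ValueError):
            GeneratorConfig(min_spike_separation=2)


class TestThermalGenerator:
    def test_wet_peak_near_61(self, conditions):
        tt = generate_thermal_trace(conditions["1w"], GeneratorConfig(seed=1))
        assert tt.temp.max() == pytest.approx(61.0, abs=1.0)

    def test_dry_wet_peak_difference_over_100(self, conditions):
        cfg = GeneratorConfig(seed=1)
        dry = generate_thermal_trace(conditions["1d"], cfg)
        wet = generate_thermal_trace(conditions["1w"], cfg)
        assert dry.temp.max() - wet.temp.max() >= 100.0

    def test_starts_at_ambient_then_decays(self, conditions):
        cfg = GeneratorConfig(seed=1)
        tt = generate_thermal_trace(conditions["1d"], cfg)
        assert tt.temp[0] == pytest.approx(cfg.ambient_temp)
        after = tt.temp[tt.t > conditions["1d"].duration]
        assert np.all(np.diff(after) <= 1e-9)

    def test_peak_equal_ambient_gives_constant_trace(self, conditions):
        cfg = GeneratorConfig(seed=1, wet_peak=25.0, ambient_temp=25.0)
        tt = generate_thermal_trace(conditions["1w"], cfg)
        np.testing.assert_allclose(tt.temp, 25.0, atol=1e-12)


class TestDeviationGenerator:
    def test_depth_load_collapses_after_onset(self):
        tr = generate_deviation_trace(GeneratorConfig(seed=7, sampling_rate=200.0), onset=20.0)
        tail = np.abs(tr.fz[tr.t > 20.0])
        assert tail.mean() < 0.5 and tail.max() < 0.5
        assert tr.deviation_onset == 20.0

    def test_precursor_slope_positive_by_normal_equations(self):
        # closed-form least-squares slope over the 2 s window before onset
        tr = generate_deviation_trace(GeneratorConfig(seed=7, sampling_rate=200.0), onset=20.0)
        sel = (tr.t >= 18.0) & (tr.t < 20.0)
        tt, yy = tr.t[sel], tr.fz[sel]
        tbar, ybar = tt.mean(), yy.mean()
        slope = float(((tt - tbar) * (yy - ybar)).sum() / ((tt - tbar) ** 2).sum())
        assert slope > 0.0

    def test_onset_outside_record_is_error(self):
        with pytest.raises(ValueError):
            generate_deviation_trace(GeneratorConfig(seed=1), onset=31.0)
        with pytest.raises(ValueError):
            generate_deviation_trace(GeneratorConfig(seed=1), onset=0.0)
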