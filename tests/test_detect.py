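"""Spike-detector semantics, oracle equivalence, and rule properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grindforce import (
    DetectorConfig,
    count_spikes,
    detect_spikes,
    oracle_detect,
    qualifying_mask,
    spike_force_range,
)

from conftest import make_trace


class TestRuleSemantics:
    def test_isolated_excursion_is_one_spike(self):
        # hand enumeration: mean = 10/7 ~ 1.43; only index 3 passes all
        # three conditions (|10-1.43| = 8.57 >= 5, both neighbor diffs 10)
        tr = make_trace([0, 0, 0, 10, 0, 0, 0])
        events = detect_spikes(tr)
        assert [(e.index, e.peak_force) for e in events["x"]] == [(3, 10.0)]
        assert events["y"] == [] and events["z"] == []
        assert events["x"][0].excursion == pytest.approx(10 - 10 / 7)

    def test_plateau_below_mean_threshold_is_no_spike(self):
        # mean = 2; |6-2| = 4 < 5 fails the mean condition, and the plateau
        # fails the neighbor condition anyway
        tr = make_trace([0, 0, 6, 6, 0, 0])
        assert detect_spikes(tr) == {"x": [], "y": [], "z": []}

    def test_constant_trace_has_no_spikes(self):
        tr = make_trace([3.0] * 50)
        assert all(not v for v in detect_spikes(tr).values())

    def test_endpoints_never_qualify(self):
        tr = make_trace([30, 0, 0, 0, 30])
        for evs in detect_spikes(tr).values():
            assert all(0 < e.index < tr.n - 1 for e in evs)

    def test_adjacent_qualifiers_merge_to_extremal_sample(self):
        # indices 3 and 5 both qualify and sit within merge_gap -> one
        # event at the larger deviation
        tr = make_trace([0, 0, 0, 20, 0, 25, 0, 0, 0, 0, 0, 0])
        events = detect_spikes(tr)["x"]
        assert len(events) == 1
        assert events[0].index == 5

    def test_merge_gap_one_keeps_separate_events(self):
        tr = make_trace([0, 0, 0, 20, 0, 25, 0, 0, 0, 0, 0, 0])
        events = detect_spikes(tr, DetectorConfig(merge_gap=1))["x"]
        assert [e.index for e in events] == [3, 5]

    def test_running_mean_baseline_catches_drifting_signal(self):
        # a slow ramp hides a spike from the task mean but not from a
        # centered running mean
        n = 400
        ramp = np.linspace(-20, 20, n)
        ramp[300] += 12.0
        tr = make_trace(ramp, rate=100.0)
        run = detect_spikes(tr, DetectorConfig(baseline_mode="running_mean"))
        assert [e.index for e in run["x"]] == [300]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(make_trace([0, 1]))


class TestCountsAndRanges:
    def test_counts_are_list_lengths(self, trace_cache):
        events = detect_spikes(trace_cache("3", 1))
        counts = count_spikes(events)
        assert counts == {a: len(events[a]) for a in "xyz"}
        assert counts["x"] == 92

    def test_empty_events_count_zero(self):
        assert count_spikes({"x": [], "y": [], "z": []}) == {"x": 0, "y": 0, "z": 0}

    def test_single_event_range_collapses(self):
        tr = make_trace([0, 0, 0, 10, 0, 0, 0])
        rng = spike_force_range(detect_spikes(tr))
        assert rng["x"] == (10.0, 10.0)
        assert rng["y"] is None

    def test_counts_match_annotations(self, trace_cache):
        tr = trace_cache("4", 2)
        counts = count_spikes(detect_spikes(tr))
        planted = {a: sum(1 for e in tr.annotations if e.axis == a) for a in "xyz"}
        assert counts == planted


def _random_trace(rng, n):
    return make_trace(rng.uniform(-20, 20, n), rate=50.0,
                      values_y=rng.uniform(-20, 20, n),
                      values_z=rng.uniform(-20, 20, n))


class TestOracleEquivalence:
    @pytest.mark.parametrize("config", [
        DetectorConfig(),
        DetectorConfig(threshold=3.0, merge_gap=1),
        DetectorConfig(baseline_mode="running_mean", running_window=0.5),
    ])
    def test_matches_on_randomized_traces(self, config):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            tr = _random_trace(rng, int(rng.integers(3, 101)))
            fast = detect_spikes(tr, config)
            slow = oracle_detect(tr, config)
            for axis in "xyz":
                assert [e.index for e in fast[axis]] == slow[axis]

    @given(values=st.lists(st.floats(-30, 30, allow_nan=False), min_size=3, max_size=40))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_on_hypothesis_traces(self, values):
        tr = make_trace(values, rate=10.0)
        fast = detect_spikes(tr)
        slow = oracle_detect(tr)
        assert [e.index for e in fast["x"]] == slow["x"]

    def test_oracle_hand_enumeration(self):
        assert oracle_detect(make_trace([0, 0, 0, 10, 0, 0, 0]))["x"] == [3]
        assert oracle_detect(make_trace([2.0] * 10))["x"] == []


class TestRuleProperties:
    def test_threshold_monotonicity_of_qualifying_samples(self):
        # monotone for the raw rule; merged event counts need not be
        # (a lower threshold can bridge two groups into one event)
        rng = np.random.default_rng(7)
        for _ in range(20):
            tr = _random_trace(rng, 80)
            counts = [
                sum(int(m.sum()) for m in qualifying_mask(
                    tr, DetectorConfig(threshold=thr)).values())
                for thr in (1.0, 2.0, 3.0, 5.0, 8.0, 12.0)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_monotonicity_of_events_on_isolated_spikes(self, trace_cache):
        # with spikes >= 50 samples apart merging never bridges groups, so
        # event counts are monotone too
        tr = trace_cache("1d", 1)
        counts = [
            sum(len(v) for v in detect_spikes(tr, DetectorConfig(threshold=thr)).values())
            for thr in (5.0, 6.0, 8.0, 10.0, 14.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            DetectorConfig(threshold=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(merge_gap=0)
        with pytest.raises(ValueError):
            DetectorConfig(baseline_mode="median")
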