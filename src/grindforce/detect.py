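"""Threshold-rule spike detection on triaxial force traces.

A sample counts as a spike on an axis when its force deviates by at least
``threshold`` newtons (default 5 N) from that axis's baseline AND by at
least ``threshold`` from the sample immediately before AND the sample
immediately after. The baseline is either the whole-trial mean of the axis
(``task_mean``, the default — trials report one base value each) or a
centered running mean (``running_mean``). Endpoints can never qualify.

Qualifying samples closer than ``merge_gap`` samples are collapsed into a
single event at the sample of maximal deviation from baseline, so ringing
around one physical excursion is counted once.

:func:`oracle_detect` re-implements the same rule as naive per-sample
Python, sharing no code with :func:`detect_spikes`; it exists purely as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import AXES, ForceTrace, SpikeEvent


@dataclass(frozen=True)
class DetectorConfig:
    """Spike-detector parameters.

    threshold : N, minimum deviation from baseline and from both neighbors.
    baseline_mode : "task_mean" (whole-trial per-axis mean) or
        "running_mean" (centered moving average of ``running_window`` s).
    merge_gap : samples; qualifying samples at most this far apart collapse
        into one event.
    """

    threshold: float = 5.0
    baseline_mode: str = "task_mean"
    running_window: float = 1.0
    merge_gap: int = 3

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.baseline_mode not in ("task_mean", "running_mean"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.running_window <= 0:
            raise ValueError("running_window must be positive")
        if self.merge_gap < 1:
            raise ValueError("merge_gap must be >= 1")


def _baseline(values: np.ndarray, config: DetectorConfig, rate: float) -> np.ndarray:
    if config.baseline_mode == "task_mean":
        return np.full(values.shape, values.mean())
    # centered running mean, window shrinking at the edges
    n = len(values)
    half = max(1, int(round(config.running_window * rate))) // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def qualifying_mask(
    trace: ForceTrace, config: DetectorConfig | None = None
) -> dict[str, np.ndarray]:
    """Per-axis boolean mask of samples satisfying the raw spike rule.

    This is the statistic before event merging: endpoints are always
    False. Unlike merged event counts, the number of True samples is
    monotone non-increasing in the threshold.
    """
    config = config or DetectorConfig()
    if trace.n < 3:
        raise ValueError("spike detection needs at least 3 samples")
    out: dict[str, np.ndarray] = {}
    for axis in AXES:
        f = trace.channel(axis)
        b = _baseline(f, config, trace.sampling_rate)
        dev = np.abs(f - b)
        mask = np.zeros(trace.n, dtype=bool)
        mask[1:-1] = (
            (dev[1:-1] >= config.threshold)
            & (np.abs(f[1:-1] - f[:-2]) >= config.threshold)
            & (np.abs(f[1:-1] - f[2:]) >= config.threshold)
        )
        out[axis] = mask
    return out


def detect_spikes(
    trace: ForceTrace, config: DetectorConfig | None = None
) -> dict[str, list[SpikeEvent]]:
    """Detect spikes per axis; returns ``{"x": [...], "y": [...], "z": [...]}``.

    Events are sorted by time; ``peak_force`` is the signed force at the
    event sample and ``excursion`` its absolute deviation from the baseline.
    Raises ``ValueError`` on traces shorter than 3 samples.
    """
    config = config or DetectorConfig()
    masks = qualifying_mask(trace, config)
    out: dict[str, list[SpikeEvent]] = {}
    for axis in AXES:
        f = trace.channel(axis)
        b = _baseline(f, config, trace.sampling_rate)
        dev = np.abs(f - b)
        qual = np.flatnonzero(masks[axis])
        events: list[SpikeEvent] = []
        if qual.size:
            splits = np.flatnonzero(np.diff(qual) > config.merge_gap) + 1
            for group in np.split(qual, splits):
                k = int(group[np.argmax(dev[group])])
                events.append(
                    SpikeEvent(
                        axis=axis,
                        index=k,
                        time=float(trace.t[k]),
                        peak_force=float(f[k]),
                        excursion=float(dev[k]),
                    )
                )
        out[axis] = events
    return out


def count_spikes(events: dict[str, list[SpikeEvent]]) -> dict[str, int]:
    """Per-axis spike counts (length of each event list)."""
    return {axis: len(events.get(axis, [])) for axis in AXES}


def spike_force_range(
    events: dict[str, list[SpikeEvent]]
) -> dict[str, tuple[float, float] | None]:
    """Per-axis (min, max) signed peak force in newtons; None when empty."""
    out: dict[str, tuple[float, float] | None] = {}
    for axis in AXES:
        evs = events.get(axis, [])
        if not evs:
            out[axis] = None
        else:
            peaks = [e.peak_force for e in evs]
            out[axis] = (min(peaks), max(peaks))
    return out


def oracle_detect(
    trace: ForceTrace, config: DetectorConfig | None = None
) -> dict[str, list[int]]:
    """Naive per-sample re-evaluation of the spike rule; returns indices.

    Written independently of :func:`detect_spikes` (plain Python loops, no
    shared helpers) so the two can serve as cross-checks of each other.
    """
    config = config or DetectorConfig()
    if trace.n < 3:
        raise ValueError("spike detection needs at least 3 samples")
    thr = config.threshold
    result: dict[str, list[int]] = {}
    for axis in AXES:
        f = [float(v) for v in trace.channel(axis)]
        n = len(f)
        if config.baseline_mode == "task_mean":
            mean = sum(f) / n
            base = [mean] * n
        else:
            half = max(1, int(round(config.running_window * trace.sampling_rate))) // 2
            base = []
            for i in range(n):
                lo = i - half if i - half > 0 else 0
                hi = i + half + 1 if i + half + 1 < n else n
                base.append(sum(f[lo:hi]) / (hi - lo))
        qualifying = []
        for i in range(1, n - 1):
            if (
                abs(f[i] - base[i]) >= thr
                and abs(f[i] - f[i - 1]) >= thr
                and abs(f[i] - f[i + 1]) >= thr
            ):
                qualifying.append(i)
        merged: list[int] = []
        group: list[int] = []
        for i in qualifying:
            if group and i - group[-1] > config.merge_gap:
                merged.append(max(group, key=lambda j: (abs(f[j] - base[j]), -j)))
                group = []
            group.append(i)
        if group:
            merged.append(max(group, key=lambda j: (abs(f[j] - base[j]), -j)))
        result[axis] = merged
    return result
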