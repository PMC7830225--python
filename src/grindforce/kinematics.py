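"""Grinding kinematics (V = L/T) and thermal cooling-effect analysis.

The grinding speed of a trial is the measured grinding distance L (mm)
divided by the active grinding time T (s), where T is extracted from the
dynamometer record: the interval during which the resultant force
magnitude exceeds an onset threshold. The thermal side reduces a
temperature trace to its peak and quantifies the cooling effect of
irrigation as the difference between paired dry and wet peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoActiveSegmentError
from .traces import ForceTrace, ThermalTrace


@dataclass(frozen=True)
class KinematicsRecord:
    """Distance, active interval, and speed of one grinding measurement."""

    L: float          # grinding distance, mm
    t_start: float    # s
    t_end: float      # s
    T: float          # grinding time, s
    V: float          # speed, mm/s

    @property
    def mm_per_min(self) -> float:
        return 60.0 * self.V


@dataclass(frozen=True)
class ThermalSummary:
    peak_temp: float          # °C
    time_of_peak: float       # s
    cooling_effect: float | None = None  # °C, dry peak − wet peak when paired


def segment_active(
    trace: ForceTrace,
    onset_threshold: float = 0.5,
    min_hold: float = 0.2,
) -> tuple[float, float]:
    """Active grinding interval from the resultant force magnitude.

    ``t_start`` is the first time the magnitude exceeds ``onset_threshold``
    (N) and stays above it for at least ``min_hold`` seconds; ``t_end`` the
    last such time. Short blips below the hold time are ignored. Raises
    :class:`NoActiveSegmentError` when no qualifying run exists.
    """
    mag = trace.resultant()
    above = mag > onset_threshold
    hold = max(1, int(round(min_hold * trace.sampling_rate)))
    if not above.any():
        raise NoActiveSegmentError(
            f"no sample exceeds {onset_threshold} N resultant force")
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges, [len(above) - 1]))
    qualifying = [
        (s, e) for s, e in zip(starts, ends)
        if above[s] and (e - s + 1) >= hold
    ]
    if not qualifying:
        raise NoActiveSegmentError(
            f"no run above {onset_threshold} N lasts {min_hold} s")
    t_start = float(trace.t[qualifying[0][0]])
    t_end = float(trace.t[qualifying[-1][1]])
    return t_start, t_end


def compute_speed(L: float, T: float, t_start: float = 0.0) -> KinematicsRecord:
    """Speed of one measurement, V = L/T (mm/s). T must be positive."""
    if L < 0:
        raise ValueError("grinding distance L must be non-negative")
    if T <= 0:
        raise ValueError("grinding time T must be positive")
    return KinematicsRecord(L=L, t_start=t_start, t_end=t_start + T, T=T, V=L / T)


def kinematics_from_trace(
    trace: ForceTrace,
    L: float,
    onset_threshold: float = 0.5,
    min_hold: float = 0.2,
) -> KinematicsRecord:
    """Segment the active interval of a trace and compute V = L/T."""
    t_start, t_end = segment_active(trace, onset_threshold, min_hold)
    T = t_end - t_start
    if T <= 0:
        raise NoActiveSegmentError("active segment has zero duration")
    rec = compute_speed(L, T, t_start=t_start)
    return rec


def mean_speed(records: list[KinematicsRecord]) -> float:
    """Arithmetic mean speed over measurements, in mm/min."""
    if not records:
        raise ValueError("need at least one kinematics record")
    return 60.0 * float(np.mean([r.V for r in records]))


def thermal_summary(thermal: ThermalTrace) -> ThermalSummary:
    """Peak temperature and when it occurred."""
    k = int(np.argmax(thermal.temp))
    return ThermalSummary(peak_temp=float(thermal.temp[k]),
                          time_of_peak=float(thermal.t[k]))


def cooling_effect(dry: ThermalTrace, wet: ThermalTrace) -> float:
    """Peak-temperature difference (dry − wet) of a paired task, °C."""
    return thermal_summary(dry).peak_temp - thermal_summary(wet).peak_temp
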