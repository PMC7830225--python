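"""Tip-deviation detection and precursor scoring.

During manual grinding the rotating bur can slip off the bone surface;
the depth-axis load then collapses to zero almost instantly. The
observation motivating this module is that the collapse is preceded by a
rise of the depth-axis force — a usable early-warning sign for a safety
mechanism.

``detect_deviation`` finds the collapse: the earliest time after which the
depth-axis force magnitude stays below ``eps`` continuously through the
end of the record for at least ``hold`` seconds, with at least one second
of active grinding immediately before. ``precursor_score`` fits a
least-squares slope to the depth-axis force over a window before onset;
a slope above ``slope_threshold`` raises the warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .summary import AxisRoleMap
from .traces import ForceTrace


@dataclass
class DeviationEvent:
    """A detected depth-load collapse with optional precursor score."""

    onset: float                      # s
    precursor_slope: float | None = None  # N/s over the precursor window
    warning: bool | None = None       # slope above the warning threshold


def detect_deviation(
    trace: ForceTrace,
    roles: AxisRoleMap,
    eps: float = 0.5,
    hold: float = 1.0,
    activity_threshold: float = 1.0,
) -> DeviationEvent | None:
    """Find a tip-deviation event; ``None`` (a valid result) when absent.

    The onset is the start of the final run of |depth force| < ``eps``
    that extends to the end of the record, provided that run lasts at
    least ``hold`` seconds and the mean resultant force over the preceding
    second is at least ``activity_threshold`` (the tool must actually have
    been grinding before the collapse).
    """
    depth = trace.channel(roles.depth)
    below = np.abs(depth) < eps
    if not below[-1]:
        return None
    above_idx = np.flatnonzero(~below)
    start = int(above_idx[-1]) + 1 if above_idx.size else 0
    rate = trace.sampling_rate
    run_seconds = (trace.n - start) / rate
    if run_seconds < hold:
        return None
    onset = float(trace.t[start])
    if onset < 1.0:
        return None  # no full second of grinding before the collapse
    pre = slice(start - int(round(rate)), start)
    if float(trace.resultant()[pre].mean()) < activity_threshold:
        return None
    return DeviationEvent(onset=onset)


def precursor_score(
    trace: ForceTrace,
    event: DeviationEvent,
    roles: AxisRoleMap,
    window: float = 2.0,
    slope_threshold: float = 0.5,
) -> float:
    """Least-squares slope (N/s) of the depth-axis force before onset.

    Fits force against time over [onset − window, onset). Also fills
    ``event.precursor_slope`` and ``event.warning`` in place and returns
    the slope. Raises ``ValueError`` when the window would extend before
    the start of the record.
    """
    if event.onset - window < 0:
        raise ValueError("precursor window extends before the record start")
    rate = trace.sampling_rate
    k_on = int(round(event.onset * rate))
    k0 = int(round((event.onset - window) * rate))
    tt = trace.t[k0:k_on]
    yy = trace.channel(roles.depth)[k0:k_on]
    if len(tt) < 2:
        raise ValueError("precursor window holds fewer than 2 samples")
    slope = float(np.polyfit(tt, yy, 1)[0])
    event.precursor_slope = slope
    event.warning = slope > slope_threshold
    return slope
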