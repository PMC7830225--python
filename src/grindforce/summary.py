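"""Per-condition summaries: baseline estimation, axis roles, report tables.

The three dynamometer axes play different mechanical roles depending on
the tool's direction of travel. When the tool travels along y, the y force
reflects feed, x reflects torque, and z cutting depth; when it travels
along x the roles of x and y swap. ``estimate_baseline`` recovers the
spike-free force envelope (base ± amplitude) of a trial, and
``summarize``/``compare_conditions`` assemble the per-series report table
and the dry-versus-wet spike contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import DetectorConfig, count_spikes, detect_spikes, spike_force_range
from .errors import DegenerateTraceError
from .traces import AXES, ForceTrace, GrindingCondition, PerAxis, SpikeEvent


@dataclass(frozen=True)
class AxisRoleMap:
    """Which axis carries feed, torque, and cutting-depth force."""

    feed: str
    torque: str
    depth: str

    def __post_init__(self):
        if sorted((self.feed, self.torque, self.depth)) != sorted(AXES):
            raise ValueError("roles must be a permutation of x, y, z")

    def as_dict(self) -> dict[str, str]:
        return {"feed": self.feed, "torque": self.torque, "depth": self.depth}


@dataclass(frozen=True)
class GrindingSummary:
    """One report row: envelope, spike statistics, and axis roles."""

    series_id: str
    base: PerAxis                 # N, rounded to 0.1
    amplitude: PerAxis            # N, rounded to 0.1
    spike_count: PerAxis
    spike_range: PerAxis          # (lo, hi) signed N or None per axis
    roles: AxisRoleMap


def map_axis_roles(travel: str) -> AxisRoleMap:
    """Map a travel direction (axis + sign, e.g. ``"y-"``) to axis roles.

    The travel axis carries feed, the other horizontal axis torque, and z
    always depth. Vertical (z) travel is unsupported.
    """
    axis = travel[0]
    if axis == "z":
        raise ValueError("z travel is unsupported: depth axis cannot be feed")
    if axis not in ("x", "y") or travel[1:] not in ("+", "-"):
        raise ValueError(f"travel must be x/y plus sign, got {travel!r}")
    other = "y" if axis == "x" else "x"
    return AxisRoleMap(feed=axis, torque=other, depth="z")


def estimate_baseline(
    trace: ForceTrace,
    events: dict[str, list[SpikeEvent]],
    exclusion: int = 3,
) -> dict[str, tuple[float, float]]:
    """Spike-free force envelope per axis: (base, amplitude), 0.1 N.

    Spike samples and their ``exclusion`` neighbors on each side are
    dropped; base is the mean of the remaining samples and amplitude their
    maximum absolute deviation from it. Raises
    :class:`DegenerateTraceError` when nothing is left on some axis.
    """
    out: dict[str, tuple[float, float]] = {}
    n = trace.n
    for axis in AXES:
        keep = np.ones(n, dtype=bool)
        for e in events.get(axis, []):
            lo = max(0, e.index - exclusion)
            hi = min(n, e.index + exclusion + 1)
            keep[lo:hi] = False
        if not keep.any():
            raise DegenerateTraceError(f"axis {axis}: every sample is a spike")
        rest = trace.channel(axis)[keep]
        base = float(rest.mean())
        amp = float(np.max(np.abs(rest - base)))
        out[axis] = (round(base, 1), round(amp, 1))
    return out


def summarize(
    trace: ForceTrace,
    condition: GrindingCondition,
    config: DetectorConfig | None = None,
) -> GrindingSummary:
    """Full per-trial analysis: detect spikes, estimate the envelope, map roles."""
    config = config or DetectorConfig()
    events = detect_spikes(trace, config)
    counts = count_spikes(events)
    ranges = spike_force_range(events)
    env = estimate_baseline(trace, events, exclusion=config.merge_gap)
    return GrindingSummary(
        series_id=condition.series_id,
        base=PerAxis(*(env[a][0] for a in AXES)),
        amplitude=PerAxis(*(env[a][1] for a in AXES)),
        spike_count=PerAxis(*(counts[a] for a in AXES)),
        spike_range=PerAxis(*(ranges[a] for a in AXES)),
        roles=map_axis_roles(condition.travel),
    )


def _fmt_force(base: float, amp: float) -> str:
    return f"{base:.1f}±{amp:.1f}"


def _fmt_spikes(count: int, rng) -> str:
    if count == 0 or rng is None:
        return str(count)
    lo, hi = rng
    return f"{count} {lo:.1f}~{hi:.1f}"


def compare_conditions(summaries: list[GrindingSummary], fmt: str = "tsv") -> str:
    """Render a deterministic report table, one row per series.

    Columns mirror the per-series record layout (force envelope and spike
    frequency/force per axis, plus the axis-role mapping), followed by a
    dry-minus-wet spike-count section for series paired by prefix
    (``1d``/``1w``, ``2d``/``2w``). Same inputs give identical bytes.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    if fmt not in ("tsv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    header = (
        ["series"]
        + [f"force_{a}" for a in AXES]
        + [f"spikes_{a}" for a in AXES]
        + ["roles"]
    )
    rows = []
    for s in summaries:
        rows.append(
            [s.series_id]
            + [_fmt_force(s.base[a], s.amplitude[a]) for a in AXES]
            + [_fmt_spikes(s.spike_count[a], s.spike_range[a]) for a in AXES]
            + [f"feed={s.roles.feed},torque={s.roles.torque},depth={s.roles.depth}"]
        )
    by_id = {s.series_id: s for s in summaries}
    deltas = []
    for s in summaries:
        if s.series_id.endswith("d"):
            wet_id = s.series_id[:-1] + "w"
            if wet_id in by_id:
                w = by_id[wet_id]
                deltas.append(
                    [f"{s.series_id}-{wet_id}"]
                    + [str(s.spike_count[a] - w.spike_count[a]) for a in AXES]
                )
    lines = []
    if fmt == "tsv":
        lines.append("\t".join(header))
        lines.extend("\t".join(r) for r in rows)
        if deltas:
            lines.append("")
            lines.append("\t".join(["pair"] + [f"dspikes_{a}" for a in AXES]))
            lines.extend("\t".join(d) for d in deltas)
    else:
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join("---" for _ in header) + "|")
        lines.extend("| " + " | ".join(r) + " |" for r in rows)
        if deltas:
            lines.append("")
            dh = ["pair"] + [f"dspikes_{a}" for a in AXES]
            lines.append("| " + " | ".join(dh) + " |")
            lines.append("|" + "|".join("---" for _ in dh) + "|")
            lines.extend("| " + " | ".join(d) + " |" for d in deltas)
    return "\n".join(lines) + "\n"
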