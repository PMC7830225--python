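"""Domain types and file I/O for grinding-force and thermal traces.

The central containers are :class:`ForceTrace` (a uniformly sampled triaxial
force record, newtons) and :class:`ThermalTrace` (tool-tip temperature,
degrees Celsius), plus :class:`GrindingCondition`, the full parameterization
of one experimental series (tissue, atmosphere, actuator, travel direction,
force envelope, spike statistics).

Traces are exchanged as plain CSV: ``t,fx,fy,fz`` for force,
``t,temp`` for temperature, comma-separated, ``.`` decimal, full float
precision, so that a write/read round trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import TraceFormatError

AXES = ("x", "y", "z")

#: tolerance on the uniform time grid, seconds
GRID_TOL = 1e-9


@dataclass(frozen=True)
class PerAxis:
    """A value per force axis (x, y, z): floats, counts, or (lo, hi) pairs."""

    x: object
    y: object
    z: object

    def __getitem__(self, axis: str):
        if axis not in AXES:
            raise KeyError(f"unknown axis {axis!r}")
        return getattr(self, axis)

    def as_dict(self) -> dict:
        return {a: self[a] for a in AXES}

    @classmethod
    def of(cls, value) -> "PerAxis":
        """Coerce a PerAxis, mapping, 3-sequence, or scalar to a PerAxis."""
        if isinstance(value, cls):
            return value
        if isinstance(value, dict):
            return cls(value["x"], value["y"], value["z"])
        if isinstance(value, (list, tuple)) and len(value) == 3:
            return cls(*value)
        return cls(value, value, value)


@dataclass(frozen=True)
class SpikeEvent:
    """One sharp force excursion on one axis.

    A spike is a sample deviating at least 5 N from the trial's average on
    that axis and at least 5 N from both neighboring samples. ``peak_force``
    is signed; ``excursion`` is the absolute deviation from the baseline
    used by the detector.
    """

    axis: str
    index: int
    time: float
    peak_force: float
    excursion: float

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.excursion < 0:
            raise ValueError("excursion must be non-negative")


@dataclass(frozen=True)
class GrindingCondition:
    """Parameterization of one experimental grinding series.

    ``base`` and ``amplitude`` describe the spike-free force envelope
    (base ± amplitude, N) per axis; ``spike_count`` and ``spike_peak_range``
    give the number of planted sharp excursions per axis and the signed
    interval their peak forces are drawn from.
    """

    series_id: str
    tissue: str                  # cortical | cancellous | mixed
    atmosphere: str              # dry | wet
    actuator: str                # manual | machine
    travel: str                  # axis + sign, e.g. "y-" or "x+"
    duration: float              # seconds
    base: PerAxis                # N
    amplitude: PerAxis           # N, >= 0
    spike_count: PerAxis         # integer >= 0
    spike_peak_range: PerAxis    # (lo, hi) signed N
    feed_rate: float = 55.0      # mm/min
    cut_depth: float = 2.0       # mm
    tilt: float = 0.0            # degrees

    def __post_init__(self):
        object.__setattr__(self, "base", PerAxis.of(self.base))
        object.__setattr__(self, "amplitude", PerAxis.of(self.amplitude))
        object.__setattr__(self, "spike_count", PerAxis.of(self.spike_count))
        rng = PerAxis.of(self.spike_peak_range)
        rng = PerAxis(*(tuple(float(v) for v in rng[a]) for a in AXES))
        object.__setattr__(self, "spike_peak_range", rng)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.travel[0] not in AXES or self.travel[1:] not in ("+", "-"):
            raise ValueError(f"travel must be axis+sign, got {self.travel!r}")
        for a in AXES:
            if self.amplitude[a] < 0:
                raise ValueError(f"amplitude[{a}] must be >= 0")
            if self.spike_count[a] < 0:
                raise ValueError(f"spike_count[{a}] must be >= 0")
            lo, hi = self.spike_peak_range[a]
            if lo > hi:
                raise ValueError(f"spike_peak_range[{a}]: lo > hi")

    @property
    def travel_axis(self) -> str:
        return self.travel[0]

    def to_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "tissue": self.tissue,
            "atmosphere": self.atmosphere,
            "actuator": self.actuator,
            "travel": self.travel,
            "duration": self.duration,
            "base": self.base.as_dict(),
            "amplitude": self.amplitude.as_dict(),
            "spike_count": self.spike_count.as_dict(),
            "spike_peak_range": {a: list(self.spike_peak_range[a]) for a in AXES},
            "feed_rate": self.feed_rate,
            "cut_depth": self.cut_depth,
            "tilt": self.tilt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrindingCondition":
        return cls(**d)


@dataclass
class ForceTrace:
    """Uniformly sampled triaxial force time series.

    ``t`` is a 0-based uniform grid in seconds with step ``1/sampling_rate``;
    ``fx, fy, fz`` are force channels in newtons, one value per time point.
    ``annotations`` optionally records generator-planted spikes and
    ``deviation_onset`` a planted tip-deviation time.
    """

    sampling_rate: float
    t: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    condition_id: str = ""
    annotations: list[SpikeEvent] | None = None
    deviation_onset: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if self.n else 0.0

    def channel(self, axis: str) -> np.ndarray:
        if axis not in AXES:
            raise KeyError(f"unknown axis {axis!r}")
        return getattr(self, "f" + axis)

    def resultant(self) -> np.ndarray:
        """Euclidean magnitude sqrt(fx² + fy² + fz²) per sample, N."""
        return np.sqrt(self.fx**2 + self.fy**2 + self.fz**2)

    def require_valid(self) -> "ForceTrace":
        problems = validate_trace(self)
        if problems:
            raise TraceFormatError("; ".join(problems))
        return self


@dataclass
class ThermalTrace:
    """Uniformly sampled tool-tip temperature time series (°C)."""

    sampling_rate: float
    t: np.ndarray
    temp: np.ndarray
    condition_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)

    @property
    def n(self) -> int:
        return len(self.t)

    def require_valid(self) -> "ThermalTrace":
        problems = _grid_violations(self.t, self.sampling_rate)
        if len(self.temp) != len(self.t):
            problems.append("channel length mismatch")
        if not np.all(np.isfinite(self.temp)):
            k = int(np.flatnonzero(~np.isfinite(self.temp))[0])
            problems.append(f"non-finite value temp[{k}]")
        elif np.any(self.temp < -273.15):
            problems.append("temperature below absolute zero")
        if problems:
            raise TraceFormatError("; ".join(problems))
        return self


def _grid_violations(t: np.ndarray, sampling_rate: float) -> list[str]:
    out: list[str] = []
    if len(t) < 2:
        out.append("fewer than 2 samples")
        return out
    if not np.isfinite(sampling_rate) or sampling_rate <= 0:
        out.append("sampling_rate must be positive")
        return out
    if abs(t[0]) > GRID_TOL:
        out.append("time grid does not start at 0")
    dt = np.diff(t)
    if np.any(np.abs(dt - 1.0 / sampling_rate) > GRID_TOL):
        out.append("non-uniform sampling")
    return out


def validate_trace(trace: ForceTrace) -> list[str]:
    """Check every ForceTrace invariant; return human-readable violations.

    Total: never raises on arbitrary finite (or non-finite) input; an empty
    list means the trace is valid.
    """
    out: list[str] = []
    lengths = {len(trace.t), len(trace.fx), len(trace.fy), len(trace.fz)}
    if len(lengths) != 1:
        out.append("channel length mismatch")
    for axis in AXES:
        ch = trace.channel(axis)
        bad = np.flatnonzero(~np.isfinite(ch))
        if bad.size:
            out.append(f"non-finite value f{axis}[{int(bad[0])}]")
    out.extend(_grid_violations(trace.t, trace.sampling_rate))
    return out


def _read_numeric_csv(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for c in columns:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.index[col.isna() & df[c].notna()]
        if len(bad):
            raise TraceFormatError(
                f"{path}: non-numeric value in column {c} at data row {int(bad[0])}"
            )
        if col.isna().any():
            k = int(col.index[col.isna()][0])
            raise TraceFormatError(f"{path}: empty cell in column {c} at data row {k}")
        df[c] = col.astype(float)
    return df


def _infer_rate(t: np.ndarray, path) -> float:
    if len(t) < 2:
        raise TraceFormatError(f"{path}: need at least 2 rows to infer sampling rate")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0 or np.any(np.abs(dt - step) > GRID_TOL):
        k = int(np.argmax(np.abs(dt - step)))
        raise TraceFormatError(f"{path}: non-uniform time grid near data row {k + 1}")
    return 1.0 / step


def read_force_csv(path, sampling_rate_override: float | None = None) -> ForceTrace:
    """Read a ``t,fx,fy,fz`` CSV into a validated :class:`ForceTrace`.

    The sampling rate is inferred from the time grid unless overridden.
    """
    df = _read_numeric_csv(path, ("t", "fx", "fy", "fz"))
    t = df["t"].to_numpy()
    rate = sampling_rate_override or _infer_rate(t, path)
    trace = ForceTrace(
        sampling_rate=rate,
        t=t,
        fx=df["fx"].to_numpy(),
        fy=df["fy"].to_numpy(),
        fz=df["fz"].to_numpy(),
        condition_id=Path(path).stem,
    )
    return trace.require_valid()


def write_force_csv(trace: ForceTrace, path) -> None:
    """Write a trace as ``t,fx,fy,fz`` CSV at full float precision."""
    trace.require_valid()
    df = pd.DataFrame({"t": trace.t, "fx": trace.fx, "fy": trace.fy, "fz": trace.fz})
    df.to_csv(path, index=False)


def read_thermal_csv(path, sampling_rate_override: float | None = None) -> ThermalTrace:
    """Read a ``t,temp`` CSV into a validated :class:`ThermalTrace`."""
    df = _read_numeric_csv(path, ("t", "temp"))
    t = df["t"].to_numpy()
    rate = sampling_rate_override or _infer_rate(t, path)
    trace = ThermalTrace(
        sampling_rate=rate,
        t=t,
        temp=df["temp"].to_numpy(),
        condition_id=Path(path).stem,
    )
    return trace.require_valid()


def write_thermal_csv(trace: ThermalTrace, path) -> None:
    trace.require_valid()
    pd.DataFrame({"t": trace.t, "temp": trace.temp}).to_csv(path, index=False)


def load_conditions_yaml(path) -> list[GrindingCondition]:
    """Load grinding conditions from YAML (one mapping or a list of them).

    Field names mirror :class:`GrindingCondition`; per-axis fields are
    mappings ``{x: ..., y: ..., z: ...}``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = [data]
    return [GrindingCondition.from_dict(d) for d in data]


def dump_conditions_yaml(conditions: Iterable[GrindingCondition], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([c.to_dict() for c in conditions], fh, sort_keys=False)
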