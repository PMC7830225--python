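"""Seeded synthetic generators for grinding-force, thermal, and deviation traces.

The generators are phenomenological: they reproduce the statistical
structure the analysis assumes — a smooth per-axis force envelope
(base ± amplitude), isolated single-sample spikes with prescribed per-axis
counts and signed peak ranges, exponential heating/cooling profiles, and a
tip-deviation event in which the depth-axis load collapses to zero after a
precursor rise — without any physics of material removal.

Force-trace contract (all checked):
  (a) spike-free samples of each axis lie within base ± amplitude;
  (b) successive spike-free samples differ by less than
      ``baseline_smoothness`` newtons (default 2 N, well under the 5 N
      spike rule, so the envelope alone can never trigger the detector);
  (c) exactly ``spike_count[axis]`` single-sample spikes per axis, pairwise
      at least ``min_spike_separation`` samples apart, never at the first
      or last sample, each drawn uniformly from the portion of the signed
      peak range that satisfies the detection rule (>= 5 N from the axis
      mean and from both neighbors);
  (d) the ``annotations`` list records the planted events exactly;
  (e) the trace is self-validated with the reference detector and
      resampled (bounded by ``max_retries``) on any mismatch.

``builtin_conditions`` transcribes the six experimental series of the
study this package models: manual/machine actuation, cortical/cancellous
bone, dry/wet atmosphere, with published per-axis force envelopes, spike
counts, and spike peak ranges.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .detect import DetectorConfig, detect_spikes
from .errors import InfeasibleConditionError
from .traces import AXES, ForceTrace, GrindingCondition, PerAxis, SpikeEvent, ThermalTrace

#: detection threshold the generator guarantees planted spikes against, N
SPIKE_THRESHOLD = 5.0

#: safety margin over the threshold for the mean-deviation condition, N;
#: covers the shift of the whole-trace mean caused by planting the spikes
MEAN_MARGIN = 0.6


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generators.

    seed : master seed; identical (condition, config) pairs give
        bit-identical traces.
    sampling_rate : Hz (default 1000).
    baseline_smoothness : max |successive-sample difference| of the
        spike-free signal, N; must stay below the 5 N detection threshold.
    min_spike_separation : samples between planted spikes (default 50).
    max_retries : resampling attempts before declaring a condition
        infeasible.
    ambient_temp, dry_peak, wet_peak : °C; the dry peak is a representative
        value for a measurement reported only as a lower bound.
    thermal_rise_tau, thermal_decay_tau : exponential time constants, s.
    thermal_rate : Hz of the thermal trace (thermal cameras sample slowly).
    """

    seed: int = 0
    sampling_rate: float = 1000.0
    baseline_smoothness: float = 2.0
    min_spike_separation: int = 50
    max_retries: int = 20
    ambient_temp: float = 25.0
    dry_peak: float = 270.0
    wet_peak: float = 61.0
    thermal_rise_tau: float = 4.0
    thermal_decay_tau: float = 6.0
    thermal_rate: float = 10.0

    def __post_init__(self):
        if not 0 < self.baseline_smoothness < SPIKE_THRESHOLD:
            raise ValueError("baseline_smoothness must be in (0, 5) N")
        if self.min_spike_separation < 3:
            raise ValueError("min_spike_separation must be >= 3")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")
        if self.dry_peak < self.ambient_temp or self.wet_peak < self.ambient_temp:
            raise ValueError("thermal peaks must not be below ambient")
        if self.sampling_rate <= 0 or self.thermal_rate <= 0:
            raise ValueError("sampling rates must be positive")


def builtin_conditions() -> list[GrindingCondition]:
    """The six built-in experimental series (1d, 1w, 2d, 2w, 3, 4).

    Manual series travel along y (negative direction), machine series along
    x; durations are 30 s tasks; the manual feed 55 mm/min is the midpoint
    of the reported "about 50-60 mm/min", the machine feed is exactly
    55 mm/min. Per-axis base ± amplitude envelopes, spike counts, and
    signed spike peak ranges transcribe the published per-series records.
    Zero-count axes carry a (0, 0) placeholder range, never sampled.
    """
    z = (0.0, 0.0)
    rows = [
        # series, tissue, atm, actuator, travel, tilt,
        #   base,             amplitude,        counts,      peak ranges
        ("1d", "cortical", "dry", "manual", "y-", 60.0,
         (-1.5, -2.0, 0.0), (1.5, 2.0, 1.0), (23, 10, 21),
         ((-10, 5), (-1, 11), (-12, 13))),
        ("1w", "cortical", "wet", "manual", "y-", 60.0,
         (-2.0, -3.0, -3.0), (2.0, 3.0, 4.0), (0, 0, 0), (z, z, z)),
        ("2d", "cancellous", "dry", "manual", "y-", 60.0,
         (-1.5, 1.5, 1.5), (1.0, 1.5, 2.5), (0, 0, 5),
         (z, z, (-6, 10))),
        # the single y-axis spike's printed range is unreadable in the
        # source table; the same row's z-axis range is adopted for it
        ("2w", "cancellous", "wet", "manual", "y-", 60.0,
         (-3.5, 4.0, 5.0), (2.0, 1.5, 2.5), (0, 1, 11),
         (z, (-2, 15), (-2, 15))),
        ("3", "cortical", "wet", "machine", "x+", 0.0,
         (0.0, -5.0, -8.0), (5.0, 5.0, 3.0), (92, 10, 19),
         ((-80, 80), (-12, 15), (-23, 43))),
        ("4", "mixed", "wet", "machine", "x+", 0.0,
         (0.0, 0.0, 0.0), (3.0, 3.0, 3.0), (21, 25, 21),
         ((-18, 13), (-27, 17), (-17, 24))),
    ]
    out = []
    for sid, tissue, atm, act, travel, tilt, base, amp, cnt, rng in rows:
        out.append(
            GrindingCondition(
                series_id=sid,
                tissue=tissue,
                atmosphere=atm,
                actuator=act,
                travel=travel,
                duration=30.0,
                base=PerAxis(*base),
                amplitude=PerAxis(*amp),
                spike_count=PerAxis(*cnt),
                spike_peak_range=PerAxis(*rng),
                feed_rate=55.0,
                cut_depth=2.0,
                tilt=tilt,
            )
        )
    return out


def conditions_by_id() -> dict[str, GrindingCondition]:
    return {c.series_id: c for c in builtin_conditions()}


def _series_key(label: str) -> int:
    # stable across processes (hash() is salted; zlib.crc32 is not)
    return zlib.crc32(label.encode("utf-8")) % (2**31)


def _smooth_noise(rng: np.random.Generator, t: np.ndarray, rate: float,
                  amplitude: float, smoothness: float) -> np.ndarray:
    """Zero-mean smooth signal with max|x| == amplitude and successive-sample
    differences < smoothness, built from a cubic spline through random nodes."""
    n = len(t)
    if amplitude == 0.0:
        return np.zeros(n)
    node_dt = 0.1
    for _ in range(12):
        k = max(int(np.ceil(t[-1] / node_dt)) + 3, 4)
        nodes_t = np.linspace(-node_dt, t[-1] + node_dt, k)
        nodes_v = rng.uniform(-1.0, 1.0, k)
        x = CubicSpline(nodes_t, nodes_v)(t)
        x -= x.mean()
        peak = np.max(np.abs(x))
        if peak < 1e-12:
            continue
        x *= amplitude / peak
        if n < 2 or np.max(np.abs(np.diff(x))) < smoothness:
            return x
        node_dt *= 2.0  # smoother nodes for low sampling rates
    raise RuntimeError("could not build a baseline satisfying the smoothness bound")


def _pick_spike_indices(rng: np.random.Generator, n: int, count: int, sep: int
                        ) -> np.ndarray:
    """``count`` sorted indices in (0, n-1), pairwise >= sep apart."""
    if count == 0:
        return np.empty(0, dtype=int)
    span = (n - 2) - (count - 1) * (sep - 1)  # positions 1 .. n-2
    if span < count:
        raise ValueError("trace too short for requested spike count/separation")
    u = np.sort(rng.choice(span, size=count, replace=False))
    return 1 + u + np.arange(count) * (sep - 1)


def _feasible_intervals(lo: float, hi: float, centers: list[tuple[float, float]]
                        ) -> list[tuple[float, float]]:
    """Subtract open bands (c - m, c + m) from [lo, hi]."""
    segs = [(lo, hi)]
    for c, m in centers:
        nxt = []
        for a, b in segs:
            if b <= c - m or a >= c + m:
                nxt.append((a, b))
                continue
            if a < c - m:
                nxt.append((a, c - m))
            if b > c + m:
                nxt.append((c + m, b))
        segs = nxt
    return [(a, b) for a, b in segs if b > a]


def _sample_from_intervals(rng: np.random.Generator,
                           segs: list[tuple[float, float]]) -> float:
    lengths = np.array([b - a for a, b in segs])
    r = rng.uniform(0.0, lengths.sum())
    for (a, b), w in zip(segs, lengths):
        if r <= w:
            return a + r
        r -= w
    return segs[-1][1]


def generate_force_trace(condition: GrindingCondition,
                         config: GeneratorConfig) -> ForceTrace:
    """Simulate one grinding trial satisfying the planted-spike contract.

    Raises :class:`InfeasibleConditionError` when a spike peak range offers
    no value at least 5 N from the axis baseline, or when self-validation
    keeps failing after ``max_retries`` resamples.
    """
    n = int(round(condition.duration * config.sampling_rate))
    if n < 2:
        raise ValueError("duration x sampling_rate must give at least 2 samples")
    t = np.arange(n) / config.sampling_rate
    eps = 1e-6  # float-safety on the >= comparisons of the detection rule

    # structural feasibility: some peak must clear the mean condition
    for axis in AXES:
        if condition.spike_count[axis] == 0:
            continue
        lo, hi = condition.spike_peak_range[axis]
        base = condition.base[axis]
        if not _feasible_intervals(lo, hi, [(base, SPIKE_THRESHOLD + MEAN_MARGIN)]):
            raise InfeasibleConditionError(
                axis, f"spike peak range [{lo}, {hi}] lies entirely within "
                f"{SPIKE_THRESHOLD} N of the baseline {base} N")

    root = np.random.SeedSequence(
        [config.seed % (2**31), _series_key(condition.series_id)])
    last_problem = "exhausted retries"
    for attempt, child in enumerate(root.spawn(config.max_retries)):
        rngs = [np.random.default_rng(s) for s in child.spawn(3)]
        channels: dict[str, np.ndarray] = {}
        annotations: list[SpikeEvent] = []
        feasible = True
        for axis, rng in zip(AXES, rngs):
            base = condition.base[axis]
            amp = condition.amplitude[axis]
            signal = base + _smooth_noise(
                rng, t, config.sampling_rate, amp, config.baseline_smoothness)
            count = int(condition.spike_count[axis])
            idx = _pick_spike_indices(rng, n, count, config.min_spike_separation)
            lo, hi = condition.spike_peak_range[axis]
            for i in idx:
                bands = [
                    (base, SPIKE_THRESHOLD + MEAN_MARGIN),
                    (float(signal[i - 1]), SPIKE_THRESHOLD + eps),
                    (float(signal[i + 1]), SPIKE_THRESHOLD + eps),
                ]
                segs = _feasible_intervals(lo, hi, bands)
                if not segs:
                    feasible = False
                    break
                peak = _sample_from_intervals(rng, segs)
                signal[i] = peak
            if not feasible:
                last_problem = f"axis {axis}: no feasible spike peak at attempt {attempt}"
                break
            channels[axis] = signal
            for i in idx:
                annotations.append(
                    SpikeEvent(axis=axis, index=int(i), time=float(t[i]),
                               peak_force=float(signal[i]),
                               excursion=float(abs(signal[i] - signal.mean()))))
        if not feasible:
            continue
        trace = ForceTrace(
            sampling_rate=config.sampling_rate, t=t,
            fx=channels["x"], fy=channels["y"], fz=channels["z"],
            condition_id=condition.series_id,
            annotations=sorted(annotations, key=lambda e: (e.axis, e.index)))
        detected = detect_spikes(trace, DetectorConfig(threshold=SPIKE_THRESHOLD))
        ok = True
        for axis in AXES:
            want = sorted(e.index for e in annotations if e.axis == axis)
            got = sorted(e.index for e in detected[axis])
            if want != got:
                ok = False
                last_problem = (f"axis {axis}: detector found {len(got)} spikes, "
                                f"planted {len(want)}")
                break
        if ok:
            return trace
    bad_axis = last_problem.split(":")[0].replace("axis ", "").strip()
    raise InfeasibleConditionError(
        bad_axis if bad_axis in AXES else "x",
        f"self-validation failed after {config.max_retries} attempts "
        f"({last_problem})")


def generate_thermal_trace(condition: GrindingCondition,
                           config: GeneratorConfig,
                           cool_window: float = 10.0) -> ThermalTrace:
    """Tool-tip temperature profile for one trial.

    Starts at ambient, rises exponentially toward the atmosphere-dependent
    peak during the active grinding interval (normalized so the maximum hits
    the peak exactly at the end of grinding), then decays exponentially over
    ``cool_window`` seconds. Deterministic given the config.
    """
    if condition.duration <= 0:
        raise ValueError("duration must be positive")
    peak = config.dry_peak if condition.atmosphere == "dry" else config.wet_peak
    total = condition.duration + cool_window
    n = int(round(total * config.thermal_rate)) + 1
    t = np.arange(n) / config.thermal_rate
    d = condition.duration
    rise_scale = 1.0 - np.exp(-d / config.thermal_rise_tau)
    temp = np.empty(n)
    active = t <= d
    temp[active] = config.ambient_temp + (peak - config.ambient_temp) * (
        1.0 - np.exp(-t[active] / config.thermal_rise_tau)) / rise_scale
    t_end = config.ambient_temp + (peak - config.ambient_temp)
    temp[~active] = config.ambient_temp + (t_end - config.ambient_temp) * np.exp(
        -(t[~active] - d) / config.thermal_decay_tau)
    return ThermalTrace(sampling_rate=config.thermal_rate, t=t, temp=temp,
                        condition_id=f"{condition.series_id}-thermal")


#: envelope of the manual cancellous wet trial the deviation event emulates
_DEV_BASE = PerAxis(-3.5, 4.0, 5.0)
_DEV_AMP = PerAxis(2.0, 1.5, 2.5)
#: residual noise amplitude after tip deviation, N (tool off the bone)
_DEV_RESIDUAL = 0.3
#: precursor ramp on the depth axis: gain over the window before onset
_DEV_RAMP_GAIN = 10.0
_DEV_RAMP_WINDOW = 2.0


def generate_deviation_trace(config: GeneratorConfig, onset: float,
                             duration: float = 30.0) -> ForceTrace:
    """Trial ending in tip deviation: the depth (z) load collapses to ~0 N
    at ``onset``, preceded by a monotone-trend rise over a 2 s precursor
    window. ``deviation_onset`` is recorded on the returned trace."""
    if not 0.0 < onset < duration:
        raise ValueError("onset must lie strictly inside the record")
    n = int(round(duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    root = np.random.SeedSequence([config.seed % (2**31), _series_key("deviation")])
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    channels = {}
    for axis, rng in zip(AXES, rngs):
        channels[axis] = _DEV_BASE[axis] + _smooth_noise(
            rng, t, config.sampling_rate, _DEV_AMP[axis],
            config.baseline_smoothness)
    k_on = int(round(onset * config.sampling_rate))
    w0 = max(0, k_on - int(round(_DEV_RAMP_WINDOW * config.sampling_rate)))
    ramp = np.zeros(n)
    if k_on > w0:
        ramp[w0:k_on] = _DEV_RAMP_GAIN * (t[w0:k_on] - t[w0]) / (t[k_on - 1] - t[w0] + 1e-12)
    fz = channels["z"] + np.sign(_DEV_BASE["z"]) * ramp
    residual = {axis: _smooth_noise(rng, t, config.sampling_rate, _DEV_RESIDUAL,
                                    config.baseline_smoothness)
                for axis, rng in zip(AXES, [rngs[3]] * 3)}
    fx, fy = channels["x"], channels["y"]
    fx = np.where(t >= onset, residual["x"], fx)
    fy = np.where(t >= onset, residual["y"], fy)
    fz = np.where(t >= onset, residual["z"], fz)
    return ForceTrace(sampling_rate=config.sampling_rate, t=t,
                      fx=fx, fy=fy, fz=fz, condition_id="deviation",
                      deviation_onset=float(onset))
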