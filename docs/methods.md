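# Methods

This note documents the models, algorithms, and design choices behind
`grindforce`: what each component computes, the parameters that matter,
what the synthetic generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## The spike statistic

The core statistic is a threshold rule on a uniformly sampled force
channel. Sample *i* (0 < *i* < n−1) on an axis qualifies as a spike when

    |F_i − B_i| ≥ θ   and   |F_i − F_{i−1}| ≥ θ   and   |F_i − F_{i+1}| ≥ θ

with θ = 5 N by default. All comparisons are inclusive (≥, "5 N or
more"). Endpoints can never qualify because they lack a neighbor.

**Baseline B.** "The average value at the time of measurement" is read as
the per-axis mean over the whole trial (`task_mean`), because force
records of this kind are reported with one base value per trial. For
drifting records a centered running mean (`running_mean`, default window
1 s, shrinking at the edges) is available; the two modes share the same
qualification and merge logic.

**Merging.** Qualifying samples at most `merge_gap` samples apart
(default 3) collapse into one event at the sample of maximal |F − B|
(ties break to the earlier sample). This prevents double-counting ringing
around one physical excursion. Whether the original counting merged
adjacent qualifying samples is unknowable from a published table alone;
planted single-sample spikes are unaffected by any merge_gap ≥ 1.

**Monotonicity caveat.** The count of *qualifying samples* is monotone
non-increasing in θ. The count of *merged events* is not, in general: a
sample qualifying only at a lower threshold can bridge two groups more
than `merge_gap` apart into one event, so lowering θ can reduce the event
count. `qualifying_mask` exposes the raw rule so both quantities are
available; on traces whose spikes are isolated (≥ `min_spike_separation`
apart, as all synthetic fixtures are) event counts are monotone as well.

**The rule applies per axis independently**; a simultaneous excursion on
two axes counts once on each, matching per-axis reporting.

`oracle_detect` re-implements the rule as naive per-sample Python with no
shared helpers. It exists so detector and oracle falsify each other in
randomized equivalence tests; it is never the production path.

## Synthetic trials

The generator is phenomenological by design: published records summarize
each trial as a per-axis envelope (base ± amplitude), per-axis spike
counts, and signed spike peak ranges, and that is exactly the structure
generated — no material-removal physics, no specific cutting energy.

**Spike-free envelope.** Each axis is base plus a smooth noise term:
a cubic spline through uniform random nodes (0.1 s spacing; doubled when
needed at low sampling rates), mean-subtracted and rescaled so its
maximum absolute value equals the amplitude exactly. Consequences that
the analysis relies on:

- every spike-free sample lies within base ± amplitude, and the envelope
  is attained, so amplitude estimation can recover it;
- the spike-free per-axis mean equals base exactly;
- successive samples differ by less than `baseline_smoothness`
  (default 2 N < θ), so the envelope alone can never satisfy the
  neighbor conditions of the spike rule — neither at a baseline sample
  nor at the neighbor of a planted spike.

**Planted spikes.** Spikes are single-sample excursions, the reading of a
rule that compares a sample against "immediately before and after".
Indices are drawn uniformly among interior positions with pairwise
separation ≥ `min_spike_separation` (default 50 samples), so merging
never joins two planted events. Each peak is drawn uniformly from the
subset of the signed peak range that satisfies the detection rule:
at least θ + 0.6 N from the axis base (the 0.6 N margin covers the shift
of the whole-trace mean caused by planting; the worst builtin case, 92
spikes of up to 85 N offset in 30 000 samples, shifts the mean by
≈ 0.26 N) and at least θ from both realized neighbors. Interval
subtraction gives the feasible set exactly; a structurally empty set
(range entirely within θ of base) raises an infeasibility error naming
the axis.

**Self-validation.** After planting, the trace is run through the
reference detector; the generated trace is accepted only if detected
indices equal planted indices on every axis, otherwise the whole trace is
resampled from a fresh child stream (bounded by `max_retries`, default
20). In practice the first attempt validates; the loop is a guarantee,
not a crutch.

**Determinism.** All randomness flows from a `SeedSequence` keyed by the
config seed and a CRC32 of the series id, so identical (condition,
config) pairs give bit-identical traces across processes, and different
series get independent streams from the same seed.

**Thermal traces.** Temperature starts at ambient (25 °C), rises
exponentially (τ = 4 s) toward the atmosphere-dependent peak — 270 °C
dry, 61 °C wet — normalized so the maximum equals the peak exactly at the
end of the active interval, then decays exponentially (τ = 6 s) over a
10 s cooling window at a 10 Hz thermal-camera rate. The dry peak is a
representative value for a measurement reported only as a lower bound
("more than 270 °C"); with these defaults the dry-minus-wet cooling
effect is 209 °C. A peak equal to ambient degenerates to a constant
trace.

**Deviation trials.** The tip-deviation generator emulates the one
observed slippage event: envelope parameters of the manual cancellous wet
series, a linear +10 N ramp on the depth (z) channel over the 2 s before
onset (slope ≈ 5 N/s, comfortably above both the smooth-noise slope
variability of ≈ ±2.5 N/s and the 0.5 N/s warning threshold), then all
channels drop to residual noise of 0.3 N amplitude — the tool is off the
bone, so |fz| stays below the 0.5 N detection epsilon.

### What the generator does not emulate

Real dynamometer records have colored noise tied to tool rotation
(~1 kHz at 64 000 rpm), multi-sample spike transients, axis coupling,
drift from thermal load on the sensor, and operator-specific feed
variation. Passing recovery tests therefore shows that the detector
implements the stated rule exactly and recovers structure the rule
defines; it does not validate the rule itself against hardware noise.
The `running_mean` baseline and configurable thresholds exist precisely
because real records will need them.

## Envelope estimation

`estimate_baseline` drops spike samples and their ± `merge_gap` neighbors,
then reports base = mean and amplitude = max |residual| of the remaining
samples, rounded to 0.1 N (the precision such tables print). The mean is
preferred over the midrange for robustness to noise shape. An axis with
no samples left is a degenerate input and raises. On synthetic fixtures
recovery is exact to the rounding step (observed errors 0.0 N across all
six conditions × ten seeds; the tests assert the looser 0.2/0.3 N).

## Axis roles

Travel along y ⇒ (feed = y, torque = x, depth = z); travel along x swaps
x and y. The mapping ignores travel sign and rejects z travel (the depth
axis cannot be the feed axis in this geometry). One source table lists
the machine series travel as x(−) while the text says X(+); the mapping
is sign-invariant, so the conditions store "x+" and the discrepancy is
immaterial.

## Kinematics

The active grinding interval is extracted from the resultant force
magnitude √(fx² + fy² + fz²): t_start is the start of the first run above
`onset_threshold` (0.5 N) lasting ≥ `min_hold` (0.2 s), t_end the end of
the last such run. The resultant is used rather than any single axis
because grinding loads different axes depending on travel direction; the
hold time rejects noise blips. Raising the threshold can only shrink the
segment (runs at a higher threshold are subsets of runs at a lower one).
Speed is V = L/T with L the measured grinding distance; per-trial speeds
average arithmetically, reported in mm/min. With the built-in manual
conditions (feed 55 mm/min — the midpoint of the reported "about
50–60 mm/min" — over 30 s tasks, L = 27.5 mm) the recovered mean manual
speed is 55.0 mm/min.

## Tip-deviation monitor

The detector operationalizes a single observed event, favoring a simple,
falsifiable definition: onset is the start of the final run of
|depth force| < ε (0.5 N) that extends to the end of the record, provided
the run lasts ≥ 1 s and the mean resultant force over the preceding
second is ≥ 1 N (there must have been active grinding to deviate from).
The precursor score is the least-squares slope of the depth-axis force
over the 2 s before onset; slope > 0.5 N/s raises the warning flag. The
slope is linear in the trace, so force rescaling scales the score. Onset
recovery on generated deviations is exact to one sample. Rising feed-axis
force is also described as part of the precursor signature; only the
depth axis is scored here, feed-axis scoring being a natural extension.

False positives are possible by construction when a trial's depth-axis
envelope crosses zero near the end of the record (e.g. an 0 ± 1 N depth
channel); with the default ε and hold this is rare (none across the six
builtin conditions × ten seeds) but not impossible, which is why the
monitor reports an event object rather than acting on it.

## Sizes, tolerances, defaults

- Sampling rate 1000 Hz, 30 s trials (30 000 samples × 3 axes): the
  record length is stated; the rate is a package default chosen as
  typical for piezoelectric dynamometry, configurable everywhere.
- CSV dialect fixed (comma, header, "." decimal, full float precision):
  write/read round trips preserve samples to < 1e-9, grid uniformity is
  checked to 1e-9 s.
- Test and acceptance runs use the full 1000 Hz × 30 s fixtures (ten
  seeds per condition, cached per session); the whole suite runs in a few
  seconds on one CPU. Deviation-monitor unit tests use 200 Hz fixtures,
  where one-sample onset granularity (5 ms) still sits well inside the
  10 ms assertion tolerance.
- The statsmodels-style `GrindingTrialModel` / `GrindingTrialResults`
  facade is presentation only; every computation lives in the functional
  modules (`detect`, `summary`, `kinematics`, `deviation`, `synth`) and
  is importable without the facade.

## Known limitations

- The generator's spike peaks are uniform on the feasible subset of the
  printed range, not on the full range; peaks within 5 N of the baseline
  would contradict the detection rule that defines them.
- The unreadable printed peak range for the single y-axis spike of the
  manual cancellous wet series is taken as (−2, 15) N, the same row's
  z-axis range.
- Temperature profiles are deterministic saturating exponentials; no
  emissivity correction or heat-conduction modelling is attempted, and
  infrared-vs-contact measurement bias is out of scope.
- No statistical comparison between conditions is performed: with one
  selected trial per condition there is no replication to test.
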