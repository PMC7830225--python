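# grindforce

Triaxial grinding-force and thermal analysis for simulated bone grinding.

When a surgeon thins vertebral bone with a high-speed diamond bur — as in
a partial laminectomy — the forces the tool transmits into the bone carry
safety-relevant information: sudden resistance spikes signal heterogeneous
tissue or loss of control, the force component along each axis reflects
feed, torque, or cutting depth depending on the travel direction, and a
collapse of the depth-axis load means the bur tip has slipped off the
bone. Irrigation changes all of this: water lubricates (fewer spikes) and
cools the tip by well over 100 °C.

`grindforce` implements that analysis as a tested, reusable pipeline for
triaxial dynamometer recordings:

- **Spike detection.** A sample F_i on an axis is a spike when
  |F_i − B| ≥ 5 N, |F_i − F_{i−1}| ≥ 5 N, and |F_i − F_{i+1}| ≥ 5 N,
  where B is the trial's mean force on that axis (a centered running mean
  is available for drifting records). Qualifying samples within a small
  gap merge into one event. A brute-force oracle implementation
  cross-checks the vectorized detector.
- **Envelope estimation.** Spike-free base ± amplitude per axis, the
  standard per-trial force report.
- **Axis roles.** Travel axis → feed, the other horizontal axis → torque,
  z → depth.
- **Kinematics.** Active-interval segmentation of the record and grinding
  speed V = L/T (mm/s) with trial averaging.
- **Thermal analysis.** Peak tool-tip temperature and the dry-minus-wet
  cooling effect.
- **Tip-deviation monitoring.** Detects the depth-load collapse and scores
  the precursor rise (least-squares slope before onset) as an early
  warning.

Because raw recordings from such experiments are rarely deposited, the
package ships a seeded synthetic generator (`grindforce.synth`) whose six
built-in conditions (`1d`, `1w`, `2d`, `2w`, `3`, `4`) reproduce the
published per-series structure — manual/machine actuation,
cortical/cancellous bone, dry/wet atmosphere, per-axis force envelopes,
spike counts, and signed spike peak ranges. The generator plants spikes
that provably satisfy the detection rule and self-validates with the
detector, so detector correctness is tested as exact parameter recovery.

## Worked example

```python
>>> from grindforce import GrindingTrialModel
>>> res = GrindingTrialModel.simulate("1d", seed=1).fit(distance_mm=27.5)
>>> print(res.summary())
Grinding trial analysis
========================================================
condition: 1d           travel: y-   n = 30000 @ 1000 Hz
detector: threshold 5 N, baseline task_mean, merge gap 3
--------------------------------------------------------
axis  role      base (N)  ampl (N)  spikes  peak range (N)
x     torque        -1.5       1.5      23        -9.9~5.0
y     feed          -2.0       2.0      10        3.8~10.5
z     depth          0.0       1.0      21      -11.2~12.7
--------------------------------------------------------
kinematics: L = 27.5 mm, T = 29.999 s, V = 0.917 mm/s (55.0 mm/min)
tip deviation: none detected
planted-spike recovery: ok
```

Reading the output: series `1d` is manual grinding of cortical bone, dry,
travelling along y, so y carries feed force, x torque, z depth. The
spike-free envelope recovered per axis (−1.5 ± 1.5 N on x, etc.) matches
the parameters the trial was generated with; the detector found exactly
the 23/10/21 planted spikes on x/y/z, all peaks inside their signed
ranges. With a grinding distance of 27.5 mm over the ~30 s active
interval the speed is 55 mm/min — a typical manual feed rate.

The same pipeline runs from the shell:

```sh
grindforce simulate --condition 1d --seed 1 --out 1d_s1.csv --thermal 1d_th.csv
grindforce detect --in 1d_s1.csv --out spikes.json
grindforce run-all --conditions 1d,1w,2d,2w,3,4 --seeds 1 --out-dir out/
```

`run-all` writes per-trial CSVs, spike JSONs, a TSV report with a
dry-versus-wet spike-count contrast, and exits non-zero if any planted
count was not recovered.

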