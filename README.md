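# o17relax

Indirect ¹H-MR quantification of ¹⁷O-labelled water (H₂¹⁷O) by proton
relaxometry.

H₂¹⁷O is an MR-visible water tracer: the ¹⁷O nucleus shortens the proton
transverse relaxation time T2 through ¹H–¹⁷O scalar coupling, so the
transverse relaxation **rate** R2 = 1/T2 rises linearly with the H₂¹⁷O
mole fraction while R1 and R2\* stay flat. This package implements the
complete analysis pipeline for that measurement, aimed at quantitative-MRI
researchers working with phantom calibrations and small-animal dynamic
tracer studies:

* **Relaxometry** — voxel-wise T1 from variable-flip-angle spoiled gradient
  echo, `S(θ) = M₀ sinθ (1−E₁)/(1−cosθ E₁)` with `E₁ = e^(−TR/T1)`, and
  T2/T2\* from multi-echo trains, `S(TE) = k e^(−TE/T)`, both fitted by
  damped (Levenberg–Marquardt) least squares with deterministic closed-form
  starts; rate maps via `R = 1000/T` (T in ms, R in s⁻¹).
* **Phantom analysis** — automatic circular vial ROIs of a fixed target
  area (default 118 mm² on the centred 5 slices), per-vial median/IQR of
  the rate pooled over repeated acquisitions, Shapiro–Wilk, Spearman, and
  Games–Howell statistics, and the ordinary-least-squares calibration
  `R2 = a·C + b` over the linear range (default C ∈ [0.245, 5.5] %), with
  guarded inversion `C = (R2 − b)/a`.
* **Dynamics** — baseline-normalised voxel change
  `(R2_POST − R2_PRE)/R2_PRE` per timepoint, the mean-over-mask time curve,
  mono-exponential washout fitting, and the intravascular mixing model for
  dose planning: injecting `V = BV·(C − c_nat)/(E − C)` mL of an
  E-percent-enriched solution brings a blood volume BV from natural
  abundance `c_nat = 0.037 %` to the target concentration C.
* **Synthetic data** — a generator that emulates the two-layout, 19-vial
  cylindrical phantom and the rat-brain bolus experiment with Rician
  magnitude noise and full ground truth, so every stage is testable by
  parameter recovery without scanner data.

I/O is NIfTI-1 (via nibabel) plus small YAML protocol sidecars
(`sequence_kind`, `tr_ms`, `echo_times_ms`, `flip_angles_deg`,
`voxel_size_mm`, `series_duration_min`); the frame axis is the 4th NIfTI
dimension in sidecar order.

## Worked example

Simulate both phantom layouts with two noise repeats, then run the whole
calibration workflow (fit every repeat voxel-wise, detect vial ROIs, pool
per-vial medians, regress on concentration):

```sh
o17relax simulate-phantom --seed 1 --repeats 2 --out-dir sim
o17relax phantom-calibrate --sim-dir sim --out-dir cal
```

which prints (numbers from this exact invocation):

```
R2 = 0.4153·C + 0.2916 (rho=0.945, n=11)
```

i.e. even with only two noise repeats the recovered line sits within a few
percent of the generator's ground-truth slope 0.405 s⁻¹/% and intercept
0.3215 s⁻¹ (thirty repeats, as in `scripts/acceptance.py`, tighten this to
below 1% and 3%); `rho` is the Spearman correlation of
per-vial median R2 with concentration over all 25 vials and `n` the number
of in-range calibration points. `cal/vial_stats.tsv` holds the per-vial
median/IQR table and `cal/calibration.yaml` the model.

Dose planning for a 292-g rat (65 mL/kg blood volume, 70 %-enriched
injectate, 4.6 % target):

```sh
$ o17relax dose --weight-kg 0.292
blood volume: 18.98 mL
injection volume: 1.324 mL
resulting intravascular concentration: 4.600 %
```

The library surface mirrors the CLI; see `o17relax.pipeline` for the
one-call experiment drivers and `docs/methods.md` for the model details.

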