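# Methods

This note documents the models, the synthetic study designs, the numerical
choices, and the known limitations of the package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Signal models and fitting

**Variable-flip-angle T1.** The spoiled gradient-echo steady state is

    S(θ) = M₀ · sinθ · (1 − E₁) / (1 − cosθ · E₁),   E₁ = exp(−TR/T1).

Per voxel, (M₀, T1) minimise the unweighted sum of squared residuals over
the acquired flip angles. The start is the standard linearisation
(DESPOT1): regressing S/sinθ on S/tanθ gives slope E₁ and intercept
M₀(1 − E₁). Voxels whose linearised slope falls outside (0, 1) — including
flat signal across angles, which no T1 can produce — are marked
non-converged.

**Multi-echo T2 / T2\*.** Mono-exponential decay

    S(TE) = k · exp(−TE/T)

fitted over **all** echoes, unweighted. The start is an ordinary
least-squares line through log S vs TE using the voxel's positive
intensities; voxels whose best line does not decay (signal growing with
TE) are non-physical and marked non-converged.

**Refinement.** Both fits are polished by a Levenberg–Marquardt loop
vectorised across all foreground voxels simultaneously (2×2 normal
equations per voxel, multiplicative damping, step accepted only when the
residual decreases). Convergence is declared at relative parameter change
< 1e−8 or after 200 iterations. Relaxation times are constrained to
[1, 20000] ms; fits ending on a bound are reported non-converged.
Amplitudes are capped at 10× the series maximum for the multi-echo model
(where k is close to the first-echo signal) and 1000× for VFA, where with
TR ≪ T1 the signal is only a few percent of M₀ (at T1 = 3000 ms and
TR = 14 ms the Ernst-angle signal is ≈5% of M₀, so a 10× cap would clip
the true amplitude).

**Background and sentinels.** Voxels whose brightest frame is below 5% of
the series maximum are background and are not fitted. Failed or skipped
voxels carry NaN in the time/rate/amplitude maps; the boolean converged
mask is the authoritative record. Rates follow the fixed convention
R [s⁻¹] = 1000 / T [ms].

**No Rician bias correction** is applied, and the least squares are
unweighted. At the default simulation SNR (50 at the first echo) the
Rician floor shifts fitted rates by well under a percent in the
calibration regime; see "known limitations" for where this matters.

## The phantom study and its synthetic twin

The physical design: a cylinder with 13 holes for 50-mL vials, filled
across two layouts with 19 H₂¹⁷O concentrations (0.037, 0.043, 0.045,
0.050, 0.074, 0.093, 0.145, 0.245, 0.491, 0.881, 1.270, 1.603, 2.0, 2.5,
3.1, 3.8, 4.6, 5.5, 6.5 mole-%), each layout carrying three
natural-abundance (0.037%) control vials, imaged repeatedly with three
sequences: VFA T1 (TR 14 ms, flip angles 5–45°), 12-echo gradient-echo
T2\*, and 8-echo turbo-spin-echo T2 (TR 800 ms, TEs 20–160 ms,
96×96×1 at 1.67×1.67×5 mm).

The generator renders this design with ground truth:

* **Forward truth.** R2(C) = 0.405·C + 0.3215 s⁻¹ — the linear calibration
  constants are the simulation's ground truth, which is what makes slope
  and intercept recovery a meaningful end-to-end score. The relationship
  is linear over the whole range; any apparent detection threshold at low
  concentration emerges from noise, not from a kink in the model.
* **Negative controls.** T1 is concentration-independent (3000 ms,
  saline-like); T2\* is also concentration-independent, set to 0.8× the
  shortest in-design T2 (the T2 at the 6.5% reference), which preserves
  T2\* ≤ T2 ≤ T1 at every vial while carrying no concentration signal.
  This matches the study outcome the pipeline must reproduce: R1 and R2\*
  medians show no monotone trend with concentration.
* **Geometry.** A fixed template — one central hole plus a ring of 12 at
  52 mm, vial radius 11 mm inside a 70-mm cylinder. The vial spacing
  leaves ≥2 voxels of background between vials so connected-component ROI
  detection resolves all 13. Rendering is nearest-voxel (a voxel belongs
  to a vial iff its centre is inside); there is no partial-volume
  blending, B1/B0 inhomogeneity, or coil-sensitivity field, so repeated
  "acquisitions" differ only by noise seed.
* **Noise.** Rician: each voxel becomes √((s+g₁)² + g₂²) with independent
  zero-mean Gaussians of width σ, the magnitude-reconstruction noise
  model. The default σ gives SNR 50 at the first echo (defined on the
  mean noiseless first-echo signal over object voxels), high enough that
  per-vial medians are stable and the uncorrected Rician floor is
  negligible. All generators are bit-reproducible given a seed.

**ROI detection** thresholds the first frame of the central slice with
Otsu's method, labels connected components, keeps those with circularity
4π·area/perimeter² > 0.7, and centres a disc ROI on each centroid. The ROI
is the N voxels nearest the centroid with N = round(target area / in-plane
voxel area) — at 118 mm² and 1.67-mm voxels, N = 42 — replicated on the
centred 5 slices (all slices when fewer). Exact-count selection keeps every
ROI within one voxel-area of the target. A guard rejects images whose
foreground/background contrast is below 3:1 (Otsu always returns a split,
even on pure noise). When a layout is supplied, ROIs are matched to holes
by nearest centre.

**Statistics.** Per vial, rates are pooled over repeats and summarised by
median and IQR with linearly interpolated quartiles (the IQR value depends
on this convention, so it is fixed and documented). The battery comprises
Shapiro–Wilk normality (3 ≤ n ≤ 5000), Spearman rank correlation of median
rate vs concentration (average ranks for ties, t-approximation p), and
Games–Howell pairwise comparisons: Welch SE √(s₁²/n₁ + s₂²/n₂),
Welch–Satterthwaite degrees of freedom, q = |Δmean|·√2/SE referred to the
studentized-range distribution with k groups (its built-in familywise
adjustment; no extra correction layer, α = 0.05). Degenerate zero-variance
pairs get p = 1 (equal means) or p = 0 (unequal) by convention. The
implementation is cross-checked against an independent reference
(pingouin) in the tests.

**Calibration** is unweighted OLS of per-vial median R2 on concentration
restricted (inclusively) to [0.245, 5.5]% — the vials bracketing the linear
range, with 6.5% excluded by default — requiring at least two in-range
vials (two points give the interpolating line). Inversion
C = (R2 − b)/a flags any estimate outside the fitted range rather than
extrapolating silently.

## The dynamic rat experiment

The in vivo design: a baseline multi-echo TSE acquisition (the 20-ms-TE
train, chosen for the largest concentration response) followed by 82
consecutive 3-min series after a slow intravenous bolus, 246 min in all.
The tracer readout is the baseline-normalised voxel change
(R2_POST − R2_PRE)/R2_PRE, summarised over a brain mask per timepoint
(mean by default; median available — the voxel-wise mean-of-ratios
definition is primary, the alternative a flag). Baselines below
0.1 s⁻¹ are floored out before division. Timepoint i is stamped
i × series duration.

The synthetic twin places an elliptical ~24×16 mm "brain" on the grid with
true R2(t) = R2_base·(1 + Δ·2^(−(t−t_arr)/t½)) after arrival and R2_base
before. Defaults: R2_base = 13 s⁻¹ (typical 3-T brain tissue),
Δ = 0.10 (the observed immediate ~10% elevation), t½ = 60 min
(mono-exponential washout consistent with the observed gradual return to
baseline over ~4 h), arrival at the first post series. Only the 82×3-min
schedule is fixed by the study design; the rest are documented defaults.
Frames are assumed aligned (anaesthetised subject); there is no motion
correction.

**Dose arithmetic.** With blood volume BV = weight × 65 mL/kg, injecting
V mL of E-percent-enriched solution gives intravascular concentration
(V·E + BV·c_nat)/(V + BV); solving for the target C gives
V = BV·(C − c_nat)/(E − C). The natural-abundance background term is
included by default (a no-background variant is available for comparison).
For a 292-g rat, E = 70%, C = 4.6%: BV = 18.98 mL and V = 1.324 mL.
The related unit conversion: a mole fraction of p percent corresponds to
p/100/18 mol of H₂¹⁷O per gram of water, i.e. 20.56 μmol/g at natural
abundance.

## Problem sizes used in tests and the reproduction script

The acceptance-grade calibration experiment runs at full design size: both
layouts, all 19 concentrations plus controls, 30 repeats at SNR 50 on the
96×96 grid (≈31,000 pooled voxel samples). Unit and property tests use
reduced grids (48×48 or smaller), fewer repeats, and a shortened dynamic
schedule (e.g. 16 series × 12 min for washout recovery) — chosen so each
property is still a strict parameter-recovery check while the whole suite
stays quick; the full 82×3-min schedule itself is exercised where only the
timestamps matter.

## Known limitations

* **Long-T2 censoring bias.** Near natural abundance T2 ≈ 3 s, so the
  160-ms TSE train sees only ~5% total decay; voxel fits there are noisy,
  and excluding the non-physical (non-decaying) ones censors the low-R2
  tail, biasing those vials' medians up by ~2–4% at SNR 50. Vials inside
  the calibration range (≥0.245%) recover within 2%, and the slope and
  intercept are unaffected beyond their stated tolerances. A longer echo
  train or an estimator that retains bound-limited fits would remove the
  bias; both are out of scope here.
* The simulator omits B1/B0 inhomogeneity, slice-profile and
  coil-sensitivity effects, partial-volume edges, stimulated echoes in TSE
  trains, and physiological motion. Passing recovery tests therefore
  demonstrates correctness of the estimators and workflow under the stated
  noise model, not robustness to those instrumental effects; the
  repositioning-and-averaging strategy of a physical study has no
  counterpart here beyond fresh noise seeds.
* The published gradient-echo T2\* protocol's long-TE variant lists echo
  times exceeding its TR, which this package's protocol validation
  (TR > max TE) rejects; the default T2\* factory therefore uses the
  consistent 1-ms-interval train, and the long-interval variant requires a
  caller-supplied TR.
* Scanner-measured statistics (the published medians, IQRs, and Spearman
  rho of the physical phantoms) depend on the true scanner noise field and
  are not reproduction targets; they serve as qualitative anchors only.
* DICOM ingestion is out of scope: the pipeline starts at NIfTI-1 plus a
  YAML sidecar, with DICOM→NIfTI conversion as an external prerequisite.
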