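# Methods

## Scope and design

The package reconstructs a quantitative-imaging biomarker analysis for
chemoradiation of locally advanced head-and-neck cancer: multi-modal maps
(DWI-derived ADC, DCE-derived Ktrans/kep/vp and blood volume, PET SUV),
threshold tumor subvolumes at pre-treatment and fraction-10 timepoints,
per-tumor metric extraction, and proportional-hazards models of tumor and
patient failure. The patient cohort behind the original analysis is not
public, so the package is organized around a synthetic digital phantom and
a cohort simulator whose defaults encode the study conditions; everything
downstream of rendering is computed exactly as it would be on real data.

Image registration and DICOM handling are deliberately out of scope: the
phantom emits co-registered grids by construction, and the I/O layer
enforces a same-grid contract (shape and voxel size) across the modalities
of a case instead of performing registration.

## The phantom

Tumors are spheres on a 1.5 × 1.5 × 3.0 mm grid (a typical reformatted
head-and-neck protocol) with uniform bulk kinetics and three optional
substructures: a necrotic core whose ADC (3.0×10⁻³ mm²/s) sits above the
necrosis-exclusion threshold, a low-blood-volume blob (plasma fraction
0.015 → BV ≈ 2.7 ml/100 g) and a low-ADC blob (0.9×10⁻³ mm²/s). Blobs
persist at both timepoints — they are the boost-rule targets. The default
two-tumor case encodes the cohort's response pattern: −16.2% GTV volume at
fraction 10 (radius scaled by 0.838^⅓) and bulk ADC rising from 1.34 to
1.62 μm²/ms (+21%, the p16-positive primary-tumor rate; a p16-negative
variant would use ~+10%).

Rendered signals:

- DWI: S(b) = S₀ e^(−b·ADC) at b = 50 and 800 s/mm², S₀ = 500.
- DCE: the modified Tofts forward model per voxel, 60 frames over 360 s,
  driven by a population arterial input function — linear bolus upslope
  (arrival 10 s, rise 8 s) into a biexponential washout (amplitudes 4 + 1
  mM, decay 10⁻² and 2×10⁻⁴ s⁻¹). The original analysis left its AIF
  inside closed-source tooling; a documented population AIF keeps the
  phantom fully reproducible. DCE volumes are treated as already in
  concentration units; signal-to-concentration conversion (relaxivity,
  baseline T1) is out of scope.
- SUV: a Gaussian peak per tumor (σ = r/1.5) over a background of 1.0, so
  the 50%-of-peak isocontour sits well inside the sphere and MTV₅₀ is
  predictable from geometry.

Noise is additive Gaussian on each modality's signal (defaults: SD 2.0 on
DWI signal, 0.01 mM on DCE, 0.05 SUV — high-SNR but nonzero). Rician noise
is not modelled; at the phantom's SNR the difference is negligible, and
additive noise keeps the monotonicity property exact: the unit-variance
noise field depends only on (seed, modality, timepoint), so changing the SD
scales a fixed realization and map-recovery error is monotone in the SD by
construction. Identical specs give bit-identical output.

What the phantom does **not** emulate — and what passing tests therefore do
not show about real data: partial-volume and susceptibility effects, B0/B1
inhomogeneity, EPI distortion, motion, imperfect inter-session registration,
irregular tumor shapes, and intra-tumor kinetic gradients beyond the
piecewise-constant blobs.

## Map computation

**ADC** is the two-point inversion ln(S₁/S₂)/(b₂−b₁). Voxels with
non-positive signal are flagged invalid (NaN) and counted; negative ADCs
(signal rising with b) are kept and counted rather than clipped, so the
downstream air/necrosis thresholds see them. The invalid sentinel
propagates: cleaned analysis masks exclude NaN voxels.

**Modified Tofts fitting** uses variable projection. For fixed kep the
model is linear in (Ktrans, vp), so each candidate kep gets a closed-form
2×2 least-squares solve; constraints (Ktrans ≥ 0, 0 ≤ vp < 1) are handled
by enumerating the interior solution, both single-parameter edges and the
origin, keeping the feasible candidate with least SSE. The kep search is an
81-point grid on [0, 10] min⁻¹ followed by 20 golden-section iterations
inside the winning grid bracket (bracket shrinks ~10⁻⁴-fold; noiseless
recovery lands near 10⁻⁶ relative). `refine=False` exposes the pure grid
argmin, which the exhaustive-search oracle test compares against. The
convolution uses the trapezoid rule via its exact exponential-kernel
recursion, so forward model and brute-force quadrature agree to machine
precision on the same grid. Fits at the kep search bound are flagged
non-converged. A 64³ volume fits in well under a minute on one CPU because
every kep evaluation is a vectorized matrix product over all voxels.

**Blood volume** converts the fitted plasma fraction:
BV = 100·vp/((1−Hct)·ρ) with Hct = 0.45 and ρ = 1 g/ml (both configurable).
The original analysis cites its BV tooling without printing a formula; this
standard vascular conversion is the package's own documented choice, and it
makes the 7.64 ml/100 g threshold correspond to vp ≈ 0.042.

## Subvolumes and metrics

All threshold inequalities are strict (`<` / `>`), matching the printed
protocol; a voxel exactly at a cutoff is excluded. "Persisting" subvolumes
are the voxelwise **intersection** of the pre and fraction-10 masks on the
common grid — the strictest reproducible reading — with union exposed as an
option. Subvolumes are voxel sets, not connected components; no separate
vessel mask exists (vessels fall under the high-ADC exclusion). The MTV₅₀
reference (mean of the 4 largest SUVs) is computed over the cleaned
analysis mask, so every subvolume nests inside it; ties at the 4th-largest
value are resolved by value, not voxel identity. GTVs smaller than 4 voxels
use all available voxels with a warning.

Missing metric values are never silently zero: an empty MTV leaves SUV
statistics and TLG missing; an empty analysis mask leaves mean ADC/BV
missing; change rates require a positive pre value. Patient-level
aggregation sums volume-type metrics (GTV, TV_BV, TV_ADC, MTV₅₀, TLG) and
averages intensity-type metrics over the tumors where they are defined;
"averaged" max SUV is the mean of per-tumor maxima (the global maximum is
an option). Note the TLG identity tlg = mtv₅₀ × mean SUV holds per tumor
but not for the summed aggregate. Human-readable ADC is μm²/ms (10⁻³
mm²/s).

## Survival analysis

ITFFR rows (one per tumor) take the tumor's own progression as the event
and censor at the earliest of distant failure, death or last follow-up of
the patient; DFFS rows (one per patient) take distant failure as the event
and censor at the first locoregional failure, death or last follow-up.
The 18-month landmark labels tumors LF/RF (locoregional progression ≤ 18
months), DF (locoregionally controlled, distant failure ≤ 18 months) or
NED (no progression, follow-up ≥ 18 months); locoregional progression after
the cutoff, or no progression with follow-up shorter than the cutoff,
excludes the tumor. The DF arm's ≤-cutoff qualifier is this package's
reading — the source protocol states the two exclusion rules but does not
time-qualify the DF group.

The Cox fitter maximizes the partial likelihood by Newton iteration with
step-halving; Breslow tie handling is the default (the source analysis
never states one), Efron is an option and matches lifelines where ties
exist. Monotone likelihoods (|β| diverging) and zero-variance covariates
return `converged=False` with a diagnostic rather than numbers. Per-SD
covariates are divided by the sample SD of the analysis rows actually
entering the model; centered covariates have the sample mean subtracted, so
a main effect in an interaction model is the effect at the partner's mean.
For an interaction (x, g) with binary g the fit reports the derived effect
of x in each group (β_x and β_x + β_{x:g}) with delta-method SEs. Naive
model-based SEs are the default, mirroring a tumor-level analysis that
ignores within-patient clustering; a cluster-robust sandwich summary
(score residuals aggregated by patient) is produced alongside when a
cluster column is named. Harrell's c-index counts ties in risk as 0.5.
Rank tests use exact enumeration when both groups have ≤ 8 observations,
otherwise the tie-corrected normal/chi-square approximations; BH-FDR flags
adjusted p < 0.10, two-sided throughout. A two-group logrank utility covers
the dose-arm comparison.

## Cohort simulator

Per-tumor locoregional progression times are exponential with hazard
h₀·exp(βᵀx); distant failure and death are patient-level exponential clocks
independent of the covariates (keeping ITFFR censoring independent, so the
recovery experiments are well-posed); administrative censoring is uniform
over 10–58 months (the cohort's follow-up range). Defaults: 54 patients,
57% p16-positive, one primary plus Poisson(1.5) nodal tumors per patient
(≈2.5 tumors/patient), h₀ = 0.012, distant-failure 0.008 and death 0.003
events/month — chosen to reproduce the cohort's approximate event mix
(~20% locoregional failure, ~26% distant failure).

## Validation studies and problem sizes

- Map recovery: 64³ noiseless phantom; worst-voxel relative error ≤ 1%
  (measured ≈ 10⁻³–10⁻⁴ % for the Tofts maps, ~10⁻¹⁴ % for ADC).
- Subvolume volumetry: analytic sphere volumes recovered within a
  one-voxel surface shell (4πr² × max voxel dimension).
- Cox oracle: Newton fit vs exhaustive grid search of the written-out
  Breslow partial likelihood on ≤8-row fixtures (with ties), |Δβ| < 10⁻³.
- Coefficient recovery: 100 simulated cohorts of ~500 tumors at the
  published effect sizes (p16 −1.578, ADC-per-SD 0.645); each estimate
  within 2 estimated SE of truth in ≥ 90% of replicates. Coverage runs a
  few points below the nominal 95% because the naive SE ignores the
  within-patient clustering of the patient-level p16 covariate — the same
  caveat the cluster-robust option addresses.
- Type-I error: 400 null cohorts at the trial's 54 patients; Wald
  rejection at 0.05 within 5% ± 2%.

## Known limitations

Spheres and piecewise-constant kinetics are an idealization; the fitter's
accuracy on real, noisy, motion-affected DCE data will be bounded by the
acquisition, not by these numerics. The simulator's proportional-hazards
generator matches the fitted model's family, so the recovery studies test
estimation, not model misspecification. BH re-adjustment of already
adjusted p-values is not an identity (the step-up multiplies by n/rank
again); only the significance decisions are stable under re-adjustment.
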