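# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `boldcvr`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The pipeline reimplements the standard awake-rodent hypercapnic-challenge
workflow on a block design of 50 baseline, 50 challenge and 50 recovery
volumes at TR 6 s. Its statistical core treats each voxel's timepoints as
independent samples: percent change about the per-voxel baseline-window
mean, a two-tailed Welch t-test of challenge vs baseline windows,
Benjamini–Hochberg (BH) step-up at q = 0.05 across all masked voxels of a
subject jointly, and an activation rule that is the conjunction
*FDR-significant ∧ Δ > 0 ∧ Δ ≥ 1%*. The two published thresholds (the
t-test and the 1% floor) are combined as a conjunction because a conjunction
is order-independent; decreases are excluded because the volume of
activation is defined over signal *increases*. The 1% threshold is applied
to the window-mean Δ (not per-timepoint excursions); that reading is a
design choice, and the alternative would only shrink activation counts.

Degenerate voxels are handled explicitly: zero variance in both windows with
equal means gives t = 0, p = 1; zero variance with unequal means gives
p = 0 with a degeneracy flag (this is what makes the noiseless end-to-end
identity exact rather than undefined).

The false-positive "filter" is BH because it is the standard procedure
guaranteeing the stated on-average false-discovery bound; the method is a
pluggable argument (`fdr_method`), so Benjamini–Yekutieli can be swapped in
where dependence is a concern.

### Autocorrelation: a deliberate, quantified non-correction

Treating within-window timepoints as independent follows the procedure this
package reimplements; no autocorrelation correction is applied. With AR(1)
noise the variance of a 50-volume window mean is inflated by roughly
(1+ρ)/(1−ρ) relative to the independent case, so the Welch statistic is
anti-conservative. The consequences, measured by
`validation.fdr_null_calibration` (200 global-null phantoms, 15,000 masked
voxels, ρ = 0.2):

* the expected **fraction of voxels** rejected under the global null stays
  far below q (measured ≈ 6.5×10⁻⁴ ≤ 0.05) — the activation *map* remains
  sparse under the null;
* the **familywise realized FDP** (which, under a global null, is 1 whenever
  any voxel is rejected) is large (measured ≈ 0.9). With ρ = 0 the same
  cascade is exactly calibrated (BH on valid p-values; measured mean FDP
  ≈ 0.02 in the suite's white-noise check). Any ρ > 0 breaks the familywise
  bound — at these voxel counts even ρ = 0.05 roughly doubles it.

In practice this means single null voxels scattered across the brain (about
1 per 1,500) survive BH under realistic noise; per-region VOA under the null
is correspondingly a small nonzero count, visible in the worked example.
Users analyzing real data with this procedure should interpret isolated
voxels accordingly, or switch to a GLM with prewhitening — out of scope
here, because the point of the package is the published procedure.

## The phantom generator (what passing tests mean)

`boldcvr.phantom` is the package's study-condition definition, not a
convenience fixture. Defaults:

| parameter | default | rationale |
|---|---|---|
| geometry | 96×96×22 vox, 0.3125×0.3125×1 mm, TR 6 s, 150 vols | reference acquisition |
| brain | ellipsoid, ~15,000 voxels | published in-brain voxel count |
| atlas | 171 leaves in 12 composites (prefrontal 8, somatosensory 17, thalamus 26, cerebellum 17, …) | published hierarchy counts; leaf *shapes* are synthetic raster chunks |
| baseline intensity | 1000, ±15% per-label contrast | arbitrary units; contrast gives registration texture |
| noise σ | 20 (2% of baseline, tSNR 50) | realistic for 312 µm awake-rodent spin-echo |
| AR(1) ρ | 0.2 | low-frequency physiological/motion residue at TR 6 s |
| drift | 0.002 %/volume (0.3% per run) | mild scanner drift |
| response amplitude | 3% BOLD, exponential ramp τ = 3 volumes (18 s) | typical hypercapnic response; no hemodynamic model is claimed |
| injured sustain | 1% post-challenge plateau | models failure to return to baseline (magnitude is a free parameter) |
| sham bump | 1% over volumes 141–150 | models the late 1-min transient (free parameter) |
| motion | smooth trajectories, max displacement ∈ [27, 70] µm | published displacement range; a "rejected" preset jumps 400 µm |

Motion is applied *after* signal synthesis by linear resampling, so
realignment faces genuine interpolation loss. Noise is generated for tissue
voxels only (background stays zero); the AR(1) process is initialized at its
stationary distribution. RNG is a seeded `numpy` Generator with per-subject
child seeds derived from the master seed by counter, making cohorts
byte-reproducible.

What the phantom does **not** emulate: real anatomy and region shapes,
spatially correlated (physiological) noise, field inhomogeneity, spin-echo
signal physics, CO₂ transport dynamics, or between-subject amplitude
variability. Passing tests therefore demonstrate that the *procedure* is
implemented correctly and behaves as analyzed under its stated noise model —
not that the published effect sizes would reproduce on real data (the raw
data are not deposited, and the published group MDs are explicitly not
reproduction targets).

## Registration and realignment

Rigid realignment is Gauss–Newton least squares on the six parameters with
analytic image gradients, after pre-smoothing both volumes (FWHM 0.65 mm),
on a sampling grid of 0.45 mm spacing from which a 0.97 fraction of points
is kept (fixed-seed subsampling, so output is deterministic). Two passes:
all volumes to the first, then all volumes to the rebuilt mean; one final
reslice with a 4th-degree B-spline. These settings are the standard package
defaults for this kind of data; no equivalence with any specific software's
iteration schedule is claimed — the accuracy claim is recovery of known
synthetic motion (RMS residual ≈ 1–2 µm on sub-voxel trajectories, tested
against injected truth after removing the unidentifiable mean offset; the
QC table reports the estimated *motion*, i.e. the inverse of the correction
pull-map, so it compares directly to a trajectory).

Atlas registration is a 9-parameter fit (scale, then rotation, then
translation, about the volume center — the convention is serialized with
every transform) by the same Gauss–Newton scheme on a synthetic intensity
template, with a closed-form intensity gain/offset estimated each iteration
so amplitude mismatches are never absorbed into geometry (without this the
recovered scale biases low by a few percent). Labels are pulled back to
subject space with nearest-neighbor interpolation, which can only preserve
or shrink the label set. Because phantoms are generated in atlas space, the
pipeline default is `register_mode="skip"` (identity segmentation); the
full fit is exercised by tests and available for real-data layouts.

Boundary handling: reflective for Gaussian smoothing (preserves the volume
mean to <0.5%), zero-fill for reslicing. Rotations are extrinsic x-y-z Euler
angles about the volume center.

## Group statistics

The mean difference is always injured − sham, so hypo-reactivity in the
injured group reads as a negative MD. The 95% CI is a seeded bias-corrected
bootstrap over subjects (scipy's BCa, 5000 resamples by default), matching
estimation-graph practice; an analytic Welch CI is available
(`ci_method="welch"`). Composite means use subjects as replicates (the
leaf-areas-as-replicates reading is available by operating on the leaf
table directly). Per-leaf MDs and CIs are exported for estimation graphs.

The mixed ANOVA uses the classical split-plot decomposition with
(subject × leaf region) pairs as units — the only unit definition consistent
with denominators like 110 = 8·14 − 2 and 236 = 17·14 − 2 printed for this
design — and reports uncorrected integer df by default (Greenhouse–Geisser
is behind a flag). The SS decomposition identity and agreement with both a
brute-force oracle and `pingouin.mixed_anova` are tested to 1e-10/1e-8.
Unbalanced series lengths are rejected rather than approximated.

## Validation studies and problem sizes

The validation suite (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses cropped grids that keep the reference
brain-to-grid proportions:

* voxelwise null calibration: 60×60×16 grid cropped around a 15,000-voxel
  brain, 200 phantoms, full 150-volume design;
* cohort-level studies (region-level type-I rate, planted-effect power,
  noiseless identity): 32×32×10 grid, ~2,650-voxel brain, 171 regions,
  7+7 subjects (2+2 for the exactness check), 150 volumes;
* motion recovery: full 96×96×22 geometry with 20 volumes (the estimator is
  per-volume, so trajectory length only scales runtime).

The region-level null uses identical *nonzero* profiles (2% everywhere) in
both groups: with zero response, per-subject VOA is almost surely 0 and the
Welch statistic degenerates to p = 1, which would measure nothing; 2% keeps
counts off floor and ceiling. Measured rate ≈ 0.04–0.05 at α = 0.05.

The planted-effect study halves the injured prefrontal amplitude
(3% → 1.5%) with all other regions at 3% in both groups; detection =
negative MD with Welch p < 0.05.

## Known limitations

* The voxel test's familywise FDR inflation under autocorrelated noise is
  documented, not corrected (see above).
* The demo atlas shares only the hierarchy *counts* with any real rat atlas;
  its region shapes and adjacency are synthetic.
* The affine registration is automatic and intensity-based; the interactive,
  operator-guided alignment used with real atlases has no algorithmic
  description to reproduce, and no equivalence is claimed.
* Slice-timing, susceptibility distortion, nonrigid motion and GLM/HRF
  modeling are out of scope.
* Free parameters of the injured/sham temporal signatures (sustain and bump
  magnitudes) are not published quantities; they exist so the
  condition × time interaction has a planted cause, and their defaults are
  this package's choices.
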