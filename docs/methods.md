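# Methods

`crmoco` re-implements, at desk scale, an MR-based cardiorespiratory
motion-compensation workflow for simultaneous [18F]NaF PET/MR coronary
plaque imaging: from raw (simulated) multi-echo MR k-space and binned PET
emission data with surrogate signals, through non-rigid motion-model
estimation and a dynamic 4-tissue attenuation map, to motion-corrected
PET reconstruction and focal-hotspot quantification.  Everything runs on
a synthetic 2D thorax phantom with exact analytic ground-truth motion, so
every stage of the chain is testable against oracles that clinical data
cannot provide.

## The phantom and what it emulates

A coronal-like 2D slice (default 128×128 at 2 mm) contains two lungs, a
heart (myocardium ring + blood pool), subcutaneous fat, soft tissue, air,
and a small focal plaque on the epicardial surface facing the lung — the
situation that makes coronary PET hard: a millimetre-scale hotspot
adjacent to the lung–soft-tissue attenuation interface, moving with both
respiration and the heartbeat.  An optional stent is a disc with zero MR
signal (water and fat), soft-tissue attenuation and plaque-level
activity.

**Activity** follows the [18F]NaF pattern: low myocardial uptake, a
blood-pool-dominated background (blood 1.2, myocardium 0.9, soft 1.0,
fat 0.4, lung 0.2 a.u.), plaque = `plaque_to_blood_activity_ratio` ×
blood.  The ratio defaults to 10: a 3 mm focus reconstructed at 2 mm
voxels with a 4 mm post-filter loses ~75% of its peak to partial volume,
so an underlying concentration ratio of order ten is what places the
*measured* target-to-background ratio in the clinically reported
1.1–3.4 range (at ratio 3 the reconstructed peak would sit below the
blood pool and no hotspot would exist to quantify).

**Respiration** is a superior–inferior displacement, full amplitude
(default 15 mm) at and below the diaphragm, smooth-stepped to zero at the
chest apex and again towards the inferior body edge (the abdomen
compresses; nothing is advected through the field-of-view boundary).  The
driving waveform is `A·r_k·sin⁴(π(t−t_k)/T_k)` per breathing cycle:
end-exhale is the prevalent state (>60% of samples below half-maximum),
and cycle-to-cycle amplitude (±8%) and period (±0.2 s around 4 s)
variability make the belt/self-navigator alignment well-posed — an
exactly periodic waveform would leave the time shift ambiguous modulo one
period.  **Cardiac** motion is a radial contraction about the heart
centre (default 12% at peak systole, zero at the end-diastolic reference
phase), tapered to zero just outside the myocardium.

Both deformations are monotone 1D maps (row coordinate, radius),
inverted numerically to interpolation precision; the package-wide field
convention is the *pull-back*: a field stored for motion state `t` is
sampled on the state grid and points into the reference frame, so
`warp(I_ref, d)` produces the state-`t` image.  This one convention
serves the MR encoding model, the attenuation-map warp and the PET MCIR
forward model alike; ground-truth fields are exact by construction.
Warped activity is weighted by the Jacobian determinant of the pull-back
map so counts are conserved when tissue compresses (within 2% of
interpolation error at default amplitudes; exactly for integer-pixel
translations).

**Surrogates.** The belt is the true diaphragm trace delayed by
`belt_lag` (0.3 s) with additive Gaussian noise (2% of amplitude); the
self-navigator is the heart's SI displacement plus noise; R-peaks
accumulate normally distributed RR intervals (1.0 ± 0.05 s).  One master
seed drives deterministic per-module substreams.

What the phantom does *not* model: anatomically realistic (XCAT-grade)
anatomy, bone, perfusion or tracer kinetics, B0/multi-peak fat effects,
coil sensitivities, scanner dead time, randoms, PSF.  Passing tests
therefore demonstrate the correctness and the qualitative clinical
behaviour of the algorithms — not quantitative transfer to patient data.

## MR acquisition and water/fat reconstruction

A 2D golden-angle radial trajectory (111.246° increment, TR-spaced
timestamps, default TR 7.57 ms, TE 2.62/4.13/5.64 ms, FA 15° as
metadata) stands in for 3D radial phase encoding: any retrospectively
selected spoke subset covers k-space quasi-uniformly, which is the
property cardiorespiratory binning needs.  Readout samples extend to
1.4× the axis Nyquist (within the corner Nyquist √2) so that radial
sampling covers the Cartesian image spectrum; without this the
least-squares water/fat solution has an irreducible ~6% error from the
missing k-space corners.  `spoke_stride` simulates every n-th TR so a
desk-scale spoke count can span the full MR window.  The signal model per
echo is `W + F·exp(i2πΔf·TE_e)` (single-peak fat, Δf = −428 Hz) of the
phantom deformed to the true state at the spoke timestamp, plus complex
white noise.  The non-uniform DFT exploits the uniform radial sample
spacing: each spoke's sample matrix is geometric in the sample index, so
forward and adjoint are exact, matrix-free recursions (the adjoint is the
same factorisation run as Horner's scheme) — the adjoint test holds to
machine precision.

Binning: respiratory bins are equal-count amplitude quantiles of the
(shifted) belt at the spoke times (6 bins; balances per-bin
undersampling); cardiac bins are equal-width in the phase fraction of the
current RR interval (12 bins; robust to RR variability).  Times before
the first R-peak wrap around with the first interval.

Reconstruction solves, by CGLS with radial-ramp density compensation and
relative Tikhonov weight 1e−3 (a compressed-sensing/TV option is
reserved but deliberately not implemented: quadratic regularisation
keeps the solver testable against closed-form least-squares oracles),

    min_{W,F} Σ_{b,e} ‖D^{1/2}(E_b(M_b W + c_e M_b F) − y_{be})‖² + λ(‖W‖²+‖F‖²)

with per-bin encoding `E_b`, echo phasors `c_e`, and optional motion
warps `M_b` (sparse bilinear matrices; the adjoint is the exact
transpose).  The CGLS objective is monotonically non-increasing.  Without
a motion model each bin is reconstructed independently; with one, a
single reference-state image is estimated from all bins jointly.

## Motion-model estimation

The registration minimises the dual-channel cost

    C(m) = w·S(|W|∘m, |W|_ref) + (1−w)·S(|F|∘m, |F|_ref) + r·R(m)

over a cubic B-spline field (control spacing 16 mm, fixed in physical
space across three multiresolution levels, so coefficients carry over
between levels), with `w = 0.5`.  `S` is negative normalised mutual
information — Parzen joint histograms with linear kernels, 32 fixed-width
bins over the joint 1st–99th percentile window, analytic gradient — or
SSD for fast exact tests.  `R` is the bending energy of the control
lattice.  `r` defaults to a deterministic heuristic: 10% of the initial
similarity magnitude relative to the bending energy of a unit
checkerboard probe.  Images are pre-smoothed by a 0.8 px Gaussian: the
piecewise-linear Parzen NMI surface otherwise has sub-pixel local optima
that strand the optimiser (L-BFGS-B on the analytic gradient) at ~85% of
a known translation.  Fields whose maximum magnitude is below 0.05 px
snap to exactly zero (sub-centipixel registration noise), which also
makes a zero-motion run reduce cr-MCIR to AVG exactly at the model
level.

Direction: `build_model` registers the *reference-bin* image (moving)
onto each bin image (fixed), so every stored field directly warps the
reference state into that bin — the direction all downstream consumers
need.  The mirrored problem has the identical cost form.  Empty bins
inherit the nearest non-empty bin's field and are flagged.

The respiratory reference is end-exhale or end-inhale, whichever
half-range of the belt amplitude holds more samples (ties break to
end-exhale); the cardiac reference is end-diastole (phase bin 0, where
the contraction is zero by construction).  The cardiorespiratory model
composes fields with cardiac innermost (in reference coordinates) and
respiration outermost — the order in which the models are estimated;
the order is a parameter since neither order is canonical.

The belt is aligned to the MR self-navigator by the time shift
maximising their normalised cross-correlation within ±one respiratory
period, preferring the smallest |shift| among near-equal peaks
(quasi-periodic breathing produces secondary maxima one period apart);
the shift is applied globally.  Outside the MR window, respiratory bins
come from the stored quantile thresholds applied to the shifted belt,
with out-of-range amplitudes clamped to the edge bins and counted.

## Attenuation map

k-means (k = 4, seeded k-means++ via scikit-learn) clusters pixels in the
(|W|, |F|) feature plane; classes are identified from centroids (air =
smallest total magnitude, lung = next, fat = larger fat fraction of the
remaining two, soft = the other), making the labelling invariant to
cluster-index permutations.  Signal-void inpainting reassigns air/lung
components that are fully enclosed by the hole-filled body mask and
smaller than 200 mm² to the majority class of a dilated boundary ring;
the operation is idempotent and leaves the lungs untouched through the
enclosure/size criteria.  Class attenuation values at 511 keV are the
standard literature coefficients (air 0, lung 0.0224, fat 0.0864, soft
0.0975 cm⁻¹) — these are not stated in the clinical source and are
configurable.  Warping a μ-map into a motion state uses linear
interpolation along the pull-back field with air fill.

## PET simulation and reconstruction

A 2D parallel-beam projector (pixel-driven with linear radial
interpolation, length-weighted, 180 angles over 180°) is built once as a
sparse matrix, so the backprojector is the exact transpose.  Attenuation
factors are `exp(−∫μ dl)` with the path in cm.  The scan is partitioned
into 0.25 s frames; each frame is binned through the shifted belt + ECG
exactly as the reconstruction will bin, and each combined bin's expected
sinogram is the attenuated projection of the phantom deformed to the
bin's mean true state, scaled by occupancy (plus an optional flat
scatter background at a configurable scatter fraction), normalised so
the expected total is `total_counts` (default 2e6); counts are Poisson.
The emission simulation uses the *ground-truth* per-bin attenuation,
while reconstruction uses the MR-derived map — so attenuation-mismatch
artefacts arise exactly as they do on a scanner.

OSEM uses 21 subsets (interleaved angle strata of 9 or 8 angles — 180/21
is not integer), 3 full iterations, uniform-ones initialisation inside
the FOV circle, an additive expected-scatter term when present, and a
4 mm Gaussian post-filter (σ = FWHM/2√(2 ln 2), circular boundary, which
conserves the image sum exactly; the phantom is air-padded so the
boundary is irrelevant).  cr-MCIR warps the current reference-frame
estimate into each bin (sparse warp), projects with that bin's warped
μ-map and occupancy, and applies the *warp adjoint* (matrix transpose,
not the inverse warp) in the update, keeping the forward/backward pair
an exact adjoint pair; the per-subset sensitivity is the matching
warp-adjoint of the attenuated backprojected ones, guarded by a small
epsilon.  With an all-zero model the update reduces algebraically to
AVG (verified at 1e−6).  A `dynamic_mu=False` mode applies one static
breath-hold μ-map to all bins, for quantifying the dynamic-AC benefit.

## Quantification

Plaque signal `s`: 5×5 patch around the in-ROI SUV maximum; an exact
Otsu split (between-class variance maximised over all splits between
distinct sorted values) excludes background pixels; `s` is the mean of
the strictly-supra-threshold values (patch mean if constant; patches are
clipped and logged at image edges).  Background `b`, `σ_b`: mean and
sample SD (n−1) of a blood-pool ROI disjoint from the plaque ROI.
`TBR = s/b`, `CBR = |s−b|/σ_b`, view-averaged before percent ratios when
several views are configured.  The width `D` comes from a constrained
fit of `a·exp(−(x−b)²/(2c²)) + d·x + e` to a line profile through the
plaque (`a,b,c,e ≥ 0`, `d ∈ [−1,1]`, trust-region least squares with
data-driven initialisation), `D = 2√(2 ln 2)·c`.  The pipeline's default
profile runs along the superior–inferior axis through the plaque — the
dominant motion direction, so the fitted width captures exactly the
blur the motion model is supposed to remove (a cross-motion profile
would measure only the static transverse extent); in this slice that is
also the perpendicular-to-vessel direction.  The `(2c²)` exponent
is deliberate: it is the only convention under which that `D` formula is
the true FWHM; a strict mode with exponent `c²` (whose FWHM is
`2√(ln 2)·c`) is available for sensitivity checks.  Ratios are rounded
to integer percent; summary means/SDs to two decimals with n−1
normalisation.

The Wilcoxon signed-rank test drops zero differences, uses average ranks
for ties, and evaluates the exact two-sided null distribution by a
generating-function recursion over doubled (hence integer) ranks —
identical to enumerating all 2ⁿ sign assignments, in O(n·ΣR) time.  An
`approx` mode delegates to the normal approximation, the long-time
default of common statistics software and therefore the convention
behind most published p-values: on the embedded 10-plaque reference
table the exact method gives p = 0.014/0.037/0.004 (TBR/CBR/width) where
the published convention prints 0.02/0.04/0.01.

## Pipeline and problem sizes

`run_full` executes: phantom + surrogates → MR acquisition → belt
alignment → respiratory binning/reconstruction → respiratory model →
cardiac binning with respiration-corrected reconstructions (each cardiac
bin solved jointly over its respiratory sub-bins with the respiratory
model in the encoding) → cardiac model → concatenation → fully
motion-compensated MR reconstruction → AC map → PET simulation → AVG and
cr-MCIR OSEM → study-table row.  Every stage persists artifacts (NIfTI /
CSV / YAML / npz) and a manifest of content hashes; a re-run with the
same seed is bit-identical.

The end-to-end synthetic study in `scripts/acceptance.py` runs on a
64×64 grid at 2 mm (the clinical voxel scale over a reduced field of
view), ~1500 spokes spanning the full 720 s MR window via spoke striding,
6×12 bins, 2e6 counts over 2700 s, OSEM 21/3 with the 4 mm filter, 15
CGLS iterations and 50 registration iterations per level — sizes chosen
so the whole study completes in minutes on one core while preserving
every algorithmic decision.  Unit tests use 32–48 px grids.

## Known limitations

* 2D only by default; the interfaces are dimension-agnostic but the 3D
  path is not exercised.
* The cardiac model of a contracting ring moves the epicardial plaque
  only weakly; the demonstrated motion benefit is respiration-dominated.
* Estimated models on undersampled bins carry ~0.3 px artefact-driven
  fields even at zero true motion, so the pipeline-level AVG/cr-MCIR
  identity holds to ~1%, not machine precision (the algebraic identity
  with an all-zero model does hold to 1e−6).
* CBR is intrinsically noisy at desk counts (its clinical
  between-patient SD was ±38% as well); the robust motion-compensation
  signatures are the TBR increase and the width decrease.
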