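# Methods

## Data model and coordinates

A dataset is a velocity field sampled on a regular grid: `data[x, y, z, t, c]`
in m/s, with voxel spacing in mm, a frame duration in s (the cycle length is
`n_frames × frame_duration_s`), a velocity-encoding limit (VENC, m/s), and a
boolean LA mask on the same grid. Voxel indices are 0-based; world positions
are `index × spacing` at voxel centers, in mm. The mitral-valve-opening frame
index splits the cycle into a systolic block `[0, mv_open_frame)` and a
diastolic block `[mv_open_frame, n_frames)`; both must be non-empty.
Grid sizes and frame counts follow typical atrial 4D-flow protocols
(~2.5–3 mm voxels, 20–30 frames, VENC 1.1–1.2 m/s); tests and examples use
smaller grids and frame counts chosen so each check isolates one property.

## Preprocessing chain

**Aliasing (VENC wrap).** Phase-contrast velocities live on a circle: a true
value v is stored as ((v + VENC) mod 2·VENC) − VENC. We adopt the half-open
convention (−VENC, +VENC] so wrap and unwrap compose exactly. Unwrapping is
temporal: per voxel and component, frames are scanned in order and whenever
the jump to the previous frame exceeds VENC, the multiple of 2·VENC that
minimizes the jump is added (up to `max_passes`, default 3). This recovers
any trajectory whose first frame is within the encoded range and whose
inter-frame jumps stay below VENC; spatial unwrapping is out of scope.

**Eddy currents.** Residual eddy-current fields add a slowly varying,
time-invariant velocity offset. We model it as a spatial polynomial (order 1,
affine, by default; order 2 available) fitted per component by least squares
to the *temporally averaged* velocity of designated static-tissue voxels —
the standard stationary-tissue assumption — and subtract the fitted surface
from every frame. The fit requires at least 10 static voxels per coefficient
and rejects rank-deficient static geometries (e.g. coplanar voxels for an
affine fit). Static-voxel selection on clinical data is an input, not
something this package infers.

**Denoising.** The denoise stage is Gaussian spatial smoothing (default
width 1 voxel, per frame and component) followed by a divergence-free
projection. The smoothing width is the package's main noise/resolution
trade-off: derivative-based biomarkers amplify velocity noise of SD σ_v into
vorticity noise of order σ_v/h (≈ 20 rad/s at σ_v = 0.05 m/s and h = 2.5 mm,
an order of magnitude above atrial vorticity scales), while coherent
structures at the vortex-core scale (≥ 4 voxels) lose only a few percent of
their vorticity to a 1-voxel kernel. Heavier smoothing (2–3 voxels) is
counterproductive on confined atrial-scale vortices: the boundary shell it
blurs is a large fraction of the LA volume.

**Divergence-free projection.** Blood is incompressible, so the velocity
field should be solenoidal; projecting onto the divergence-free subspace
removes the compressible component of the residual noise and enforces the
constraint the data should satisfy. The projection is a Fourier multiplier
v̂ ← v̂ − κ(κ·v̂)/|κ|² on the periodically extended grid, using the modified
wavenumbers κ_j = sin(k_j h_j)/h_j that diagonalize the central-difference
derivative. Consequences, by construction: the output's discrete central
divergence vanishes in the grid interior; the operator is exactly
idempotent; the mean (k = 0) flow is preserved; fields whose discrete
divergence is already zero — rigid rotation, uniform flow — pass through
unchanged; Nyquist modes, invisible to the central difference, are left
untouched. The periodic extension can introduce artefacts within a few
voxels of the grid boundary for fields with strong boundary-normal flow;
analysis masks should not touch the grid edge.

## Biomarkers

All gradients are central differences (one-sided at grid edges) with spacing
converted to metres; mask-boundary stencils may use out-of-mask voxels,
where velocity data exists, matching common practice.

* **Speed** = ‖v‖₂ per voxel/frame. Per-voxel temporal peak and mean are
  computed first; the global mean velocity is the mask average of per-voxel
  means. The global *peak* reduction is not uniquely standard: the default is
  the mask average of per-voxel temporal peaks (robust to single-voxel
  noise); the alternative — the maximum over all mask voxels and frames — is
  available via `peak_reduction="max"`.
* **Stasis** per voxel is n_stasis/N_tot, the fraction of frames with speed
  strictly below the threshold (default 0.1 m/s; strict `<` so counts are
  integer-exact and reproducible bit-for-bit). Global stasis is the mask
  average, a proportion in [0, 1].
* **Vorticity** is summarized as the volume-averaged |∇ × v| per frame
  (rad/s); its AUC over the cycle uses the rectangle rule (value × frame
  duration), exact for uniform-width frame bins.
* **λ2 vortex volumes.** λ2 is the middle eigenvalue of S² + Ω²; λ2 < 0
  marks pressure-minimum vortex cores (for rigid rotation at rate Ω,
  λ2 = −Ω² exactly). The vortex threshold is half the mean of the *negative*
  λ2 values over mask voxels and all frames, and a vortex voxel must be more
  negative than the threshold. Restricting the mean to negative values is a
  deliberate disambiguation: averaging all λ2 values (mostly ≈ 0 outside
  vortices) would drag the threshold toward zero and label nearly any weakly
  rotational voxel a vortex. Connected components use 26-connectivity
  (stated for determinism); the largest component per frame, times the voxel
  volume, gives the per-frame vortex volume, reported as cycle mean and
  within-block systolic/diastolic peaks. Frames with no vortex voxels
  contribute zero.

## Pathlines and flow patterns

Pathlines are integrated with classic RK4 through the time-varying field,
trilinear in space and linear in time (periodic over the cycle), released
from seed planes at each frame and carried to the end of one averaged cycle;
termination on grid exit or first mitral-plane crossing is recorded.
Pathlines leaving the grid within 2 steps are discarded as seeding
artefacts. RK4 is exact for uniform fields, and on a steady rotation the
endpoint error contracts ~16× when the step halves (4th order; the radius
drift alone contracts faster still, ~32×, because the leading per-step error
on a circular orbit is tangential).

Visual pattern reading is replaced by an explicit rule so contingency-table
analyses are computable: per phase (pathlines released in the systolic or
diastolic frame block), the winding angle about the mask-centroid axis is
accumulated per pathline; the call is **vortex** if the median winding is
≥ π and at least half the pathlines reach the mitral plane,
**short_range_vortex** if the rotation criterion holds but transport falls
short (reach fraction < 0.5), else **other**. Both thresholds are
configurable; π (half a turn at the median) separates circulating from
passing flow cleanly on the analytic phantoms, and 0.5 reach encodes
"most pathlines fail to reach the valve". The classification is
deterministic and invariant to pathline order.

## Reproducibility statistics

* **Within-subject CV (RMS method).** For paired sessions,
  CV = √[(1/n) Σᵢ (dᵢ²/2)/m̄ᵢ²], with dᵢ the pair difference and m̄ᵢ the pair
  mean — the two-replicate root-mean-square form; designs with more than two
  replicates per contrast are out of scope. The estimator is
  scale-invariant and zero iff every pair agrees.
* **Bootstrap inference.** Subjects are the resampling unit. CIs are
  percentile 2.5/97.5 over 1000 resamples by default (BCa was considered and
  not adopted: the plain percentile interval is the declared convention, and
  its coverage is verified by simulation). CV comparisons resample within
  each group independently (independent contrast) or draw subjects jointly
  carrying both pair sets (dependent contrast, preserving correlation;
  10000 resamples by default). Two-tailed p-values use the add-one
  correction 2·min(#{Δ* ≤ 0}+1, #{Δ* ≥ 0}+1)/(B+1), capped at 1. All
  procedures are seeded and bit-reproducible, and invariant to row order.
* **Agreement.** Bland–Altman bias ± 1.96·SD of differences (n−1
  denominator). The agreement power calculation follows the
  normal-approximation framework of Lu et al. (2016): the estimated limit
  d̄ ± 1.96·s has standard error s·√(1/n + 1.96²/(2(n−1))); agreement is
  declared when the 1−α/2 confidence bound of each limit lies inside the
  allowed difference δ, giving power Φ(τ₁) + Φ(τ₂) − 1 with
  τ₁,₂ = (δ ∓ d̄ − 1.96·s)/SE − z₁₋α/₂. At the design point used throughout
  (n = 74, d̄ = 0.01, s = 0.05, δ = 0.15, α = 0.05) the computed power is
  ≈ 98.8%, comfortably above the 90% design requirement; `ba_sample_size`
  inverts the formula by search.
* **ICC.** ICC(A,1) — two-way model, absolute agreement, single measures —
  from ANOVA mean squares: (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)),
  p from F = MSR/MSE. It penalizes systematic rater offsets (unlike the
  consistency form) and reduces to Pearson r in the no-bias, equal-variance
  limit.
* **McNemar.** Exact two-tailed binomial on the discordant counts when
  b + c < 25, chi-square with continuity correction otherwise (the
  switch point is declared, not canonical).
* **Correlations.** Pearson r with a stratified bootstrap CI (resampling
  within rhythm strata, preserving their sizes); Spearman ρ with average
  ranks for ties and t-approximate p; Bonferroni adjustment min(1, m·p).

## Synthetic data: what it emulates, what it does not

**Phantoms.** Closed-form primitives — uniform flow (zero curl), rigid
rotation (|∇ × v| = 2Ω, λ2 = −Ω²), Lamb–Oseen vortex (v_θ(r) =
Γ/(2πr)(1 − e^(−r²/r_c²)), peak vorticity Γ/(πr_c²)) — are sampled at voxel
centers, summed, scaled by a per-frame temporal profile (separable
space–time), and optionally confined by a smooth cosine taper in the
ellipsoid coordinate so velocity decays to zero outside the analysis mask
(no-slip-like) leaving a genuinely static background for eddy fitting. The
default phantom is a confined Lamb–Oseen vortex with Γ = 0.066 m²/s and a
10 mm core: peak speeds ~0.7 m/s and concentrated vorticity, representative
of trans-atrial flow, with VENC 0.6 m/s so the fastest frames alias.
Corruption defaults — Gaussian noise SD 0.05 m/s, cm/s-scale affine eddy
offsets with mm-gradients, wrapping on — are declared free parameters
(acquisition papers do not publish their raw artifact magnitudes) chosen to
be large enough that uncorrected data fails visibly. The phantoms do not
emulate atrial anatomy, pulmonary-vein inflow jets, turbulence, partial
volume, or MR physics (k-space sampling, phase noise structure); passing
tests demonstrate correctness of the operators and the corrections under
known ground truth, not clinical accuracy.

**Study simulator.** Each subject draws a true biomarker value from its
group (SR/AF) distribution; session values are true × (1 + η) with η drawn
at the session-level CV (rescan for scan1a/scan1b, interval for scan2 — the
interval value additionally scaled by 1 + hr_effect·ΔHR), and observer
readings multiply in reading-level error (intra for the two same-observer
reads of scan1a, inter for the second observer). The error model is
multiplicative because the CV is a proportional-error statistic. Because
stages layer, a measured contrast compounds the variances of the stages it
spans (e.g. the scan1a-vs-scan2 CV ≈ √[(cv_rescan² + cv_interval²)/2 + ...]);
parameter-recovery tests therefore activate one source at a time.
Non-positive draws are redrawn with a warning counter — a mild truncation at
the default group means/SDs (SR 0.35 ± 0.12, AF 0.55 ± 0.15, stasis-like
proportions; within-CV defaults 3/7/10/14% for intra/inter/rescan/interval;
HR effect −0.004 per bpm, i.e. a 10 bpm drop raises the biomarker ~4%).
Defaults were chosen once as plausible for an atrial flow cohort with
rhythm-dependent severity; they are inputs, not estimates.

## Numerical and scale choices

Simulation sizes in the tests (32³ default phantom grid, 8 frames; 200
replicates for CI coverage; 500 for null calibration at reduced 1000-sample
bootstraps) were chosen as the smallest sizes at which the targeted
statistical bands are stable across seeds. Bootstrap seeds derive from the
user seed via `numpy.random.default_rng`. Eigenvalues of S² + Ω² use
`numpy.linalg.eigvalsh` (the matrix is symmetric by construction). Degenerate
inputs fail loudly and early: empty masks, non-positive CV inputs,
mismatched subject sets, rank-deficient eddy designs, sub-4-voxel grids for
the projection.

## Known limitations

* Temporal unwrapping cannot recover a voxel whose *first* frame is aliased
  (e.g. a wrap induced purely by a static offset); such corruptions are
  outside its contract.
* The λ2 threshold convention ("half the mean negative λ2") is one of
  several in use; thresholds and the peak-velocity reduction are exposed as
  parameters precisely because field conventions differ.
* The pattern classifier is a proxy for visual reading; its thresholds are
  calibrated on analytic phantoms, not against human raters.
* The periodic projection assumes negligible boundary-normal flow at the
  grid edge; fields with strong through-plane flow at the volume boundary
  acquire local artefacts there.
* Regional analyses (e.g. appendage-specific flow) and multi-replicate
  (> 2 sessions) CV designs are not implemented.
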