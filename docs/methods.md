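# Methods

## Signal model

A voxel of a coherent white-matter tract is modelled as one axially
symmetric anisotropic tensor plus a discretised spectrum of isotropic
diffusion components:

S_k = S_0 [ f·exp(−b_k λ⊥)·exp(−b_k(λ∥−λ⊥)cos²Φ_k) + Σ_i w_i·exp(−b_k D_i) ]

with b_k the diffusion weighting of measurement k (stored in s/mm² as
printed on scanners, multiplied by 10⁻³ inside the exponentials so that
b·D is dimensionless when D is in µm²/ms), Φ_k the angle between the
k-th gradient direction and the fiber axis, and f + Σ w_i = 1 so all
compartment weights are signal-intensity fractions of S_0.  The
isotropic grid runs from 0 to the non-restricted limit in steps of
0.05 µm²/ms (61 points in vivo, 41 ex vivo); the step is chosen so the
0.6 µm²/ms restricted/non-restricted boundary falls exactly on a grid
point.  The spectrum is summarised by the restricted fraction
(D ≤ 0.6 µm²/ms, boundary inclusive) and the non-restricted fraction
(0.6 < D ≤ 3 in vivo, ≤ 2 ex vivo); any mass above the upper limit is
excluded from both bands, logged, and reported as `excluded_fraction`,
so the four parts always sum to one exactly.

Assumptions: a single coherent fiber population per voxel (appropriate
for pre-chiasmatic optic nerve; no crossing-fiber search), Gaussian
compartmental diffusion, no exchange, no relaxation weighting
differences between compartments.

## Acquisition schemes

Built-in designs mirror small-animal optic-nerve protocols: 25
measurements in vivo (one b = 0 reference plus 24 weighted directions,
max b = 2,200 s/mm²) and 99 ex vivo (1 + 98, max b = 3,000 s/mm²).
Weighted directions are laid out by antipodally symmetric electrostatic
repulsion on the hemisphere (seeded, deterministic, generated at call
time and cached); b-values cycle through four shells at 25/50/75/100 %
of the maximum, because the spectrum inversion needs several decay
scales.  b-values below 10 s/mm² are treated as b = 0 references, which
tolerates real-world bval files.  External data are read as NIfTI-1
plus FSL-style bval/bvec text.

## DTI fit

The comparison arm is a weighted log-linear least-squares single-tensor
fit (first pass OLS on log-signal, second pass weighted by the squared
predicted signal), eigen-decomposed in descending order.  AD is the
largest eigenvalue, RD the mean of the two smaller ones,
MD = trace/3, FA = sqrt(3/2 · Σ(λᵢ−MD)²/Σλᵢ²).  Negative eigenvalues
are not clipped; the voxel is flagged invalid instead, which preserves
diagnostic value.  Signals at or below zero are floored at 10⁻⁸ of the
voxel maximum before the log and flag the voxel.  Nonlinear least
squares was deliberately avoided: the log-linear fit is deterministic,
standard, and adequate at the simulated SNR.

Note: the published table this package's phantom is parameterised from
prints DTI MD values (≈ 0.19–0.24 µm²/ms) that are inconsistent with
(λ∥ + 2 λ⊥)/3 of its own printed DTI eigenvalues (≈ 0.6–0.7); the MD
convention used there is not stated.  This package computes MD strictly
as trace/3 and never asserts the printed MD.

## Spectrum inversion

Per voxel, the fit is a nested optimisation:

1. **Axis seed.**  The DTI principal eigenvector, sign-normalised to
   non-negative z (ties broken toward non-negative y, then x) so
   antipodal representations are unique.
2. **Diffusivity search.**  For a candidate (λ∥, λ⊥) the inner problem
   is non-negative least squares over the column basis [anisotropic
   signature at (λ∥, λ⊥, axis); exp(−b_k D_i) for every grid D_i].  The
   outer search is a coarse grid (default step 0.25 µm²/ms over
   λ∥ ∈ [0.1, 4], λ⊥ ∈ [0, 1.5]) followed by a compass (pattern) search
   with step halving down to 2·10⁻³ µm²/ms.  A compass search is used
   instead of a simplex method because NNLS active-set changes make the
   residual surface piecewise and simplex refinement stalls above the
   valley floor.  Ties break toward the lowest residual, then the
   smallest λ⊥, then the smallest λ∥, making the output deterministic.
3. **Axis refinement.**  The restricted/non-restricted split is
   sensitive to even sub-degree axis error (the DTI eigenvector seed is
   biased by ~0.5–1° on mixed voxels because the log-linear fit of a
   multi-compartment signal interacts with the discrete direction set),
   so the axis is refined by a compass search over tangent-plane tilts
   (2° down to 0.05°), alternating with the diffusivity search until
   the axis stops moving (at most 4 alternations).  This is the one
   place the implementation goes beyond a fixed DTI orientation; it is
   required to recover fractions to better than 0.03 on noise-free
   mixtures.
4. **Final solve and normalisation.**  At the selected optimum the
   inner problem is re-solved with a small ridge (Tikhonov) penalty on
   the isotropic weights — absolute weight
   `ridge_penalty · mean(signal²) / (K · n_iso)` with relative
   `ridge_penalty = 0.1` — which stabilises the near-collinear
   isotropic basis without noticeably biasing the band sums.  The
   penalty is excluded from the reported residual.  Weights are
   normalised by their sum, so fractions partition unity by
   construction.

The fiber compartment is constrained to genuine anisotropy,
λ∥ − λ⊥ ≥ 0.2 µm²/ms (`min_anisotropy`): a degenerate λ∥ = λ⊥ fiber
column duplicates an isotropic basis column, and because the fiber
column is ridge-exempt it would otherwise absorb isotropic mass (a pure
restricted voxel would fit as all fiber).  All tissue presets have
λ∥ − λ⊥ ≥ 0.44, so the constraint never binds on realistic tissue.  The
search phase ranks candidates by the unpenalised NNLS residual (the
ridge would only blur the ranking and doubles the solve cost).

The Gaussian least-squares objective is retained even though simulated
noise is Rician; at SNR ≥ 20 this is standard practice, and the
resulting bias is measured by the test suite rather than corrected.

## Phantom generator

The phantom emulates the longitudinal sham/TBI optic-nerve study the
analysis is designed for.  Ground-truth compositions per group ×
timepoint come from the published group tables (in vivo days 1, 3, 7,
30; ex vivo day 3).  Choices worth stating:

* **Renormalisation.**  The printed fraction triplets (fiber,
  restricted, non-restricted) sum to 0.84–0.97, not 1; what carries the
  remainder is not stated in the source.  Presets renormalise the
  triplet to sum to 1 (the model's fractions must partition the signal)
  and record the scale factor.  E.g. day-30 sham (0.81, 0.05, 0.06)
  becomes (0.880, 0.054, 0.065).
* **Two-delta spectrum.**  The isotropic ground truth uses two delta
  components, at 0.3 µm²/ms (restricted/cellularity) and 1.8 µm²/ms
  (non-restricted/edema), because the source reports only binned
  fractions; deltas on grid points make recovery unambiguous.
* **Between-animal variability.**  Each animal draws one z-score vector
  applied to all its timepoints (a coherent longitudinal trajectory)
  and shared by both eyes — which is what induces within-mouse eye
  correlation, with no explicit correlation matrix.  The per-metric
  draw SD is the printed group SD times sqrt(`animal_variance_share`).
  The share defaults to 0.15: the published SDs cannot be decomposed
  into biological and measurement components from the tables alone, and
  for inbred C57BL/6 mice scanned in sub-millimetre nerve ROIs most of
  the printed dispersion is plausibly measurement-level (coil loading,
  physiological noise, ROI placement, fit noise), which the simulation
  generates itself through Rician noise and fitting.  The share is a
  single config field; raising it toward 0.5 makes group contrasts at
  the published effect sizes markedly under-powered at n = 5 animals
  per group.
* **Noise.**  Magnitude (Rician) corruption
  S → sqrt((S+ε₁)² + ε₂²), ε ~ N(0, S_0/SNR), default SNR 30.  The
  sample mean at b = 0 matches the analytic Rician mean to < 0.5 %
  (tested against scipy.stats.rice).
* **Geometry.**  Each nerve is a compact disc of voxels in one axial
  slice; the voxel count is the drawn nerve volume divided by the voxel
  volume, rounded (0.14 mm³ → 41 voxels at the default reconstructed
  grid of 0.0586 × 0.0586 × 1 mm).  An acquisition-grid voxel size and
  a fixed `voxels_per_nerve` override are available.  A nerve volume
  below one voxel raises an error suggesting a voxel-size override.
* **Reproducibility.**  Everything derives from the single cohort seed;
  two runs with the same spec are bit-identical.

What the phantom does **not** emulate: anatomy and partial-volume CSF
contamination, eddy/motion artifacts, scanner drift, spatially varying
coil sensitivity, crossing fibers.  Tests passing on this phantom show
the inversion and statistics are correct for the assumed model and
noise; they do not certify performance on real data with those
confounds.

## Derived metrics and statistics

* ROI means ignore flagged-invalid voxels (count logged); the small
  central metric ROI and the larger whole-nerve ROI are distinct
  inputs, never inferred from one another.
* Nerve volume = voxel count × voxel volume; axon volume =
  nerve volume × fiber fraction, exactly multiplicative.
* Percent change is 100·(comparison − reference)/denominator with an
  explicit denominator convention (`reference`, `comparison`,
  `larger`), because the published percent-change statements flip
  conventions between cohorts; report output rounds to the nearest
  integer percent, halves away from zero.  Ten published contrasts
  reproduce exactly from the printed group means under these
  conventions; a few others (e.g. the in vivo day-30 radial-diffusivity
  and fiber-fraction changes) do not reproduce from the rounded printed
  means under any offered convention and were evidently computed from
  unrounded data, so they are not asserted.
* Pearson correlation returns (r, r², two-sided p) from the t transform
  with n − 2 degrees of freedom; constant input is rejected.
* Group comparisons use Welch's t-test per metric × day, and a
  fixed-effects two-way ANOVA (group × day, Type II sums of squares,
  statsmodels) on per-eye records.  The fixed-effects ANOVA is a
  deliberate simplification of a mixed model with eyes nested in
  animals; the phantom *does* induce within-animal correlation, so the
  anticonservatism of treating eyes as independent is visible in the
  outputs, and the stats CSV header carries a note to that effect.

## Desk-scale replication experiment

`run_day30_replication` re-enacts the day-30 comparison: per seed,
simulate a sham and a TBI cohort (5 animals × 2 eyes per group, SNR 30,
whole-nerve ROIs at the drawn nerve volume, ~35–41 voxels per nerve),
fit every voxel with both models, average maps over the ROI per eye,
and Welch-test the group contrasts.  Problem sizes (20 seeds, 5 animals
per group, one timepoint) were chosen as the smallest design that
exercises the full chain while keeping the experiment comfortably
reproducible on a single CPU.  Two summary rates are attached: the
fraction of seeds in which both day-30 contrasts (restricted fraction
up, λ∥ down) are directionally correct with p < 0.05, and the fraction
in which the DTI axial-diffusivity percent decrease exceeds the
spectrum-model decrease (the single-tensor confound).

## Numerical notes and edge cases

* All-zero signals, gradient-table/image length mismatches, rank-
  deficient DTI designs (< 6 independent directions) and schemes with
  fewer than 3 nonzero b-shells are rejected with descriptive errors.
* Voxels whose fit collapses (zero total weight) are flagged invalid
  and excluded from ROI means with a logged count.
* The compass searches are fully deterministic; identical inputs give
  bit-identical results, which the pipeline exploits to make CSV
  outputs byte-reproducible (each output is stamped with a hash of the
  computation-affecting configuration and the seed).
* Orientation sign convention: non-negative z, ties broken by
  non-negative y, then x.

## Known limitations

* Single fiber population per voxel; no crossing-fiber model.
* The inversion's regularisation and basis layout are this package's
  own explicit, reproducible defaults; no claim is made that they match
  any proprietary implementation.
* Fitted λ∥ carries an upward noise-induced scatter at SNR 30 on
  high-diffusivity tissue (the parallel high-b signal sits near the
  noise floor); ROI averaging over realistic nerve sizes is required
  for stable per-eye estimates.
* The fixed-effects ANOVA treats eyes as independent (see above); for
  real studies a mixed model is preferable.
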