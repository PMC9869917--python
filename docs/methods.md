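# Methods

## Model and assumptions

The pipeline treats a spatially registered multi-parametric MRI study as a
purely spectral problem: each voxel is a C-vector over the channels
[T1 pre-contrast, T1 max-contrast, T2, ADC, high-B DWI, k_ep, prob]
(C = 7 by default), and all inference is per voxel — no spatial filtering,
no through-slice processing.  Slice spacing (6 mm by default) is carried
as metadata only.  Slices are stitched side-by-side along the column axis
into one mosaic; stitching is a pure re-layout, so pooled statistics are
unchanged (this is asserted by test).

Normal prostate tissue is modelled as multivariate Gaussian with mean μ
and covariance Σ estimated from the voxels of a normal-tissue mask.  Under
that model the RX score (x−μ)ᵀΣ⁻¹(x−μ) is χ²_C; real tissue is not
Gaussian, which is precisely why the scored maps are evaluated by ROC
sweep rather than by a fixed χ² cutoff.

The normal-tissue mask used for statistics is the prostate outline minus
the known lesion mask when one is available (phantom truth, or a supplied
tumor mask), otherwise the full prostate outline.  Both modes are
supported (`RunConfig.exclude_tumor_from_stats`).

## Covariance conditioning

The sample covariance of a few thousand voxels in 7 channels is accurate
in its leading eigenvalues and noisy in its trailing ones — exactly the
part the inverse amplifies.  Five routes are implemented:

- **unprocessed** — eigendecomposition-based full inverse; refuses
  matrices whose smallest eigenvalue is below 1e-12·λ_max (the global
  singularity tolerance).
- **delete_pc(k)** — discard the k smallest-eigenvalue components and
  score with the rank-(C−k) pseudo-inverse Σ_retained vᵢvᵢᵀ/λᵢ.  RX then
  equals RX computed in the retained whitened subspace (tested against
  that oracle).  Which components are "noise" is decided purely by
  eigenvalue order.
- **regularized / modified_regularized** — CM(γ) = (1−γ)Σ + γD with
  D = diag(Σ) or D = (tr Σ/C)·I respectively; these are the two canonical
  diagonal shrinkage targets.  γ is selected on the fixed grid
  {0.00, 0.05, …, 1.00} by 5-fold cross-validated mean Gaussian
  log-likelihood of held-out background voxels (deterministic interleaved
  folds; ties go to the smaller γ; non-positive-definite candidates score
  −∞).  On a well-sampled exact-Gaussian background γ* = 0, so the
  shrinkage routes coincide with the unprocessed inverse there — they
  differ only for scarce or contaminated data, which is the regime they
  exist for.
- **evm** — elliptical volume minimization: each of `trials` (default 100)
  seeded trials drops a random 10% of the masked voxels and records the
  covariance of the rest with its ellipsoid volume ∝ √det; the
  minimum-volume subset wins.  "Sequential removal" is implemented as
  independent random trials (rather than iterative refinement, which the
  description leaves open); the recorded minimum is non-increasing in the
  trial count for a fixed seed stream.

All conditioned operators are symmetric PSD, so RX ≥ 0 always.

## Detectors

RX is as above.  ACE is the squared whitened cosine between (x−μ) and
(s−μ) where s is the in-scene signature, the channel-mean over a seed
region (the lesion mask in phantom runs); it is bounded in [0,1] by
Cauchy–Schwarz and invariant to positive scaling of (s−μ).  With a
rank-deficient delete-PC operator, both vectors are implicitly projected
onto the retained subspace, which preserves the bound; this pairing is an
extension beyond the usual full-rank ACE and is flagged in the map
metadata.  By default ACE uses the unprocessed statistics.  Voxels with
zero whitened norm score 0 by convention; unscored voxels carry −1, a
value impossible for either detector.

## DCE washout

Post-peak signal is modelled as A·exp(−k_ep·(t−t_peak)).  The peak time is
the argmax of the curve (ties to the earliest sample; all-constant and
end-peaked curves are flagged).  The fit window is strictly after
max(t_peak, 50 s) and needs ≥ 4 samples.  Non-positive intensities are
floored at half the smallest positive curve value before logs.  The
estimator is a weighted log-linear regression (weights y², the exact
linearization for additive noise) followed by a nonlinear least-squares
refinement of (A, k_ep) in the intensity domain with that deterministic
starting point; plain unweighted log-regression was rejected because it
over-weights the near-zero tail (measured relative RMSE 24% at SNR 20
versus ~6% for the implemented estimator, against a Cramér–Rao bound of
5–7% under the default sampling).  k_ep is clamped at 0.  "prob" is the R²
of the fitted exponential clamped to [0,1] — a bounded fit-quality
surrogate chosen because the original probability-likelihood image is
defined in work not restated here; its exact form remains an open choice.

## Color reference

The RGB display maps washout → red, high-B DWI → green, ADC → blue, each
robust-stretched to [0,1] by its (2%, 98%) percentile window over prostate
voxels.  The archetypal lesion — fast washout, restricted diffusion (high
DWI, low ADC) — therefore renders yellow.  sRGB → CIELAB uses the standard
D65 conversion (via scikit-image, validated against independently computed
corner values).  Yellowness is b*/b*_yellow with b*_yellow = 94.478 (pure
sRGB yellow), clamped to [0,1], so the 0.35 mask threshold is
dimensionless.  Mask thresholds are inclusive (≥) everywhere.  The mapping
is configurable (`ChannelColorMap`); an earlier candidate with a
tumor-bright channel on blue renders lesions white and was rejected.

## Evaluation

ROC sweeps run inside the prostate mask only.  Positive calls are
score ≥ threshold; ties share one threshold; AUC is trapezoidal and equals
the Mann–Whitney two-sample statistic (tested exhaustively).  The Youden
index is reported as maximum balanced accuracy (sens+spec)/2 — so chance
performance reads 0.5, directly comparable to AUC — with the classical
J = sens+spec−1 alongside; cohort tables report means with standard errors
s/√n over cases.

## Phantom generator

The phantom emulates the minimal structure the pipeline assumes: a filled
ellipse covering ~50% of each slice stands in for the organ outline;
background voxels are i.i.d. draws from a 7-channel Gaussian whose default
covariance couples the diffusion pair (ADC vs high-B DWI, ρ = −0.6), the
DCE pair, and the two T1 channels; lesions are discs whose channel means
are shifted by a signature; gross outliers (modelling
acquisition/registration artifacts, excluded from the tumor mask) are
displaced 10 channel-SDs along random directions.  DCE curves rise
linearly to a per-voxel amplitude A ~ U(1,2) at t_peak = 60 s (sampled
every 10 s to 300 s) and decay at the voxel's k_ep, which is tied to the
spectral k_ep channel so the two views of washout agree.  The default
lesion signature raises T1max, DWI, k_ep and prob and lowers T2 and ADC,
scaled to Mahalanobis length 4.5 — chosen for clear separability (the
voxel-level ROC between χ²₇ and noncentral χ²₇(λ=L²) has AUC ≈ 0.985 at
L = 4.5, and ≈ 0.88 at L = 3, a hard ceiling no estimator can beat).  All
randomness flows from one integer seed; identical specs give
bit-identical output.

What the phantom does **not** emulate: anatomy (organ shape, zonal
structure), MR physics (bias fields, Rician noise, partial volume),
non-Gaussian tissue heterogeneity, and registration error beyond the
gross-outlier model.  Green tests therefore establish the correctness and
calibration of the algorithms under the model's own assumptions — not
clinical detection performance, which in real cohorts is bounded by
exactly the violations listed above.

## Problem sizes and numerics

Default study sizes: 64×64 slices × 3 (≈ 6,100 prostate voxels per case),
26-case cohorts for summary tables, 10⁵ voxels for the χ² calibration,
200 EVM trials for robustness checks.  Eigenvalues below 1e-12·λ_max are
treated as zero everywhere; conditioned operators are symmetrized to
cancel round-off; CSV outputs are written with fixed float formatting so
identical configurations reproduce identical bytes.
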