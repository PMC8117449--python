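# Methods

This note documents the models, numerical choices, and simulation design
behind `fetdki`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Diffusion kurtosis estimation (`fetdki.dki`)

**Signal model.** The multi-shell diffusion signal follows the cumulant
expansion `ln S(b, n) = ln S0 − b nᵀDn + (b²/6) MD² W(n)` with the rank-4
kurtosis tensor W represented by its 15 unique elements and
`W(n) = Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ`. Units: b is accepted in s/mm² (FSL `.bval`
convention) and converted internally to ms/μm², so b = 1000 s/mm² → 1.0 and
diffusivities come out in μm²/ms. The linearized design matrix has 22
columns (ln S0, 6 D elements, 15 elements of MD²·W); identifiability needs
at least two nonzero shells and 15 non-collinear directions, which is
checked as a rank-22 condition. The default simulated protocol is the
two-shell scheme b = 0/1000/2500 s/mm², 30 directions, 2 mm isotropic
voxels.

**Fitting.** A weighted least-squares fit of the log signal (weights =
signal, the first-order variance stabilization) initializes; nonlinear least
squares on the exponentiated model (Levenberg–Marquardt, analytic Jacobian,
tolerance 1e−8 on cost/step, ≤400 evaluations) refines it. Constraints are
applied by post-hoc projection, not constrained optimization: D is made
positive semidefinite by eigenvalue clipping at zero, and the directional
apparent kurtosis is clipped to [0, 3] when metrics are evaluated —
consistent with the downstream histogram truncation to [0.4, 1.2]. Voxels
with MD below 1e−6 μm²/ms (e.g., constant signal) are flagged degenerate
and their kurtosis set to zero.

**Rician noise handling.** Magnitude MRI noise is Rician; in signal-free
background the magnitude is Rayleigh(σ), and σ is estimated by its maximum-
likelihood form `sqrt(mean(M²)/2)`. Signals are corrected with the
power-images estimator `sqrt(max(M² − 2σ², 0))`; measurements floored to
zero are excluded from fitting and counted in the fit report. Because the
square root re-introduces a downward bias where the corrected value is
small, the NLLS refinement weights each residual by the delta-method
standard deviation of the corrected signal (∝ corrected/raw magnitude);
this keeps the lesion-median MK within a few percent of truth at S0-SNR 25
(verified by a seeded test).

Two subtleties, found by simulation and encoded in the tests:

- *Gaussian limit.* With W = 0, the [0, 3] kurtosis clip gives single-voxel
  MK an irreducible positive offset of order the per-voxel kurtosis noise.
  The near-zero-MK property (|MK| < 0.02) therefore holds when every
  measurement — including the strongly attenuated b = 2500 shell — keeps
  per-measurement SNR ≥ 50, and that is the condition the test implements.
- *Direction of the bias-correction benefit.* On raw magnitudes the noise
  floor inflates apparent kurtosis; the correction removes that inflation.
  The paired-replicate test demonstrates this with the log-domain (WLS)
  estimator, which isolates the floor effect. For the unweighted magnitude
  NLLS estimator at SNR 25, the floor inflation and the estimator's own
  downward bias can fortuitously cancel, so the comparison is not monotone
  there; this is a property of the estimator, not of the correction.

**Scalar metrics.** MD/AD/RD come from the ordered eigenvalues (AD = λ₁,
RD = (λ₂+λ₃)/2). AK is K along the principal eigenvector; RK averages K
over 64 equally spaced perpendicular directions (trapezoid rule on a
π-periodic smooth function, effectively exact). MK integrates K(n) over the
sphere with a Gauss–Legendre (cos θ) × uniform (φ) product rule, 24 × 48
nodes by default: for the smooth rational integrand this is converged to
machine precision and rotation-invariant at the 1e−15 level, which a
quasi-uniform point set of practical size is not (a 250–2000 point
Fibonacci design plateaus near 1e−4 quadrature error). A Monte-Carlo
directional average is kept as the independent oracle in the tests.

## PET metrics (`fetdki.pet`)

Inputs are dynamic frames in SUV (or any scale — all TBR quantities are
scale-invariant) with the 16-frame schedule 5×1, 5×3, 6×5 min over 50 min.
The summed 20–40 min image is a duration-weighted mean with partial frames
weighted by overlap. Background is the mean SUV of a user-supplied (or, for
phantoms, auto-generated contralateral) healthy-brain mask. Derived
quantities:

- **TBRmean**: mean TBR over the 8-connected supra-threshold (≥1.6) region
  in the axial slice holding the global TBR maximum.
- **TBRmax**: a 1.6 cm diameter circle centered on the hottest voxel of the
  summed image; the circle's mean SUV divided by background is the default
  (`stat="mean"`), with the circle's maximum available as an option. The
  defining description of this quantity is ambiguous between the two; the
  mean is implemented as primary because the circle otherwise has no effect.
- **3D ROI**: 26-connected component of {TBR ≥ 1.6} containing the seed.
- **TAC**: per-frame mean in a 1.6-cm-diameter sphere (≈2 ml; 257 voxel
  centers at 2 mm isotropic) centered on the hottest voxel. TTP is the
  mid-time of the first frame attaining the maximum (ties → earliest);
  slope is the OLS slope of SUV against frame mid-time over 20–50 min,
  ×60 to SUV/h.

Peak localization runs on a lightly Gaussian-smoothed copy of the summed
image (1 voxel default, 0 disables): on a noisy plateau the literal argmax
is an arbitrary rim voxel, which would drag the circle and sphere half into
background; clinical PET is intrinsically smooth, so the smoothed locator
matches practice. All reported values use unsmoothed data. Membership of
circles and spheres is by voxel-center inclusion; voxel indices are 0-based
and inputs are assumed co-registered on a common grid (no resampling).

## Histogram features (`fetdki.histogram`)

Within the PET-defined 3D ROI, each metric map is truncated to its
physiological range — 0.5–3.5 μm²/ms for diffusivity maps, 0.4–1.2 for
kurtosis maps, both ends closed — and summarized by the arithmetic mean and
centiles: C5/C10 for diffusivities, C90/C95 for kurtoses, 18 variables per
patient. Relative-frequency histograms (volume-normalized, i.e., counts
divided by in-range voxel count) are built on a fixed bin grid and smoothed
with a centered moving average spanning 0.14 μm²/ms (DT) or 0.04 (KT); bin
width defaults to window/7 so the smoother covers exactly 7 bins, and the
smoothed histogram is renormalized to unit sum. Centiles are computed on
the raw truncated voxel values with the linear-interpolation quantile
convention (numpy default) rather than from the smoothed histogram:
voxel-level quantiles are reproducible and bin-width-independent, while the
smoothed histogram is retained for display. Normalization to contralateral
white matter is deliberately omitted. A metric with zero in-range ROI
voxels yields NaN features and a log entry, not an error.

## Group statistics and the index (`fetdki.stats`)

- **Mann–Whitney U** with midrank ties; exact two-sided p by enumeration of
  all group assignments when n₁+n₂ ≤ 12 (valid under ties), otherwise the
  normal approximation with tie and continuity corrections.
- **Multiplicity**: Bonferroni per family — α/18 for the DT/KT variables,
  α/4 for the PET parameters — with the three-way reporting categories
  "significant", "significant prior to correction" (α/m < p ≤ α), and "not
  significant".
- **ROC**: empirical AUC (ties ½), identical by construction to U/(n₁n₂).
  The optimal cutoff maximizes Youden's J over ">c" criteria, ties broken
  toward higher specificity; markers where lower values indicate
  progression (diffusivities) are auto-oriented and the orientation
  reported. The p-value against AUC 0.5 uses the DeLong variance; the 95%
  CI uses Clopper–Pearson bounds on the concordant-pair proportion (the
  "exact binomial" convention; it understates pair dependence and is
  reported for comparability, not inference).
- **DeLong comparison** of paired markers via placement-value covariance.
- **Logistic models**: maximum likelihood through statsmodels' Newton/IRLS
  (tol 1e−8, ≤100 iterations). Complete/quasi-separation — statsmodels'
  detection, a singular Hessian, or a coefficient norm above 1e3 — is
  flagged on the result rather than raised; accuracy is reported at
  predicted probability 0.5. Multivariate presets: (MK C90, TBRmax),
  (MK mean, TBRmax), (MK mean, MK C90, TBRmax).
- **FET–DKI index**: 4.7·TBRmax + 39.2·MK C90 with the strict ">41" call.
  The published description of the weights swaps their pairing in one
  place; the assignment implemented here (4.7 on TBRmax) is the only one
  consistent with the 41 cutoff and the scales of the two markers, whose
  group medians then straddle the cutoff.

The screen runs ROC/logistic analysis on Bonferroni-significant features by
default (`roc_on="prior"` widens to pre-correction hits).

## Synthetic data (`fetdki.phantom`, `fetdki.cohort`)

**What is emulated.** The phantoms reproduce the acquisition geometry (two
shells, 30 directions, 2 mm voxels; 16 PET frames over 50 min), the
tissue-level contrast that drives the method (lesion MD/MK and TBR/TAC
targets set to group medians of the reference cohort), Rician DWI noise and
Gaussian PET noise, and exact ground truth for parameter-recovery testing.
The lesion is a homogeneous sphere inside an ellipsoidal "brain" of
white-matter-like tissue (eigenvalues 1.7/0.4/0.4 μm²/ms, constant
directional kurtosis 0.9 via W = K·sym(D⊗D)/MD²).

**What is not.** Anatomical structure, lesion heterogeneity (so centiles sit
near means), partial-volume effects beyond the hard sphere boundary, motion
and eddy-current artifacts, and scanner reconstruction. Passing tests
demonstrate correctness of the computational chain under the stated model,
not clinical performance on real data.

**PET TAC construction.** The lesion TAC is built directly on the frame
grid: late frames (mid-times 20–50 min) sit on a line with the requested
slope plus a peak perturbation orthogonal (in the OLS sense) to {1, t}, so
the fitted late slope is exact by construction; the bump height is the
larger of a quarter of the plateau level and the minimum needed for the TTP
frame to dominate strictly. Early frames follow a gamma-variate-like rise
kept below the peak. Only TTP, late slope, and the 20–40 min mean (which
sets the TBR target) are contractual; the rise shape is cosmetic.

**Feature-level cohorts.** Each of the 22 features gets a marginal
parameterized by the published group median and IQR: log-normal for the
positive, right-skewed quantities (σ = asinh(IQR/2m)/z₀.₇₅, exact
median/IQR match), normal for the late slope, which can be negative.
Printed quartile pairs in reversed order are sanitized by sorting.
Dependence uses a hierarchical Gaussian copula: one latent score per metric
(MD, RD, AD, MK, RK, AK, and the four PET parameters), correlated 0.4
within a tensor family and 0.3 between the MK metric and TBRmax — invented
defaults, exposed in `CorrelationSpec`; the reference study reports no
patient-level correlations. A metric's features load on its score with
weight √within_metric, making the feature-level correlation matrix positive
semidefinite by construction. The default within-metric loading is 1
(comonotone): a flat 0.8 within-metric correlation forces frequent
isotonic re-sorting to honor the per-patient ordering contract
(C5 ≤ C10 ≤ mean for diffusivities, mean ≤ C90 ≤ C95 for kurtoses), and
that sorting measurably distorts the calibrated medians; with comonotone
scores the ordering holds almost surely because the marginals' quantile
curves do not cross in the relevant range, and calibration is preserved.
The ordering projection (ascending sort per triple) remains as a safety
net and is the reason the identity-correlation configuration shows small
within-triple dependence when enforcement is left on.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline derives per-patient seeds from a
`SeedSequence`, and identical configs reproduce artifacts bit-identically.
The test suite runs phantoms at ~20³–32³ grids with lesion radii 5–10 mm,
cohort calibration at 10 000 patients per group, the Monte-Carlo kurtosis
oracle at 4×10⁵ directions, and the permutation null at 120–150 replicates
of a 32-patient screen — sizes chosen so each property is measured with
comfortable Monte-Carlo margin on a single CPU.

## Known limitations

- Exact numerical agreement with the reference study's proprietary
  processing chain (ExploreDTI fitting settings, PMOD segmentation) is not
  claimed; the published per-patient results are not reproducible without
  the original images.
- The 2D auto-contour is evaluated on the single axial slice containing the
  global TBR maximum; whether the original analysis repeated it per slice
  is not documented.
- The exact-binomial AUC confidence interval treats concordant pairs as
  independent and is therefore approximate.
- Histogram centile conventions (bin width, quantile interpolation) are not
  documented in the reference analysis; the choices here are stated above
  and exposed in `HistogramSpec`.
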