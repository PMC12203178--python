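# Methods

`nigraq` re-implements, as a tested pipeline, the image-reconstruction and
statistical machinery used to track iron accumulation in the substantia
nigra (SN) of people with early Parkinson's disease (PD) and isolated REM
sleep behaviour disorder (iRBD): quantitative susceptibility mapping (QSM)
and R2\* relaxometry of multi-echo gradient-echo MRI, extraction of nigral
territory means, and a longitudinal mixed-model analysis of a three-visit
cohort. Because no subject-level data are distributable, the package ships a
digital midbrain phantom and a synthetic cohort generator that reproduce the
*statistical structure* the analysis assumes; they are first-class, tested
code, not fixtures.

## Forward model and phantom

Susceptibility χ (in ppm of B0) induces a B0 field shift through the dipole
convolution, evaluated in Fourier space:

    f(r) = F⁻¹[ D(k) · F[χ] ],   D(k) = 1/3 − k_z²/|k|²,   D(0) := 0,

with k_z the spatial-frequency component along the B0 axis. The grid is
zero-padded two-fold per axis before the FFT to suppress circular
wrap-around of the long-range dipole field. Two consequences of
discretization matter for validation and are deliberate:

* A spatially uniform χ produces zero field only under circular convolution
  (the D(0)=0 convention); under padding a uniform block is a finite cube
  and correctly acquires its shape's demagnetizing field.
* The voxel impulse response of the k-space-sampled kernel differs from the
  continuum point dipole (the aliased lattice sum of an r⁻³ field is not
  negligible); correctness is therefore asserted against (a) a dense-FFT
  kernel oracle, exact to 1e−10, and (b) the closed-form uniform-sphere
  solution, which the discrete field matches to <5% at r ≥ 2a.

The phantom places bilateral SN ellipsoids (split into anterodorsal,
posterodorsal, anteroventral and posteroventral territories by the
red-nucleus rule below), subthalamic nuclei and red nuclei inside an
ellipsoidal brain mask, on a ≥32³ grid (64³ default for validation runs,
32³ for the demo pipeline — sizes chosen so a full round trip runs in tens
of seconds on one CPU). Two value presets exist: a healthy-like class and a
Parkinson-like class whose posteroventral χ is raised the most, mirroring
the ventral-to-dorsal gradient of early nigral degeneration. Background
susceptibility sources (air-cavity-like Gaussian blobs, amplitude a few
ppm) sit strictly outside the brain with a two-voxel standoff emulating the
skull/CSF gap; this keeps their field harmonic on the eroded brain
interior, which is what background removal assumes.

The complex signal per voxel is `S(TE) = M0·exp(−R2*·TE)·exp(i(2πf·TE+φ0))`
with `f[Hz] = γ̄·B0·f[ppm]·1e−6`, γ̄ = 42.577 MHz/T and B0 = 3 T by default
(both configurable). Echo times default to 8 echoes, TE1 = 3 ms, ΔTE = 4 ms,
bracketing nigral T2\* ≈ 20–40 ms. Noise is circular complex Gaussian per
channel, so magnitudes are Rician.

## Field fitting

`fit_complex_field` fits the 4-parameter complex model per voxel by damped
Gauss–Newton (vectorized over voxels), initialized from magnitude
log-linear regression (M0, R2\*) and the amplitude-weighted mean of
echo-to-echo phase differences (f, i.e. temporal unwrapping; φ0 from the
first echo). With *exactly uniform* echo spacing the map
`f → f + m/ΔTE, φ0 → φ0 − 2πm·TE1/ΔTE` is an exact symmetry of the model,
so frequency is identifiable only within a 1/ΔTE-wide band; the fit breaks
ties toward the band of the phase-difference estimate (the standard
convention, adequate for nigral fields ≤ ~60 Hz at the default ΔTE).
Voxels whose relative residual stays high are re-fit from aliased starts,
which genuinely recovers wrapped frequencies whenever echo spacing is
non-uniform. Fitted R2\* is clamped to [0, 1000] Hz with a flag; all-zero
voxels are masked out rather than raising.

## Background removal (Laplacian boundary value)

Fields from sources outside the brain are harmonic inside it. The
background is estimated by solving the 7-point finite-difference Laplace
equation on the mask interior (largest connected component, eroded by one
voxel) with Dirichlet boundary values taken from the total field, via
conjugate gradients (relative tolerance 1e−6, ≤10⁴ iterations;
non-convergence is an error carrying the residual norm). The local field is
`total − background` on the solved region. The intrinsic bias — the
harmonic extension of the *internal* field's boundary values is also
removed — is <0.5% RMS for sources away from the boundary, and a second
application changes an already-local field by <0.1% RMS.

## Dipole inversion (morphology-enabled, L1)

`invert_dipole_medi` minimizes

    Σ_a ‖M_a ⊙ ∇_a χ‖₁ + λ‖W ⊙ (D∗χ − f)‖₂²,

where W is the magnitude weight normalized to unit mean, and M_a keeps the
(1 − edge_fraction) smallest magnitude-gradient voxels per axis, so χ edges
are penalized except where the anatomy has edges. Defaults λ = 1000 (fields
in ppm) and edge_fraction = 0.3 follow common practice for this inversion
family. The ε-smoothed L1 (`√(|∇χ|²+ε)`, ε = 1e−6, an effective gradient
floor of ~10⁻³ ppm) is solved by iteratively reweighted least squares; each
outer iteration solves the reweighted normal equations by matrix-free
conjugate gradients with the padded-FFT dipole operator (self-adjoint).
Outer stop: relative objective change <1e−3 or 50 iterations; a rising
objective for 5 consecutive outer iterations raises with the trace. The
dipole kernel's zero cone makes the data term blind to cone-concentrated χ
components (verified: forward power of a cone component is <1% of its
norm); the gradient penalty resolves this null space, which is what the
round-trip tolerance certifies. No susceptibility referencing is applied by
default (no reference region was used in the analysis this mirrors); a
reference-region offset is available but off.

On the noiseless 64³ phantom the full chain (field fit → LBV → MEDI)
recovers each SN-subdivision ROI mean within 10% (typically 1–6%, the
residual being regularization shrinkage concentrated at structure edges)
with voxelwise correlation >0.99 against truth.

## R2\* relaxometry

`fit_r2star` fits `|S|(TE) = M0·exp(−R2*·TE)` per voxel by Gauss–Newton,
initialized by weighted log-linear regression — mono-exponential, no Rician
noise-floor term (midbrain SNR at 3 T is high enough that the plain model
is adequate, and the source analysis specifies plain nonlinear fitting).
The nonlinear fit weights errors in signal space and therefore carries
less low-SNR bias than the log-linear estimator (verified by Monte-Carlo at
SNR 10–40). Voxels with fewer than 3 echoes above 3× the estimated noise SD
are flagged low-confidence rather than dropped. The complex-model fit's
R2\* is exposed separately (`r2star_from_fieldfit`) and cross-checked
against the magnitude fit (noiseless agreement <0.1%, r > 0.95 at SNR 15).

## Nigral territories

Given whole-SN masks per hemisphere and a red-nucleus mask on one grid
(axis order: left-right, anterior-posterior with posterior at larger index,
inferior-superior with inferior at smaller index — validated, never
guessed): the dorsal SN comprises axial slices at or above the lowest
red-nucleus slice, the ventral SN the slices inferior to it; within each,
anterior/posterior splits at the midpoint of the hemisphere SN's own
anterior–posterior voxel extent (image axis, not the oblique long axis of
the SN; midpoint ties go posterior). The four territories must partition
each hemisphere's SN exactly — enforced, with empty subdivisions named in
the error. ROI statistics report per-hemisphere mean/SD/count and a
left-right averaged value computed as the mean of hemisphere means (equal
hemisphere weight, not voxel pooling, since hemisphere voxel counts
differ). Label maps are resampled through displacement fields
nearest-neighbour (labels stay categorical); continuous maps would use
linear interpolation. The percentage rate of change is
`(x_final − x_initial)/x_initial × 100`.

## Synthetic cohort

Per region and modality, a subject's value at follow-up time t (years) is

    y = μ[group] + b_subject + slope[group]·t + β_age·(age − mean age)
        + β_sex·1[male] + ε,    b ~ N(0, σ_b²),  ε ~ N(0, σ_e²).

Shipped defaults are paper-derived: visit-1 group sizes 44/49/127
(HV/iRBD/PD) with attrition to 36/20/88 and 28/11/50; visit intervals
2.1 ± 0.2 y and 2.2 ± 0.4 y; group ages 62.3 (9.7), 67.7 (5.0), 62.3 (9.0)
years truncated to [18, 80]; male proportions 0.545/0.878/0.598; per-ROI
QSM means/SDs from the published visit-1 table; annual slopes zero except
the PD posteroventral slope (0.0026 ppm/y for QSM, 0.292 Hz/y for R2\*).
R2\* group means/SDs are *derived* from printed contrasts (25.4/26.2/27.2
Hz, SD 3.4) since no R2\* group table is printed; the male–female R2\*
offset is +1.4 Hz. Where nothing is stated, realistic choices were fixed
once: the cross-sectional SD splits 80%/60% into between-subject and
residual components (σ_b = 0.8·SD, σ_e = 0.6·SD); QSM and R2\* of the same
region share correlated intercepts and residuals (ρ = 0.88, the printed
cross-modality correlation); hemispheres decompose the subject-visit value
symmetrically (L = y + d/2, R = y − d/2) with d scaled to give an
inter-side correlation of 0.85 (printed range 0.71–0.93) — so the reported
left-right average equals the latent value exactly and the design moments
are exact for the `side == "mean"` rows. Optional covariates (disease
duration, a neuromelanin volume index, a striatal DaT binding ratio) are
drawn with fixed correlations to the posteroventral-QSM subject deviate
(+0.31, −0.25, −0.25, matching the printed correlation magnitudes).
Attrition is a nested random subset, missing completely at random.

What the generator does *not* emulate: real anatomy beyond ellipsoids,
motion/flow artefacts, multi-channel coils, scanner drift, informative
dropout, or phenoconversion of iRBD subjects. Passing tests therefore
certify the estimation and inference machinery under the assumed model, not
robustness to violations of it.

## Statistics

* **Baseline**: per ROI, OLS of `value ~ Group + age + sex` at visit 1;
  group effect by partial F-test; pairwise contrasts on estimated marginal
  means (covariates at sample means, where contrasts reduce to coefficient
  differences) with Tukey adjustment via the studentized-range law. For two
  groups the adjusted p is computed as the exact t-test p (the k = 2
  studentized-range law collapses to it; this avoids quadrature error).
  Percent differences versus HV reuse the percentage-rate-of-change code.
* **Longitudinal**: REML random-intercept mixed model with fixed Group,
  Visit (years since baseline), Group×Visit, baseline age and sex, fitted
  with statsmodels (the response is standardized internally for optimizer
  conditioning and estimates transformed back; optimizers are tried in the
  order lbfgs/bfgs/powell because lbfgs occasionally walks into singular
  covariances). Subjects with a single visit are excluded and counted.
  Type-II Wald χ² respects marginality: Group and Visit are tested in the
  additive model, the interaction in the full model. Per-group slopes are
  linear combinations of the full model's coefficients with delta-method
  SEs and Wald-normal 95% CIs (a Satterthwaite small-sample correction is
  out of scope; at these sample sizes the normal approximation is the
  convention the source analysis used). Slope contrasts are
  Tukey-adjusted.
* **Correlations**: Pearson r with the t-transform p, Benjamini–Hochberg
  adjustment within each declared family; zero-variance or n<3 pairs are
  reported undefined and excluded from the family size. Leave-one-out
  influence reports the point whose removal changes r the most. (Note the
  BH-adjusted values are monotone and dominate raw p but are not idempotent
  under re-adjustment — no step-up adjustment is.)
* **Symmetry**: exact Wilcoxon signed-rank for ≤25 nonzero pairs, computed
  by dynamic programming over doubled midranks (equivalent to enumerating
  all 2ⁿ sign assignments, valid with ties); zeros dropped; normal
  approximation with continuity and tie correction above n = 25. Pearson r
  between hemispheres accompanies it.
* **Demographics**: classic one-way ANOVA by default with a Welch option
  (the choice is recorded per variable), Tukey HSD pairwise; k-group
  chi-square with Holm-corrected (or Bonferroni) pairwise 2×2 tests;
  expected counts below 1 trigger a warning recommending an exact test.

Calibration is verified by simulation at the study's sample sizes: over
2000 matched-null cohorts the baseline F-test and each Wald test reject at
a rate inside the binomial 99% band of α = 0.05, and over 200 cohorts at
the default (alternative) design the PD-slope 95% CI covers the generating
value ≥90% of the time with all fixed-effect biases below 5% of the
cross-sectional SD.

## Pipeline and demo sizes

`run_pipeline` has an imaging arm (per-subject phantoms from the two value
classes → reconstruction → ROI table → baseline model) and a cohort arm
(synthetic cohort → mixed models, correlation family, demographics), with
CSV/JSON outputs and a manifest of config hash, seeds and checksums. The
imaging demo reconstructs subjects at baseline only and uses a small
between-subject χ jitter (0.005 ppm): it is a fidelity/plumbing
demonstration of the reconstruction chain, not a power study — power at
realistic between-subject SDs (~0.03 ppm) is what the cohort-arm
simulations measure. Demo problem sizes (32³ grids, 5–6 subjects per
class, one-ROI cohort simulations) were chosen so the full demonstration
completes in a few minutes on a single CPU.

## Known limitations

Axis-aligned acquisitions only (oblique B0 out of scope); single-coil
complex input; no spatial phase unwrapping (temporal only, adequate for the
default ΔTE and nigral field magnitudes); no water–fat modelling; no
multi-compartment T2\*; mono-exponential R2\* without a noise floor biases
estimates downward at very low SNR (quantified in tests); MEDI
regularization shrinks ROI means by a few percent at structure edges; the
cohort generator's Gaussian, MCAR, linear-trajectory assumptions are
idealizations of real longitudinal data.
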