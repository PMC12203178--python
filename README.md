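# nigraq

Nigral iron quantification from multi-echo gradient-echo MRI: quantitative
susceptibility mapping (QSM), R2\* relaxometry, substantia-nigra (SN)
territory statistics, and the longitudinal cohort models used to track
posteroventral nigral iron in early Parkinson's disease (PD) and isolated
REM sleep behaviour disorder (iRBD).

It is written for neuroimaging methodologists who need a transparent,
tested re-implementation of this analysis stack — and, because the
underlying patient data cannot be redistributed, it ships a digital
midbrain phantom and a synthetic three-visit cohort generator that
reproduce the statistical structure the analysis assumes, so every stage is
verifiable end to end.

## What it computes

**Reconstruction.** The B0 field shift induced by a susceptibility
distribution χ (ppm) is the dipole convolution
`f = F⁻¹[D(k)·F[χ]]`, `D(k) = 1/3 − k_z²/|k|²`, `D(0)=0`. The pipeline
inverts this in three stages:

1. *Field fitting* — per-voxel nonlinear least squares of the complex
   signal model `S(TE) = A·exp((i2πf − R2*)TE + iφ0)` with temporal phase
   unwrapping (`fit_complex_field`);
2. *Background removal* — Laplacian boundary value method: fields from
   sources outside the brain are harmonic inside, so the background solves
   Laplace's equation with Dirichlet data from the total field
   (`remove_background_lbv`);
3. *Dipole inversion* — morphology-enabled L1 inversion,
   `min_χ Σ‖M_G ⊙ ∇χ‖₁ + λ‖W ⊙ (D∗χ − f)‖₂²`, solved by IRLS with
   conjugate-gradient inner loops (`invert_dipole_medi`).

R2\* (= 1/T2\*, Hz; rises with tissue iron) is fitted separately from the
magnitude decay `|S|(TE) = M0·e^{−R2*·TE}` (`fit_r2star`).

**Territories.** The SN is split per hemisphere into anterodorsal,
posterodorsal, anteroventral and posteroventral territories using the
red-nucleus rule (dorsal = slices where the red nucleus is visible,
ventral = slices inferior to it; anterior/posterior split halfway along the
SN's own extent). The posteroventral territory is the one earliest affected
in PD. ROI means average left and right hemisphere means.

**Statistics.** Baseline per-ROI OLS `value ~ Group + age + sex` with a
group F-test and Tukey-adjusted marginal-mean contrasts; longitudinal
random-intercept mixed models `value ~ Group*Visit + age + sex + (1|subject)`
with type-II Wald χ² tests, per-group annual slopes and slope contrasts;
Pearson correlation families with Benjamini–Hochberg FDR; exact Wilcoxon
left-right symmetry checks; demographics (ANOVA/Tukey, chi-square with
corrected pairwise tests); percentage rate of change
`(x̄_final − x̄_initial)/x̄_initial × 100`.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Simulate the default posteroventral cohort (sample sizes, means, SDs and
slopes follow the published three-visit study design) and fit the
longitudinal model:

```python
from nigraq import default_design, simulate_cohort, fit_longitudinal_lmm

design = default_design(seed=7, rois=["posteroventral"])
table, truth = simulate_cohort(design)          # 1359 rows, 220 subjects
fit = fit_longitudinal_lmm(table, "posteroventral", "qsm_ppm")
print(fit.slopes[["group", "slope", "ci_low", "ci_high", "p"]])
```

```
  group     slope    ci_low   ci_high         p
0    HV  0.000412 -0.001809  0.002634  0.716071
1  iRBD  0.000599 -0.002625  0.003824  0.715549
2    PD  0.003734  0.002171  0.005298  0.000003
```

Only the PD group shows a credible annual increase in posteroventral
susceptibility; its 95% CI covers the generating slope of 0.0026 ppm/year.
The Wald tests for this fit give Group p = 2.5e−9, Visit p = 1.2e−4 and
Group×Visit p = 0.029 — the interaction meaning the groups' trajectories
diverge over time.

The same from the shell, including the imaging arm (two phantom classes →
reconstruction → ROI extraction → baseline model):

```bash
nigraq run --seed 1 --out demo_out         # full pipeline, a few minutes
nigraq simulate-cohort --seed 7 --out cohort_out
nigraq stats-longitudinal --table cohort_out/cohort_table.csv \
    --roi posteroventral --out slopes.csv
```

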