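# Methods

## Problem and model

`ivimtrack` analyses longitudinal diffusion-weighted MRI of rectal tumours
under neoadjuvant radiochemotherapy. The measured quantity is the mean ROI
signal intensity as a function of the diffusion weighting b (s/mm²),
acquired at three time points (pre-treatment, during treatment, post-
treatment) over eleven b-values (0, 10, 20, 30, 50, 60, 100, 200, 600, 800,
1000 s/mm², acquired as a dense low-b block and a sparse high-b block). Two
signal models are used:

* **IVIM biexponential.**
  `S_b/S_0 = (1 − f)·e^(−bD) + f·e^(−b(D + D*))`, with perfusion fraction
  `f ∈ [0, 1]`, tissue diffusion coefficient `D` (mm²/s) and perfusion-
  related pseudo-diffusion coefficient `D* ≥ D` (mm²/s). This is the
  generative model of every synthetic curve.
* **Monoexponential ADC.** The apparent diffusion coefficient is minus the
  (unweighted) least-squares slope of `ln S_b` against `b`. With `f > 0` the
  perfusion compartment steepens the low-b decay, so ADC > D. ADC, not D, is
  the longitudinal biomarker the response analysis tests.

The clinical endpoint is the TN comparison of baseline clinical stage
(cT, cN) with pathological stage after surgery (ypT, ypN): ypT0 ypN0 is a
pathological complete response (pCR); any reduction of at least one level in
T or N is a partial response (downstaging); otherwise no response.
Responders are pCR or partial responders.

## Fitting procedures and numerical choices

* **ADC fit** (`fit_adc_monoexp`): ordinary least squares on the log signal
  over a configurable b-subset, default all eleven b-values (a perfusion-
  suppressed `b ≥ 200` option exists). The default follows from the
  magnitude of typical tumour ADC summaries (~0.75–1.3 ×10⁻³ mm²/s), which
  are consistent with all-b ADC fitting. Plain (unweighted) OLS is kept here
  because this is how ADC is conventionally defined.
* **Segmented IVIM fit** (`fit_ivim_segmented`): `D` and the intercept come
  from a log-linear fit over `b ≥ 200` (the acquisition's own block
  boundary); `f = 1 − exp(intercept)`, clamped to [0, 1] and flagged
  non-converged when the pre-clamp value leaves [−0.05, 1.05]; `D*` then
  comes from a bounded scalar minimisation over `[D, 100×10⁻³]` of the
  squared residual over all b. The high-b log-linear step is *signal-
  weighted* by default: under additive signal noise the log transform
  inflates the variance of strongly attenuated points by `1/S²`, and
  weighting by `S` restores equal effective variance. This weighting is what
  brings the precision of `D` at SNR 50 to a median relative error of ≈4.5%
  (unweighted: ≈5.8%).
* **Full IVIM fit** (`fit_ivim_full`): bounded trust-region nonlinear least
  squares over `(f, D, D* − D, S0)`, initialised from the segmented fit
  (the accepted stabiliser for this ill-conditioned problem; no multi-start
  by default). Parametrising the excess pseudo-diffusion `D* − D ≥ 0` makes
  the `D* ≥ D` constraint a box bound. Bounds: `D ≤ 5×10⁻³`,
  `D* − D ≤ 100×10⁻³` mm²/s (physiological caps, configurable). Curves are
  normalised by the measured b=0 signal; only the full fit re-estimates the
  scale. The optimiser never increases the residual relative to its start.
* **Estimator division of labour.** The full fit is the exact optimum of
  the model and removes the segmented fit's small deterministic bias (the
  perfusion compartment can still contribute ~2% of the b=200 signal when
  `D*` is low, biasing the one-pass segmented `D` by up to ~5–6%
  noise-free). Conversely, at clinical SNR the free four-parameter fit pays
  for its flexibility: its Fisher information at the benchmark conditions
  (SNR 50, f=0.1, D=1×10⁻³, D*=10×10⁻³) caps the precision of `D` at
  sd ≈ 11.5%, and the implementation sits at that bound. The segmented
  estimator's structural constraint roughly halves that error, so the
  pipeline reports both (`ivim.csv` has one row per method) and treats the
  segmented `D` as the estimator of record at clinical SNR.
* **Grid-search oracle** (`fit_ivim_oracle`): exhaustive residual
  minimisation over explicit parameter grids; exists to certify optima in
  tests, never used in the pipeline.

## Synthetic cohort: what it emulates

The generator reproduces the statistical structure the analysis assumes,
with defaults fixed at the study conditions: 22 patients (15 responders, 7
nonresponders), three time points, group ADC moments (×10⁻³ mm²/s)

| group         | pre         | during      | post        |
|---------------|-------------|-------------|-------------|
| responders    | 0.87 ± 0.23 | 1.13 ± 0.26 | 1.28 ± 0.32 |
| nonresponders | 0.75 ± 0.14 | 1.03 ± 0.10 | 1.18 ± 0.38 |

Rician noise at b=0 SNR 50 (magnitude MRI: the clean signal plus complex
Gaussian noise, magnitude taken), ROI areas uniform on 100–230 mm², and 60%
of responders reaching pCR.

Key generator decisions:

* **ADC is the calibrated quantity.** A target ADC is drawn per
  patient × timepoint from a truncated normal (floor 0.1×10⁻³ mm²/s, which
  prevents non-physical draws at the widest nonresponder SD); `f` and
  `D*/D` are nuisance draws (defaults `f ∈ [0.05, 0.20]`,
  `D*/D ∈ [5, 20]`, standard abdominal IVIM ranges); then `D` is solved by
  bracketed root finding so that the noise-free all-b ADC fit of the
  resulting biexponential curve equals the target exactly. This makes the
  configured moments hold for the *measured* quantity rather than the
  latent one.
* **Within-subject correlation 0.60.** ADC draws share a subject-level
  random effect: `ADC_it = μ_gt + σ_gt·(√ρ·u_i + √(1−ρ)·e_it)` with
  `ρ = 0.60`. Marginal per-timepoint moments are unchanged; what ρ controls
  is the error term of the repeated-measures analysis. The default was
  chosen because it is the value at which the repeated-measures F and LSD T
  statistics implied by the group moments above match the magnitudes such
  cohorts report (F ≈ 21, T(pre,during) ≈ 4.1, T(during,post) ≈ 2.4 for
  the responder moments at n = 15), whereas fully independent draws (ρ = 0)
  would imply F ≈ 8.7. Serial structure beyond a single shared random
  effect (e.g. AR(1) decay) is not modelled.
* **Staging consistent by construction.** Baselines are locally advanced
  (cT ∈ {3,4}, cN ∈ {0,1,2}); responders get ypT0N0 (pCR fraction) or a
  strict downstaging that is not complete; nonresponders get stable or
  progressive stages. Every generated label therefore agrees with the
  classifier — by design, so the generator cannot silently contradict the
  classification stage. A configurable count of nonresponders can be marked
  pathology-absent (patients who never reach surgery); the default
  classification policy labels them no-response with an explicit flag.

What the generator does **not** emulate: voxel-level heterogeneity and
partial-volume effects (noise is applied at the ROI-mean level, with SNR 50
read as the effective ROI-level SNR), scanner drift between time points,
reader variability in ROI placement, T2 shine-through, or any correlation
between ADC evolution and the staging labels beyond group membership.
Passing tests therefore demonstrate the statistical machinery under the
assumed data-generating process, not clinical performance on real images.

## ROI stage

ROIs are voxel index sets drawn on the b=800 image and transferred
identically to all b-values (co-acquired images share the grid; no
registration). Necrosis/cyst exclusion applies three tunable rules:
high-b attenuation ratio `S(b_max)/S(0)` below 0.5× the ROI median ratio,
ratio below an absolute floor of 0.15 (free-water-like decay, the only rule
that can catch a ROI that is necrotic throughout), and b=0 signal above 3×
the ROI median (T2-hyperintensity). Defaults are deliberately tunable: in
practice this exclusion is a radiologist judgement call, and no quantitative
rule is canonical. Image fixtures are plain `.npz` array containers
(`data`, `b_values`, optional masks) — deliberately free of medical-image
I/O dependencies.

## Statistical protocol

Within each response group, mean ADC across the three time points is
compared with a one-way ANOVA F-test; both designs are implemented and the
default is **repeated-measures** (`SS_total = SS_time + SS_subject +
SS_error`, `F = MS_time/MS_error`, df `(t−1, (t−1)(n−1))`), because the
data are the same subjects measured three times and because the group
summary moments are consistent with reported F magnitudes only under a
within-subject analysis (see the correlation note above). Pairwise
contrasts use Fisher's LSD with the ANOVA's `MS_error` and `df_error`,
protected by default (pairs are only declared significant when the omnibus
F passes), two-sided throughout. Alphas: 0.05 for the omnibus F, 0.005 for
LSD. Degenerate inputs are defined explicitly: zero error variance gives
`F = +∞, p = 0` when means differ and `F = 0, p = 1` when they do not;
groups smaller than two patients are skipped with a warning; missing
timepoint cells are an error (no imputation).

The cohort-level power property asserted in the acceptance tests is
interpreted over the *adjacent* contrasts: with the default moments the
pre-vs-post contrast necessarily has the largest cumulative difference, so
"the early rise discriminates" is operationalised as the pre-vs-during
contrast being significant in strictly more replicate cohorts than
during-vs-post, alongside ≥90% omnibus rejection for responders.

## Problem sizes used in checks

Acceptance-style checks run at: 100-point forward-model sweeps, 100
noise-free recovery parameter sets, 200–500 noisy-fit replicates, 50 random
ANOVA instances, 100 replicate cohorts for the power property, and
5000-patient groups for generator-moment verification (3-standard-error
bands). These sizes put Monte-Carlo error well below every asserted
tolerance while keeping the default suite fast.

## Known limitations

* The generator's staging marginals (distribution over cT, cN) are uniform
  within their admissible sets, not calibrated to any registry.
* The segmented fit's `D` bias for low `D*` is documented rather than
  iterated away; the full fit is the unbiased reference noise-free.
* Rician bias is simulated but not corrected in fitting (at SNR 50 the
  bias at b=1000 is ≈0.2% of the signal; a correction would matter at
  substantially lower SNR).
* `report.json` reproducibility is exact only on identical software stacks
  (floating-point formatting is part of the byte stream).
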