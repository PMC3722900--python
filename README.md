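# ivimtrack

Quantitative diffusion-weighted MRI (DW-MRI) response monitoring for
tumours under neoadjuvant radiochemotherapy, built around the intravoxel
incoherent motion (IVIM) signal model. The package is aimed at imaging
scientists who want a reproducible desk pipeline from multi-b-value ROI
signal curves to a longitudinal group analysis: does the apparent diffusion
coefficient (ADC) rise early in treatment in the patients who go on to
respond?

## The model and the statistic

The mean ROI signal at diffusion weighting `b` (s/mm²) follows the IVIM
biexponential

```
S_b / S_0 = (1 − f)·exp(−b·D) + f·exp(−b·(D + D*))
```

with perfusion fraction `f`, tissue diffusion coefficient `D` (mm²/s) and
perfusion-related pseudo-diffusion coefficient `D* ≥ D`. The ADC is the
monoexponential summary, `−slope` of `ln S_b` vs `b`. Curves are acquired
at three time points (pre / during / post treatment) over eleven b-values
(0–1000 s/mm²).

Patients are classified from TN staging — pathological complete response
(ypT0 ypN0), partial response (downstaging of at least one T or N level),
or no response — and within each group the ADC evolution is tested with a
repeated-measures one-way ANOVA (F-test) followed by Fisher LSD pairwise
contrasts (`T = |m_a − m_b| / sqrt(MS_error·(1/n_a + 1/n_b))`), at alpha
0.05 (F) and 0.005 (LSD).

Everything is testable offline: a synthetic-cohort generator produces a
22-patient cohort (15 responders / 7 nonresponders) whose group ADC
moments, staging labels and magnitude-MRI (Rician) noise match the study
conditions, with known ground truth. `docs/methods.md` documents the
model, the generator and every numerical choice.

## Worked example

```
$ ivimtrack simulate --seed 1 --out-dir demo
wrote 22 patients to demo (signals.csv, staging.csv, truth.json)

$ ivimtrack fit --signals demo/signals.csv --out-dir demo
fitted 66 patient-timepoints -> demo/adc.csv, ivim.csv

$ ivimtrack analyze --adc demo/adc.csv --staging demo/staging.csv --out-dir demo
responders: F=16.85 (df 2,28) p=1.572e-05
  LSD pre vs during: T=3.12 p=0.004149*
  LSD pre vs post: T=5.80 p=3.146e-06*
  LSD during vs post: T=2.68 p=0.01226
nonresponders: F=4.99 (df 2,12) p=0.02641
  LSD pre vs during: T=2.95 p=0.01211
  LSD pre vs post: T=2.45 p=0.03035
  LSD during vs post: T=0.50 p=0.6279
```

Reading the output: the responders' omnibus F (16.85 on 2 and 28 degrees of
freedom) rejects the hypothesis of constant mean ADC across the three time
points, and the protected LSD contrasts localise the change — the
pre-to-during rise is already significant at the strict 0.005 level (`*`),
while the during-to-post change is not. The nonresponders' F does not reach
the pattern's strength and none of their contrasts pass the LSD threshold.
An early ADC rise therefore separates the groups in this simulated cohort.
`ivimtrack run` executes the same chain end-to-end and additionally writes
`report/report.json` (byte-identical for identical config and seed) and
`manifest.json`; `ivimtrack validate` checks input tables against the
b-value scheme. ADC values in `adc.csv` are in 10⁻³ mm²/s.

The same analysis accepts real data: provide `signals.csv`
(patient_id, timepoint, b_value, mean_si) and `staging.csv`
(patient_id, cT, cN, ypT, ypN — yp columns empty for unoperated patients),
or `.npz` image stacks with tumour masks, which are run through ROI
propagation and necrosis exclusion first.

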