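# breastdwi

Discrimination of benign from malignant breast lesions on diffusion-weighted
MRI (DWI): qualitative morphological scoring, quantitative ADC analysis with
a Youden-selected cutoff, their rule-based combination, and the
diagnostic-performance statistics used to compare readings.

Breast DWI offers a contrast-free alternative to dynamic contrast-enhanced
(DCE) MRI. Malignant tissue restricts water diffusion, so a low apparent
diffusion coefficient — `ADC = ln(S1/S2)/(b2−b1)` between two diffusion
weightings, here b = 0 and 750 s/mm² — flags malignancy; and with
low-distortion acquisitions, lesion *morphology* (shape, margin,
distribution, internal pattern) can be read on DWI itself much like the
BI-RADS lexicon on DCE-MRI. This package implements that workflow as a
library for radiology researchers and biostatisticians:

* a validated lesion-table schema (CSV/XLSX) with mass/non-mass descriptor
  invariants;
* the 3-level morphological confidence score (any major finding → 3; enough
  intermediate findings → 2; else 1) and its binary mapping;
* ADC quantification from dual-b-value signals, the lowest-of-≥3-ROIs lesion
  convention, and voxelwise ADC maps;
* combination rules: score-3 lesions positive regardless of ADC, others
  re-called by ADC < cutoff; plus the DCE-MRI + ADC analogue on BI-RADS;
* statistics: exact-rational confusion metrics, Woolf odds ratios,
  Mann–Whitney AUCs with Hanley–McNeil standard errors (J = sens + spec − 1
  cutoff selection), the Hanley–McNeil independent and DeLong paired AUC
  tests;
* synthetic cohorts: a seeded generator calibrated to the reference study
  conditions, and a deterministic count-engineered cohort reproducing the
  published marginal tables.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from breastdwi import engineered_study_cohort, evaluate_pipeline

report = evaluate_pipeline(engineered_study_cohort())
print(report["detection_rate_pct"])                          # 97.92
print(report["analyses"]["dwi_quantitative"]["metrics"])
# {'sensitivity': 76.79, 'specificity': 79.31, 'ppv': 93.48,
#  'npv': 46.94, 'accuracy': 77.3}
print(report["analyses"]["dwi_combination"]["metrics"])
# {'sensitivity': 92.86, 'specificity': 72.41, 'ppv': 92.86,
#  'npv': 72.41, 'accuracy': 88.65}
```

Of 144 lesions, 141 are visible on DWI (97.92% detection). The ADC-only
reading at the 1.0 × 10⁻³ mm²/s cutoff is specific but misses a quarter of
cancers (sensitivity 76.79%); adding the morphological score recovers
sensitivity to 92.86% while keeping specificity at 72.41% — the added value
of qualitative analysis. The `examples/` scripts walk each capability:
scoring single lesions, ADC maps, simulating a cohort and selecting the
Youden cutoff (which lands near 1.0 on simulated data), and the full
five-reading evaluation.

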