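# Methods

`breastdwi` implements a diagnostic workflow for discriminating benign from
malignant breast lesions on diffusion-weighted MRI (DWI), together with the
statistics used to compare competing readings. This note documents the model,
the parameter choices, the synthetic data and the numerical conventions.

## The diagnostic readings

Five per-lesion readings are evaluated by `evaluate_pipeline`:

1. **Qualitative DWI** — each visible lesion's morphological descriptors are
   mapped to malignancy-risk classes (minor / intermediate / major) by an
   injectable lexicon (`DescriptorRiskTable`; defaults below) and aggregated
   into a 3-level confidence score: any major finding → 3; a mass with ≥ 2
   intermediate findings, or a non-mass lesion with ≥ 1 intermediate
   finding → 2; otherwise 1 (minor findings only, or a mass with a single
   intermediate finding). Scores 2–3 are positive.

   | kind | minor | intermediate | major |
   |---|---|---|---|
   | shape (mass) | oval | round, irregular | — |
   | margin (mass) | circumscribed | irregular | spiculated |
   | distribution (non-mass) | focal | linear | segmental |
   | internal pattern (both) | homogeneous | heterogeneous | rim sign |

2. **Quantitative DWI** — the apparent diffusion coefficient, from the
   mono-exponential decay `ADC = ln(S1/S2) / (b2 − b1)` between b = 0 and
   750 s/mm², in units of 10⁻³ mm²/s. (The formula is sometimes printed as
   `ln(S2/S1)/(b2−b1)`, which is negative for decaying signal; the package
   uses the standard positive orientation.) Per lesion, the lowest ADC among
   ≥ 3 ROI measurements is taken (`lesion_adc`). The lesion is positive iff
   ADC is *strictly below* the cutoff; ties at the cutoff are negative
   (`<` vs `≥` dichotomy). The default cutoff 1.0 × 10⁻³ mm²/s is the
   maximum-Youden-index operating point of the study conditions.

3. **DWI combination** — score-3 lesions are positive regardless of ADC;
   score-1/2 lesions are re-called purely by the ADC dichotomy.

4. **DCE-MRI alone** — BI-RADS ≥ 4 positive (consumed as an input label).

5. **DCE-MRI + ADC** — category 5 positive, categories 1–2 negative,
   categories 3–4 re-called by ADC. The handling of categories 1–2 and of
   DWI-invisible lesions (which keep the DCE-alone call) is not prescribed by
   the reference setting; both choices are configurable in
   `CombinationRuleConfig`.

Lesions invisible on DWI are treated as negative DWI cases and **excluded**
from DWI-level metrics (analyses run on the visible subset); the alternative
of counting them as true/false negatives was considered and rejected because
the reference protocol explicitly excludes them. They keep their BI-RADS
category, so DCE-level analyses use the full cohort.

## Statistics

* **Confusion metrics** (sensitivity, specificity, PPV, NPV, accuracy) are
  computed as exact rationals and rounded to two decimals (half up) only for
  display; a zero-denominator metric is reported as undefined (`None`), never
  as 0.
* **Odds ratios** for 2×2 tables use the exposure-vs-reference orientation
  with Woolf's log-variance 95% CI, `exp(ln OR ± 1.96·√(Σ 1/nᵢ))`. The
  multiplier is fixed at 1.96 (not Φ⁻¹(0.975) ≈ 1.95996), the convention of
  the clinical literature whose printed intervals this reproduces. A table
  with any zero cell yields an undefined OR (mirroring the "…" entries such
  tables print), not an exception.
* **ROC/AUC**: the AUC is the tie-aware Mann–Whitney probability
  (ties counted ½), computed by midranks, which equals the trapezoidal area
  under the empirical ROC points (point sets delegated to
  `sklearn.metrics.roc_curve`). Its standard error is Hanley–McNeil's
  closed form with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`.
* **Youden cutoff**: `J = sens + spec − 1` is maximized over all distinct
  observed marker values; ties are broken toward higher sensitivity, then
  toward the smaller threshold. For lower-is-positive markers (ADC) a lesion
  is positive iff its value is strictly below the cutoff.
* **AUC comparison**: independent samples use the Hanley–McNeil z-test
  `z = (A₁−A₂)/√(SE₁²+SE₂²)`; paired (same lesions) readings use the DeLong
  covariance-of-placements test. The paired method is a deliberate
  interpretation: the reference setting compares correlated curves without
  naming a method, and DeLong is the field standard.
* Chi-square and Wilcoxon rank-sum tests are thin delegations to scipy and
  only smoke-tested; they are not part of the package's contribution.
* A binary reading's ROC has a single interior operating point, so its AUC
  equals (sens + spec)/2 — balanced accuracy. The qualitative reading reports
  AUCs both on the 3-level score and on the binarized call, since a published
  AUC for such a reading may refer to either.

## Synthetic cohorts

No real lesion table ships with the package; two generators make every stage
testable.

**`generate_cohort`** samples lesions hierarchically: pathology class →
visibility → lesion type → descriptors → ADC, size, BI-RADS. Defaults
(`default_config`) are the reference study conditions:

* prevalence 112/144 malignant; P(invisible | benign) = 3/32, 0 for
  malignant;
* lesion type given visible: benign 22 mass / 7 non-mass, malignant 97/15;
* descriptors drawn *conditionally independently* given (class, type) from
  the class-conditional frequencies (e.g. malignant margin 6:73:17 over
  circumscribed:irregular:spiculated, normalized over 96 — the printed
  per-class descriptor counts disagree with the lesion-type row by one
  lesion, and the descriptor-column counts are used). Only marginals are
  emulated; descriptor–descriptor and ADC–descriptor correlation beyond
  shared class is absent, a documented limitation — the score × ADC
  cross-structure emerges only qualitatively from class mixing;
* per-lesion ADC ~ Gaussian truncated to the class's observed range
  (benign 1.14 ± 0.23 on [0.66, 1.58]; malignant 0.88 ± 0.19 on
  [0.42, 1.36]), sampled by inverse CDF on the truncated interval (exact, no
  rejection). The printed mean/SD are treated as the distribution of the
  final per-lesion ADC (after the lowest-ROI rule), since the ROI-level
  distribution is unknowable from summary tables;
* size ~ log-normal with the class median as scale and
  `σ = √(2·ln(mean/median))` (benign 0.797, malignant 0.617), truncated to
  the observed range — truncation shifts the realized median slightly;
* BI-RADS per class: benign 3:4:5 = 11:21:0, malignant 1:7:104 — the unique
  split with no benign category 5 that matches both the category totals
  (12/28/104) and the DCE operating point (sens 99.11%, spec 34.38%).

Determinism: all draws come from one `numpy` generator consumed in a fixed
field order, so identical `(config, seed)` give bitwise-identical tables.
Parameter recovery (every categorical probability within 3 binomial SEs at
n = 20 000; ADC means vs the truncated-normal mean; the ADC AUC vs a
numerical overlap integral) is asserted in the test suite.

**`engineered_study_cohort`** is a deterministic 144-lesion table whose
*joint* counts of (class, score, ADC dichotomy, BI-RADS) were solved so that
all published marginals hold at once: the 144 → 141 visibility accounting
(the three invisible lesions are benign, sized 1.5/0.6/0.4 cm), the
score × ADC and BI-RADS × ADC cross-tables, and the confusion matrices of
all five readings. Two consequences of that reconstruction are worth noting:
the published cross-tables force 2 benign score-3 lesions even though the
descriptor-frequency table shows no benign major descriptor (the cross-tables
were honored), and the qualitative reading's accuracy computes to 85.82%
from the published sensitivity/specificity counts rather than the 85.80%
printed alongside them. Descriptors are canonical templates per (type,
score), and sizes are nominal; only the counted quantities are calibrated.

## Problem sizes

Tests run the generator at n = 20 000–50 000 (seconds); the acceptance
script samples n = 10 000 for the stochastic quantities (Youden cutoff,
ADC AUC, detection rate) and uses the engineered cohort (n = 144) for all
published-count quantities. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

* Descriptor independence given class (above) means per-lesion joint
  behaviour of score and ADC in sampled cohorts is only qualitatively
  realistic; published per-lesion AUCs (e.g. the qualitative reading's AUC
  on real data) are not reproducible from summary tables and are not
  claimed.
* Multivariate logistic regression is out of scope; only univariate 2×2 odds
  ratios are computed.
* XLSX float cells are written as text to guarantee lossless round-trips
  (xlsx numeric cells keep 15 significant digits).
* No image-level processing beyond voxelwise ADC maps: ROI geometry, DICOM
  I/O and descriptor extraction from images are out of scope; descriptors
  are inputs.
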