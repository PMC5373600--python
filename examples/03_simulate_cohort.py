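"""Generate a synthetic lesion cohort and pick an ADC cutoff.

Samples a cohort under the reference study conditions (77.8% malignant,
class-conditional descriptor frequencies, truncated-Gaussian ADC), writes
it to CSV, and selects the ADC cutoff maximizing the Youden index.
"""

from pathlib import Path

from breastdwi import (
    Pathology,
    default_config,
    generate_cohort,
    split_visible,
    write_lesion_table,
    youden_cutoff,
)

cohort = generate_cohort(default_config(n_lesions=2000, seed=7))
out = Path("cohort_2000.csv")
write_lesion_table(cohort, out)
print(f"wrote {len(cohort)} lesions to {out}")

visible, invisible = split_visible(cohort)
print(f"visible on DWI: {len(visible)} "
      f"(detection rate {100 * len(visible) / len(cohort):.1f}%)")

adc = [r.adc for r in visible]
labels = [r.pathology is Pathology.MALIGNANT for r in visible]
cut = youden_cutoff(adc, labels, direction="lower_is_positive")
print(f"maximum-Youden ADC cutoff: {cut.cutoff:.2f} x10^-3 mm^2/s "
      f"(J = {cut.j:.3f}, sens {100 * cut.sensitivity:.1f}%, "
      f"spec {100 * cut.specificity:.1f}%)")
# The cutoff lands near 1.0 x10^-3 mm^2/s, the operating point that
# separates the benign (mean 1.14) and malignant (mean 0.88) ADC
# distributions of the study conditions.
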