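"""Run all five diagnostic readings over the count-engineered study cohort.

The engineered cohort reproduces the published marginal tables exactly, so
the metric columns printed here match the reference study's performance
table; the synthetic-cohort route (example 03) shows the same pipeline on
sampled data.
"""

from breastdwi import engineered_study_cohort, evaluate_pipeline

report = evaluate_pipeline(engineered_study_cohort())
print(f"lesions: {report['n_total']} total, {report['n_visible']} visible "
      f"on DWI (detection rate {report['detection_rate_pct']}%)\n")

header = f"{'reading':20s}" + "".join(
    f"{m:>13s}" for m in ("sensitivity", "specificity", "ppv", "npv",
                          "accuracy", "AUC"))
print(header)
for name, entry in report["analyses"].items():
    m = entry["metrics"]
    auc = f"{entry['roc'].auc:.3f}" if entry["roc"] else "--"
    print(f"{name:20s}" + "".join(f"{m[k]:>13.2f}" for k in
                                  ("sensitivity", "specificity", "ppv",
                                   "npv", "accuracy")) + f"{auc:>13s}")

print("\nDWI combination by lesion size:")
for stratum, entry in report["combination_by_size"].items():
    m = entry["metrics"]
    print(f"  {stratum:6s} (n={entry['n']:3d}): sens {m['sensitivity']}, "
          f"spec {m['specificity']}, accuracy {m['accuracy']}")
# Combining the morphological score with the ADC raises sensitivity over
# the ADC-only reading (92.86 vs 76.79) while keeping specificity above
# the morphology-only reading (72.41 vs 51.72).
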