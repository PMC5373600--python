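"""Score single lesions with the 3-level morphological confidence score.

Builds a handful of lesions with typical descriptor combinations, scores
each one, and shows the binary call the score maps to.
"""

from breastdwi import (
    Distribution,
    InternalPattern,
    LesionRecord,
    LesionType,
    Margin,
    Pathology,
    Shape,
    qual_positive,
    qual_score,
    risk_classes,
)

examples = [
    LesionRecord("oval-circ-homog", Pathology.BENIGN, True, LesionType.MASS,
                 shape=Shape.OVAL, margin=Margin.CIRCUMSCRIBED,
                 internal_pattern=InternalPattern.HOMOGENEOUS,
                 adc=1.3, size_cm=1.1, birads=3),
    LesionRecord("irregular-mass", Pathology.MALIGNANT, True, LesionType.MASS,
                 shape=Shape.IRREGULAR, margin=Margin.IRREGULAR,
                 internal_pattern=InternalPattern.HOMOGENEOUS,
                 adc=0.9, size_cm=1.8, birads=4),
    LesionRecord("spiculated-rim", Pathology.MALIGNANT, True, LesionType.MASS,
                 shape=Shape.IRREGULAR, margin=Margin.SPICULATED,
                 internal_pattern=InternalPattern.RIM,
                 adc=0.7, size_cm=2.4, birads=5),
    LesionRecord("segmental-nonmass", Pathology.MALIGNANT, True,
                 LesionType.NONMASS, distribution=Distribution.SEGMENTAL,
                 internal_pattern=InternalPattern.HETEROGENEOUS,
                 adc=0.95, size_cm=3.0, birads=4),
]

for lesion in examples:
    classes = risk_classes(lesion)
    score = qual_score(lesion)
    call = "positive" if qual_positive(score) else "negative"
    print(f"{lesion.lesion_id:20s} risk classes {dict(classes)} "
          f"-> score {score} ({call})")

# A score of 1 means probably benign (< 10% malignancy probability), 2 is
# indeterminate (10-50%), 3 probably malignant (> 50%); scores 2-3 are read
# as positive for malignancy.
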