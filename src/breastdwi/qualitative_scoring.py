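"""Three-level morphological confidence scoring of lesions on DWI.

Each descriptor value of a visible lesion is mapped to an estimated
malignancy-risk class (minor / intermediate / major) by a
:class:`~breastdwi.lesion_schema.DescriptorRiskTable`; the per-lesion score
aggregates those classes:

* score 3 (probably malignant) — any major finding (spiculated margin,
  segmental distribution, or rim sign);
* score 2 (indeterminate) — a mass with at least two intermediate findings,
  or a non-mass lesion with at least one intermediate finding;
* score 1 (probably benign) — otherwise, i.e. minor findings only, or a
  mass with a single intermediate finding.

Score 1 is read as negative; scores 2 and 3 as positive for malignancy.
"""

from __future__ import annotations

from collections import Counter

from .lesion_schema import (
    DescriptorRiskTable,
    LesionRecord,
    LesionType,
    RiskClass,
)

__all__ = ["risk_classes", "qual_score", "qual_positive"]


def risk_classes(record: LesionRecord,
                 table: DescriptorRiskTable | None = None) -> Counter:
    """Multiset of risk classes of a visible lesion's descriptors.

    Masses contribute shape, margin and internal pattern (3 entries);
    non-mass lesions contribute distribution and internal pattern (2).
    """
    if not record.dwi_visible:
        raise ValueError(f"{record.lesion_id}: lesion not visible on DWI; "
                         "no morphological descriptors to score")
    table = table or DescriptorRiskTable()
    if record.lesion_type is LesionType.MASS:
        kinds = (("shape", record.shape), ("margin", record.margin),
                 ("internal_pattern", record.internal_pattern))
    else:
        kinds = (("distribution", record.distribution),
                 ("internal_pattern", record.internal_pattern))
    return Counter(table.risk(kind, value) for kind, value in kinds)


def qual_score(record: LesionRecord,
               table: DescriptorRiskTable | None = None) -> int:
    """The 3-level qualitative confidence score of a visible lesion."""
    classes = risk_classes(record, table)
    if classes[RiskClass.MAJOR] > 0:
        return 3
    n_intermediate = classes[RiskClass.INTERMEDIATE]
    threshold = 2 if record.lesion_type is LesionType.MASS else 1
    return 2 if n_intermediate >= threshold else 1


def qual_positive(score: int) -> bool:
    """Binary mapping of the confidence score: 1 negative, 2-3 positive."""
    if score not in (1, 2, 3):
        raise ValueError(f"score must be 1, 2 or 3, got {score}")
    return score >= 2
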