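"""ADC-based reclassification rules combining morphology with quantitation.

Two combination readings are provided:

* **DWI combination** — lesions scored 1 or 2 on qualitative morphology are
  reclassified purely by their ADC (positive iff ADC strictly below the
  cutoff, default 1.0e-3 mm^2/s); score-3 lesions are called malignant
  regardless of ADC.
* **DCE + ADC** — the analogue on the DCE-MRI BI-RADS read: category 5 stays
  positive, categories 3-4 are re-called by ADC, categories 1-2 stay
  negative.  Lesions invisible on DWI have no ADC and keep the DCE-alone
  call (positive iff category >= 4).

Ties at the cutoff (ADC exactly equal) are negative: the dichotomy is
"< cutoff" vs ">= cutoff".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import pandas as pd

from .lesion_schema import DescriptorRiskTable, DwiAssessment, LesionRecord

__all__ = ["CombinationRuleConfig", "combine_dwi", "combine_dce",
           "assess_lesion", "cross_table"]


@dataclass(frozen=True)
class CombinationRuleConfig:
    """Parameters of the reclassification rules.

    adc_cutoff : ADC dichotomization threshold, 1e-3 mm^2/s (default 1.0,
        the maximum-Youden ROC cutoff of the study setting).
    override_score : qualitative score at/above which a lesion is positive
        regardless of ADC (default 3).
    birads_override : BI-RADS category at/above which the DCE+ADC call is
        positive regardless of ADC (default 5).
    birads_negative_max : BI-RADS category at/below which the DCE+ADC call
        is negative regardless of ADC (default 2; the study setting never
        re-calls category 1-2 lesions).
    """

    adc_cutoff: float = 1.0
    override_score: int = 3
    birads_override: int = 5
    birads_negative_max: int = 2

    def __post_init__(self) -> None:
        if not self.adc_cutoff > 0:
            raise ValueError(f"adc_cutoff must be > 0, got {self.adc_cutoff}")


def combine_dwi(score: int, adc: float,
                cfg: CombinationRuleConfig | None = None) -> bool:
    """Combined DWI call for one lesion: True means positive for malignancy."""
    cfg = cfg or CombinationRuleConfig()
    if score not in (1, 2, 3):
        raise ValueError(f"score must be 1, 2 or 3, got {score}")
    if score >= cfg.override_score:
        return True
    return adc < cfg.adc_cutoff


def combine_dce(birads: int, adc: float | None,
                cfg: CombinationRuleConfig | None = None) -> bool:
    """DCE-MRI + ADC call for one lesion.

    ``adc=None`` marks a lesion invisible on DWI: it keeps the DCE-alone
    call (positive iff BI-RADS >= 4).
    """
    cfg = cfg or CombinationRuleConfig()
    if not (isinstance(birads, int) and 1 <= birads <= 5):
        raise ValueError(f"birads must be an integer 1-5, got {birads}")
    if adc is None:
        return birads >= 4
    if birads <= cfg.birads_negative_max:
        return False
    if birads >= cfg.birads_override:
        return True
    return adc < cfg.adc_cutoff


def assess_lesion(record: LesionRecord,
                  cfg: CombinationRuleConfig | None = None,
                  table: DescriptorRiskTable | None = None) -> DwiAssessment:
    """Full DWI assessment of one visible lesion: qualitative score, ADC
    dichotomy and combined classification."""
    from .qualitative_scoring import qual_score  # avoid import cycle

    cfg = cfg or CombinationRuleConfig()
    score = qual_score(record, table)
    return DwiAssessment(
        lesion_id=record.lesion_id,
        qual_score=score,
        adc_positive=record.adc < cfg.adc_cutoff,
        combined_positive=combine_dwi(score, record.adc, cfg))


def cross_table(levels: Sequence[Hashable],
                adc_below_cutoff: Sequence[bool]) -> pd.DataFrame:
    """Ordinal-level x ADC-dichotomy contingency table with row percentages.

    ``levels`` are qualitative scores or BI-RADS categories (one per
    lesion); ``adc_below_cutoff`` is True where the lesion's ADC lies
    strictly below the cutoff (pass False for lesions without an ADC).
    Returns a DataFrame indexed by level with counts, row percentages and
    row totals, sorted by level.
    """
    if len(levels) != len(adc_below_cutoff):
        raise ValueError(
            f"length mismatch: {len(levels)} levels vs "
            f"{len(adc_below_cutoff)} dichotomy flags")
    df = pd.DataFrame({"level": list(levels),
                       "below": [bool(b) for b in adc_below_cutoff]})
    out = pd.DataFrame({
        "n_below_cutoff": df[df.below].groupby("level").size(),
        "n_at_or_above": df[~df.below].groupby("level").size(),
    }).fillna(0).astype(int).sort_index()
    out["total"] = out.n_below_cutoff + out.n_at_or_above
    out["pct_below_cutoff"] = 100.0 * out.n_below_cutoff / out.total
    out["pct_at_or_above"] = 100.0 * out.n_at_or_above / out.total
    return out
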