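"""Domain types and table I/O for breast-lesion DWI analysis.

A lesion is one row of a study table: a pathology label (benign/malignant),
whether it was visible on diffusion-weighted images, its BI-RADS lesion type
(mass vs non-mass), the morphological descriptors read from the DWI images,
the per-lesion apparent diffusion coefficient (ADC), the lesion size and the
DCE-MRI BI-RADS category.  ADC is carried in units of 1e-3 mm^2/s throughout
(the display unit of clinical breast DWI); :func:`adc_to_si` /
:func:`adc_from_si` convert to/from mm^2/s.

Mass lesions carry shape + margin; non-mass lesions carry a distribution
pattern; both carry an internal signal pattern.  Lesions invisible on DWI
carry no descriptors and no ADC but keep their BI-RADS category, so that
DCE-level analyses can run on the full cohort while DWI analyses run on the
visible subset (see :func:`split_visible`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Pathology",
    "LesionType",
    "Shape",
    "Margin",
    "Distribution",
    "InternalPattern",
    "RiskClass",
    "LesionRecord",
    "DescriptorRiskTable",
    "DwiAssessment",
    "SchemaError",
    "RecordValidationError",
    "read_lesion_table",
    "write_lesion_table",
    "split_visible",
    "detection_rate",
    "adc_to_si",
    "adc_from_si",
    "TABLE_COLUMNS",
]


class Pathology(str, enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class LesionType(str, enum.Enum):
    MASS = "mass"
    NONMASS = "nonmass"


class Shape(str, enum.Enum):
    OVAL = "oval"
    ROUND = "round"
    IRREGULAR = "irregular"


class Margin(str, enum.Enum):
    CIRCUMSCRIBED = "circumscribed"
    IRREGULAR = "irregular"
    SPICULATED = "spiculated"


class Distribution(str, enum.Enum):
    FOCAL = "focal"
    LINEAR = "linear"
    SEGMENTAL = "segmental"


class InternalPattern(str, enum.Enum):
    HOMOGENEOUS = "homogeneous"
    HETEROGENEOUS = "heterogeneous"
    RIM = "rim"


class RiskClass(enum.IntEnum):
    """Estimated malignancy risk of a morphological descriptor value."""

    MINOR = 1
    INTERMEDIATE = 2
    MAJOR = 3


class SchemaError(ValueError):
    """A lesion table does not conform to the documented column schema."""


class RecordValidationError(ValueError):
    """A lesion record violates an invariant; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None) -> None:
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)
        self.row = row


#: Maximum physically plausible ADC, in 1e-3 mm^2/s (free water ~3.0 at 37 C).
ADC_MAX = 4.0


@dataclass(frozen=True)
class LesionRecord:
    """One pathologically verified breast lesion.

    Invariants (enforced at construction):

    * descriptors and ADC are present iff the lesion is visible on DWI;
    * mass lesions have ``shape`` and ``margin`` and no ``distribution``;
      non-mass lesions have ``distribution`` and no shape/margin;
      both types have ``internal_pattern``;
    * ``adc`` lies in (0, 4.0] (1e-3 mm^2/s); ``size_cm`` > 0;
      ``birads`` is an integer BI-RADS category 1-5.
    """

    lesion_id: str
    pathology: Pathology
    dwi_visible: bool
    lesion_type: LesionType | None = None
    shape: Shape | None = None
    margin: Margin | None = None
    distribution: Distribution | None = None
    internal_pattern: InternalPattern | None = None
    adc: float | None = None
    size_cm: float = 1.0
    birads: int = 4

    def __post_init__(self) -> None:
        if self.dwi_visible:
            if self.lesion_type is None:
                raise RecordValidationError(
                    f"{self.lesion_id}: visible lesion needs a lesion_type")
            if self.adc is None:
                raise RecordValidationError(
                    f"{self.lesion_id}: visible lesion needs an ADC value")
            if not 0 < self.adc <= ADC_MAX:
                raise RecordValidationError(
                    f"{self.lesion_id}: adc={self.adc} outside (0, {ADC_MAX}]")
            if self.internal_pattern is None:
                raise RecordValidationError(
                    f"{self.lesion_id}: visible lesion needs internal_pattern")
            if self.lesion_type is LesionType.MASS:
                if self.shape is None or self.margin is None:
                    raise RecordValidationError(
                        f"{self.lesion_id}: mass lesion needs shape and margin")
                if self.distribution is not None:
                    raise RecordValidationError(
                        f"{self.lesion_id}: mass lesion cannot have a distribution")
            else:
                if self.distribution is None:
                    raise RecordValidationError(
                        f"{self.lesion_id}: non-mass lesion needs a distribution")
                if self.shape is not None or self.margin is not None:
                    raise RecordValidationError(
                        f"{self.lesion_id}: non-mass lesion cannot have shape/margin")
        else:
            for name in ("lesion_type", "shape", "margin", "distribution",
                         "internal_pattern", "adc"):
                if getattr(self, name) is not None:
                    raise RecordValidationError(
                        f"{self.lesion_id}: invisible lesion cannot carry {name}")
        if not self.size_cm > 0:
            raise RecordValidationError(
                f"{self.lesion_id}: size_cm must be > 0, got {self.size_cm}")
        if not (isinstance(self.birads, int) and 1 <= self.birads <= 5):
            raise RecordValidationError(
                f"{self.lesion_id}: birads must be an integer 1-5, got {self.birads}")


# Table 2-style default lexicon: descriptor value -> estimated malignancy risk.
_DEFAULT_RISK: dict[tuple[str, str], RiskClass] = {
    ("shape", Shape.OVAL): RiskClass.MINOR,
    ("shape", Shape.ROUND): RiskClass.INTERMEDIATE,
    ("shape", Shape.IRREGULAR): RiskClass.INTERMEDIATE,
    ("margin", Margin.CIRCUMSCRIBED): RiskClass.MINOR,
    ("margin", Margin.IRREGULAR): RiskClass.INTERMEDIATE,
    ("margin", Margin.SPICULATED): RiskClass.MAJOR,
    ("distribution", Distribution.FOCAL): RiskClass.MINOR,
    ("distribution", Distribution.LINEAR): RiskClass.INTERMEDIATE,
    ("distribution", Distribution.SEGMENTAL): RiskClass.MAJOR,
    ("internal_pattern", InternalPattern.HOMOGENEOUS): RiskClass.MINOR,
    ("internal_pattern", InternalPattern.HETEROGENEOUS): RiskClass.INTERMEDIATE,
    ("internal_pattern", InternalPattern.RIM): RiskClass.MAJOR,
}


@dataclass(frozen=True)
class DescriptorRiskTable:
    """Mapping (descriptor kind, value) -> malignancy risk class.

    The default content is the standard DWI morphological lexicon used for
    qualitative scoring: oval shape / circumscribed margin / focal
    distribution / homogeneous pattern are minor; round or irregular shape,
    irregular margin, linear distribution and heterogeneous pattern are
    intermediate; spiculated margin, segmental distribution and the high
    signal rim sign are major.  Injectable so lexicon variants can be tested.
    """

    mapping: Mapping[tuple[str, str], RiskClass] = field(
        default_factory=lambda: dict(_DEFAULT_RISK))

    def risk(self, kind: str, value: str) -> RiskClass:
        try:
            return self.mapping[(kind, value)]
        except KeyError:
            raise KeyError(f"no risk class for {kind}={value!r}") from None


@dataclass(frozen=True)
class DwiAssessment:
    """Per-lesion output of the DWI pipeline.

    ``qual_score`` is the 3-level morphological confidence score,
    ``adc_positive`` the quantitative call (ADC strictly below the cutoff),
    ``combined_positive`` the combination call.  A score-3 lesion is always
    combination-positive regardless of ADC.
    """

    lesion_id: str
    qual_score: int
    adc_positive: bool
    combined_positive: bool

    def __post_init__(self) -> None:
        if self.qual_score not in (1, 2, 3):
            raise ValueError(f"qual_score must be 1, 2 or 3, got {self.qual_score}")
        if self.qual_score == 3 and not self.combined_positive:
            raise ValueError("a score-3 lesion must be combination-positive")


TABLE_COLUMNS = (
    "lesion_id", "pathology", "dwi_visible", "lesion_type", "shape", "margin",
    "distribution", "internal_pattern", "adc", "size_cm", "birads",
)

_ENUM_FIELDS = {
    "pathology": Pathology,
    "lesion_type": LesionType,
    "shape": Shape,
    "margin": Margin,
    "distribution": Distribution,
    "internal_pattern": InternalPattern,
}


def adc_to_si(adc: float) -> float:
    """Convert ADC from 1e-3 mm^2/s (display unit) to mm^2/s."""
    return adc * 1e-3


def adc_from_si(adc_mm2_s: float) -> float:
    """Convert ADC from mm^2/s to the 1e-3 mm^2/s display unit."""
    return adc_mm2_s * 1e3


def records_to_frame(records: Iterable[LesionRecord]) -> pd.DataFrame:
    """Lossless DataFrame view of a record collection (enums as strings)."""
    rows = []
    for r in records:
        row = {}
        for f in fields(LesionRecord):
            v = getattr(r, f.name)
            row[f.name] = v.value if isinstance(v, enum.Enum) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def _parse_row(row: Mapping[str, str], idx: int) -> LesionRecord:
    def get(col: str) -> str | None:
        v = row.get(col)
        if v is None:
            return None
        v = str(v).strip()
        return v if v not in ("", "nan", "None") else None

    try:
        kwargs: dict = {"lesion_id": get("lesion_id") or f"row{idx}"}
        vis = (get("dwi_visible") or "").lower()
        if vis not in ("true", "false", "1", "0"):
            raise RecordValidationError(
                f"dwi_visible must be boolean-like, got {row.get('dwi_visible')!r}")
        kwargs["dwi_visible"] = vis in ("true", "1")
        for col, enum_cls in _ENUM_FIELDS.items():
            raw = get(col)
            if raw is None:
                kwargs[col] = None
            else:
                try:
                    kwargs[col] = enum_cls(raw.lower())
                except ValueError:
                    raise RecordValidationError(
                        f"invalid {col} value {raw!r} "
                        f"(expected one of {[e.value for e in enum_cls]})")
        if kwargs["pathology"] is None:
            raise RecordValidationError("pathology is required")
        adc_raw = get("adc")
        kwargs["adc"] = float(adc_raw) if adc_raw is not None else None
        kwargs["size_cm"] = float(get("size_cm") or "nan")
        birads_raw = get("birads")
        if birads_raw is None:
            raise RecordValidationError("birads is required")
        kwargs["birads"] = int(float(birads_raw))
        return LesionRecord(**kwargs)
    except RecordValidationError as e:
        raise RecordValidationError(str(e), row=idx) from None
    except (TypeError, ValueError) as e:
        raise RecordValidationError(str(e), row=idx) from None


def read_lesion_table(path: str | Path, format: str | None = None) -> list[LesionRecord]:
    """Read and validate a lesion table from CSV or XLSX.

    Column headers are matched case-insensitively against the documented
    schema (:data:`TABLE_COLUMNS`); every row is validated against the
    :class:`LesionRecord` invariants and row order is preserved.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`RecordValidationError` (with the row index) for invalid rows.
    """
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0, dtype=str, keep_default_na=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return [_parse_row(row, i) for i, row in enumerate(df.to_dict("records"))]


def write_lesion_table(records: Sequence[LesionRecord], path: str | Path,
                       format: str | None = None) -> None:
    """Write records to CSV or XLSX, losslessly round-trippable by
    :func:`read_lesion_table` (floats written at full repr precision)."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv")
    df = records_to_frame(records)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "xlsx":
        # floats stored as text: xlsx numeric cells keep only 15 significant
        # digits, which would break lossless round-trips
        for col in ("adc", "size_cm"):
            df[col] = df[col].map(lambda v: repr(v) if isinstance(v, float) else v)
        df.to_excel(path, index=False, sheet_name="lesions")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def split_visible(records: Sequence[LesionRecord]
                  ) -> tuple[list[LesionRecord], list[LesionRecord]]:
    """Partition a cohort into (DWI-visible, not visible) lesions.

    A lesion not visible on diffusion-weighted images is treated as a
    negative DWI case and excluded from all DWI-level analyses; the full
    cohort (including invisible lesions, which keep their BI-RADS category)
    is retained for DCE-level analyses.
    """
    visible = [r for r in records if r.dwi_visible]
    not_visible = [r for r in records if not r.dwi_visible]
    return visible, not_visible


def detection_rate(records: Sequence[LesionRecord]) -> Fraction:
    """Fraction of lesions visible on DWI (exact rational)."""
    if not records:
        raise ValueError("empty cohort")
    visible, _ = split_visible(records)
    return Fraction(len(visible), len(records))
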